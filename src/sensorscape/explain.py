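"""Model interpretation: additive attributions, heatmap ordering, embeddings.

Feature attributions follow the Shapley/TreeSHAP contract: per sample and per
class the attributions plus the base value reconstruct the model's raw score
exactly (local accuracy).  They are obtained from the boosting backend's exact
tree-path algorithm; :func:`attribute` verifies the reconstruction on every row
and refuses to return a table that violates it.  A positive value pushes the
model toward the class.

The unsupervised views used alongside the models are hierarchical clustering of
log2-transformed profiles (heatmap row/column ordering) and a 2-D t-SNE
embedding of samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats
from sklearn.manifold import TSNE

from .models import SensorProfileClassifier, SensorProfileRegressor
from .profile import SensorProfileMatrix

_ADDITIVITY_RTOL = 1e-6


@dataclass
class AttributionTable:
    """Long-format additive attributions plus per-(sample, class) base values.

    ``table`` columns: sample, class, feature, value.  ``base`` is indexed by
    sample with one column per class.
    """

    table: pd.DataFrame
    base: pd.DataFrame
    feature_names: list[str]

    def pivot(self, cls: str) -> pd.DataFrame:
        """Sample x feature attribution matrix for one class."""
        sub = self.table[self.table["class"] == cls]
        return sub.pivot(index="sample", columns="feature", values="value")

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def attribute(
    model: SensorProfileClassifier | SensorProfileRegressor, X: pd.DataFrame
) -> AttributionTable:
    """Exact per-class additive attributions for every row of ``X``.

    Local accuracy — sum(attributions) + base == raw score — is checked at
    relative tolerance 1e-6 for every (sample, class) pair; any violation
    raises rather than returning misleading importances.
    """
    booster = getattr(model, "booster_", None)
    if booster is None:
        raise ValueError("model is not fitted or exposes no tree structure")
    Xv = np.asarray(X, dtype=float)
    n, n_feat = Xv.shape
    samples = list(getattr(X, "index", range(n)))
    features = list(model.feature_names_)
    contrib = booster.predict(Xv, pred_contrib=True)
    raw = model.raw_scores(Xv)
    if raw.ndim == 1:
        raw = raw[:, None]
        if hasattr(model, "classes_"):
            # binary model: one margin, positive pushes toward the second class
            classes = [str(model.classes_[1])]
        else:
            classes = ["target"]
    else:
        classes = [str(c) for c in model.classes_]
    contrib = contrib.reshape(n, len(classes), n_feat + 1)
    values = contrib[:, :, :-1]
    base = contrib[:, :, -1]
    recon = values.sum(axis=2) + base
    scale = np.maximum(np.abs(raw), 1.0)
    if not np.all(np.abs(recon - raw) <= _ADDITIVITY_RTOL * scale):
        worst = float(np.max(np.abs(recon - raw) / scale))
        raise AssertionError(
            f"attribution backend violated local accuracy (max rel err {worst:.2e})"
        )
    long = pd.DataFrame(
        {
            "sample": np.repeat(samples, len(classes) * n_feat),
            "class": np.tile(np.repeat(classes, n_feat), n),
            "feature": np.tile(features, n * len(classes)),
            "value": values.reshape(-1),
        }
    )
    base_df = pd.DataFrame(base, index=pd.Index(samples, name="sample"), columns=classes)
    return AttributionTable(long, base_df, features)


def rank_features(
    t: AttributionTable, scope: str = "global", cls: str | None = None, signed: bool = False
) -> pd.Series:
    """Features ordered by summed attribution magnitude, descending.

    ``scope="global"`` sums over all samples and classes; ``scope="class"``
    restricts to one class.  By default the absolute value is summed; with
    ``signed=True`` the raw signed sum is ranked by magnitude instead.  Ties
    break by feature id so the order is stable.
    """
    if t.table.empty:
        raise ValueError("empty attribution table")
    if scope == "class":
        if cls is None:
            raise ValueError("class scope requires cls")
        sub = t.table[t.table["class"] == cls]
        if sub.empty:
            raise ValueError(f"no attributions for class {cls!r}")
    elif scope == "global":
        sub = t.table
    else:
        raise ValueError("scope must be 'class' or 'global'")
    sums = sub.groupby("feature")["value"].sum() if signed else sub.groupby("feature")["value"].apply(lambda v: v.abs().sum())
    sums = sums.reindex(t.feature_names).fillna(0.0)
    order = sorted(t.feature_names, key=lambda f: (-abs(sums[f]), f))
    out = sums.loc[order]
    out.name = "importance"
    return out


def _log2_transform(values: pd.DataFrame) -> pd.DataFrame:
    nonzero = values.to_numpy()[values.to_numpy() > 0]
    pseudo = nonzero.min() / 2 if nonzero.size else 1e-9
    return np.log2(values + pseudo)


def hierarchical_order(
    m: SensorProfileMatrix, linkage: str = "average", metric: str = "euclidean"
) -> tuple[list[int], list[int], dict]:
    """Heatmap leaf orders from hierarchical clustering of log2 profiles.

    The pseudocount for the log2 transform is half the smallest nonzero value.
    Returns (row order, column order, linkage matrices); a single row or
    column yields the trivial order.
    """
    logv = _log2_transform(m.values)
    out: dict[str, np.ndarray | None] = {"rows": None, "cols": None}
    orders = []
    for axis, key in ((logv, "rows"), (logv.T, "cols")):
        if axis.shape[0] < 2:
            orders.append(list(range(axis.shape[0])))
            continue
        Z = hierarchy.linkage(pdist(axis.to_numpy(), metric=metric), method=linkage)
        out[key] = Z
        orders.append(list(hierarchy.leaves_list(Z)))
    return orders[0], orders[1], out


def embed(
    m: SensorProfileMatrix, method: str = "tsne", seed: int = 0, perplexity: float = 30.0
) -> pd.DataFrame:
    """2-D t-SNE coordinates per sample (deterministic given ``seed``).

    Perplexity is clipped to (n-1)/3 so small corpora stay valid.
    """
    if method != "tsne":
        raise ValueError("only t-SNE embedding is supported")
    n = m.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to embed")
    perp = min(perplexity, (n - 1) / 3)
    coords = TSNE(
        n_components=2, random_state=seed, perplexity=perp, init="pca"
    ).fit_transform(m.values.to_numpy())
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    return pd.DataFrame(coords, index=m.values.index, columns=["tsne1", "tsne2"])


def correlated_feature_group(
    m: SensorProfileMatrix, anchor_feature: str, k: int
) -> pd.Series:
    """The k features most rank-correlated with the anchor across samples.

    Spearman correlation of abundance vectors; ranked by absolute value with
    the anchor itself excluded.  A constant anchor has no rank order and is an
    error.
    """
    if anchor_feature not in m.values.columns:
        raise KeyError(f"anchor feature {anchor_feature!r} not in matrix")
    anchor = m.values[anchor_feature].to_numpy()
    if np.allclose(anchor, anchor[0]):
        raise ValueError(f"anchor feature {anchor_feature!r} is constant")
    if k == 0:
        return pd.Series(dtype=float, name="spearman_rho")
    rhos: dict[str, float] = {}
    for col in m.values.columns:
        if col == anchor_feature:
            continue
        vec = m.values[col].to_numpy()
        if np.allclose(vec, vec[0]):
            continue
        rhos[col] = float(stats.spearmanr(anchor, vec).statistic)
    ordered = sorted(rhos, key=lambda c: (-abs(rhos[c]), c))[:k]
    return pd.Series({c: rhos[c] for c in ordered}, name="spearman_rho").loc[ordered]


def export_class_attributions(
    t: AttributionTable, X: pd.DataFrame, cls: str, path: str | Path, top: int = 20
) -> pd.DataFrame:
    """Flat per-class export of top-feature attributions with feature values.

    Columns: rank, feature, sample, attribution, feature_value — the tabular
    reduction of a force plot.
    """
    ranked = rank_features(t, scope="class", cls=cls)
    keep = list(ranked.index[:top])
    sub = t.table[(t.table["class"] == cls) & t.table["feature"].isin(keep)].copy()
    rank_of = {f: i + 1 for i, f in enumerate(keep)}
    sub["rank"] = sub["feature"].map(rank_of)
    sub["feature_value"] = [
        X.loc[s, f] for s, f in zip(sub["sample"], sub["feature"])
    ]
    sub = sub.sort_values(["rank", "sample"])[["rank", "feature", "sample", "value", "feature_value"]]
    sub.columns = ["rank", "feature", "sample", "attribution", "feature_value"]
    sub.to_csv(path, sep="\t", index=False)
    return sub


def plot_heatmap(m: SensorProfileMatrix, path: str | Path) -> None:
    """Log2-scale clustered heatmap of the profile matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows, cols, _ = hierarchical_order(m)
    logv = _log2_transform(m.values).iloc[rows, cols]
    fig, ax = plt.subplots(figsize=(7, 5))
    im = ax.imshow(logv.to_numpy(), aspect="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label="log2 fraction")
    ax.set_xlabel("sensor clusters")
    ax.set_ylabel("metagenomes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_embedding(coords: pd.DataFrame, labels: pd.Series, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for lab in sorted(labels.unique()):
        pts = coords[labels.reindex(coords.index) == lab]
        ax.scatter(pts["tsne1"], pts["tsne2"], s=12, label=str(lab), alpha=0.8)
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
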