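"""Ecosystem-level richness statistics and inter-ecosystem correlation.

Two complementary richness measures summarise how sensor-cluster diversity is
distributed over ecosystems:

* **Relative Ecosystem Richness (RER)** — the fraction of all clusters observed
  anywhere that occur in a given ecosystem; how much the ecosystem contributes
  to global sensor diversity.
* **Ecosystem Typical Sample Richness (ETSR)** — the mean number of distinct
  clusters per sample of the ecosystem, divided by the ecosystem's total
  distinct-cluster count; how representative a typical sample is of its
  ecosystem's repertoire.

Both are computed on the *unfiltered* matrix (presence = fraction > 0) so that
rare clusters count toward the richness picture.  Inter-ecosystem similarity is
the Spearman rank correlation between per-ecosystem mean abundance profiles.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .profile import SensorProfileMatrix, sensor_fraction


def _presence(m: SensorProfileMatrix) -> pd.DataFrame:
    return m.values > 0


def _labels(m: SensorProfileMatrix, by: str) -> pd.Series:
    if by not in m.meta.columns:
        raise ValueError(f"metadata lacks a {by!r} column")
    return m.meta[by]


def rer(m: SensorProfileMatrix, by: str = "ecosystem") -> pd.Series:
    """Relative Ecosystem Richness per label class.

    Numerator: clusters present in >= 1 sample of the class.  Denominator:
    clusters present anywhere in the matrix.
    """
    presence = _presence(m)
    denom = int(presence.any(axis=0).sum())
    if denom == 0:
        raise ValueError("no cluster is present in any sample")
    per_class = presence.groupby(_labels(m, by)).any().sum(axis=1)
    out = per_class / denom
    out.name = "rer"
    return out


def etsr(m: SensorProfileMatrix, by: str = "ecosystem") -> pd.Series:
    """Ecosystem Typical Sample Richness per label class.

    Mean per-sample distinct-cluster count divided by the class's total
    distinct-cluster count; NaN for a class with no clusters at all (0/0 is
    undefined, not zero).
    """
    presence = _presence(m)
    labels = _labels(m, by)
    per_sample = presence.sum(axis=1)
    mean_per_class = per_sample.groupby(labels).mean()
    total_per_class = presence.groupby(labels).any().sum(axis=1)
    out = mean_per_class / total_per_class.replace(0, np.nan)
    out.name = "etsr"
    return out


def ecosystem_metrics(m: SensorProfileMatrix, by: str = "ecosystem") -> pd.DataFrame:
    """RER, ETSR, mean sensor fraction and sample count per label class."""
    labels = _labels(m, by)
    table = pd.DataFrame(
        {
            "rer": rer(m, by),
            "etsr": etsr(m, by),
            "mean_sensor_fraction": sensor_fraction(m).groupby(labels).mean(),
            "n_samples": labels.value_counts().sort_index(),
        }
    )
    table.index.name = by
    return table


def ecosystem_correlation(
    m: SensorProfileMatrix, by: str = "ecosystem", method: str = "spearman"
) -> pd.DataFrame:
    """Class x class Spearman correlation of mean abundance profiles.

    The diagonal is 1 by definition; a class whose mean profile is constant has
    undefined rank correlation and gets NaN off-diagonal.
    """
    if method != "spearman":
        raise ValueError("only Spearman correlation is supported")
    labels = _labels(m, by)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes for a correlation matrix")
    means = m.values.groupby(labels).mean().loc[classes]
    corr = pd.DataFrame(np.nan, index=classes, columns=classes)
    vectors = {c: means.loc[c].to_numpy() for c in classes}
    constant = {c: np.allclose(vectors[c], vectors[c][0]) for c in classes}
    for i, a in enumerate(classes):
        corr.loc[a, a] = 1.0
        for b in classes[i + 1 :]:
            if constant[a] or constant[b]:
                continue
            rho = stats.spearmanr(vectors[a], vectors[b]).statistic
            corr.loc[a, b] = corr.loc[b, a] = rho
    return corr


def rare_cluster_enrichment(
    m: SensorProfileMatrix, by: str = "ecosystem", rarity_max_ecosystems: int = 1
) -> pd.Series:
    """Per class: the number of its clusters found in few ecosystems overall.

    A cluster is "rare" when its ecosystem-presence count (number of classes
    with >= 1 positive sample) is <= ``rarity_max_ecosystems``; the default 1
    counts ecosystem-unique clusters.
    """
    if rarity_max_ecosystems < 1:
        raise ValueError("rarity_max_ecosystems must be >= 1")
    presence = _presence(m)
    labels = _labels(m, by)
    class_presence = presence.groupby(labels).any()
    eco_counts = class_presence.sum(axis=0)
    rare = eco_counts.index[eco_counts <= rarity_max_ecosystems]
    out = class_presence[list(rare)].sum(axis=1)
    out.name = "n_rare_clusters"
    return out


def plot_richness_scatter(metrics: pd.DataFrame, path: str | Path) -> None:
    """RER vs ETSR scatter, point size proportional to sample count."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    sizes = 20 + 180 * metrics["n_samples"] / max(metrics["n_samples"].max(), 1)
    ax.scatter(metrics["rer"], metrics["etsr"], s=sizes, alpha=0.7)
    for name, row in metrics.iterrows():
        ax.annotate(str(name), (row["rer"], row["etsr"]), fontsize=6)
    ax.set_xlabel("Relative Ecosystem Richness")
    ax.set_ylabel("Ecosystem Typical Sample Richness")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation_heatmap(corr: pd.DataFrame, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.columns)), corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr.index)), corr.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
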