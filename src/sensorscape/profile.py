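"""The metagenome x sensor-cluster fractional abundance matrix.

A matrix value is the summed gene copy number of a metagenome's genes that
contribute a sensory domain to the cluster, divided by the metagenome's total
gene copy number.  A gene whose domains fall in k distinct clusters contributes
its full copy number to each of the k clusters (the per-cluster accounting also
used for the planted ground truth), so row sums are per-cluster totals, not a
unique-gene fraction.

Two filters shape the modelling matrix: clusters must be present (value > 0) in
at least ``min_prevalence`` metagenomes (default 100), and label classes must
have strictly more than ``min_per_class`` members (default 30 for ecosystems,
14 for condition labels), with ambiguous labels such as "Unclassified" dropped
outright.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .extract import GeneRecord, SensorDomain

logger = logging.getLogger(__name__)


@dataclass
class SensorProfileMatrix:
    """Fractional sensor-cluster abundances plus per-sample metadata.

    ``values``: DataFrame, rows = metagenome ids, columns = cluster ids.
    ``meta``: DataFrame indexed like the rows (ecosystem, condition, physical
    parameters).  ``totals``: per-row total gene copy number.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate row or column ids in profile matrix")
        vals = self.values.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValueError("negative abundance fraction")
        self.meta = self.meta.reindex(self.values.index)
        self.totals = self.totals.reindex(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, rows: Sequence[str]) -> "SensorProfileMatrix":
        return SensorProfileMatrix(self.values.loc[rows], self.meta.loc[rows], self.totals.loc[rows])

    def write(self, prefix: str | Path) -> dict[str, Path]:
        """Dense TSV, sparse triplet TSV and the metadata table."""
        prefix = Path(prefix)
        paths = {
            "dense": prefix.with_suffix(".dense.tsv"),
            "triplets": prefix.with_suffix(".triplets.tsv"),
            "meta": prefix.with_suffix(".meta.tsv"),
        }
        self.values.to_csv(paths["dense"], sep="\t", index_label="metagenome_id")
        stacked = self.values.stack()
        stacked = stacked[stacked > 0]
        trip = stacked.rename_axis(["metagenome_id", "cluster_id"]).rename("fraction").reset_index()
        trip.to_csv(paths["triplets"], sep="\t", index=False)
        self.meta.to_csv(paths["meta"], sep="\t", index_label="metagenome_id")
        return paths


def gene_totals_from_records(genes: Sequence[GeneRecord]) -> pd.Series:
    """Per-metagenome total gene copy number, summed over all genes."""
    totals: dict[str, float] = {}
    for g in genes:
        totals[g.metagenome_id] = totals.get(g.metagenome_id, 0.0) + g.copy_number
    return pd.Series(totals, name="total_copies")


def build_matrix(
    domains: Sequence[SensorDomain],
    assignment: ClusterAssignment,
    gene_totals: pd.Series | Mapping[str, float],
    meta: pd.DataFrame,
) -> SensorProfileMatrix:
    """Assemble the fractional abundance matrix from cluster assignments.

    Every domain must be assigned (directly or through the deduplication
    multiplicity map); metagenomes with zero total gene copies are an error
    because the fraction is undefined.  Metagenomes present in ``gene_totals``
    but without sensors keep an all-zero row.
    """
    gene_totals = pd.Series(dict(gene_totals), name="total_copies") if not isinstance(gene_totals, pd.Series) else gene_totals
    cluster_of = assignment.expand_members()
    contributions: dict[tuple[str, str], float] = {}
    seen_gene_cluster: set[tuple[str, str, str]] = set()
    for dom in domains:
        if dom.metagenome_id not in gene_totals.index:
            raise ValueError(f"metagenome {dom.metagenome_id} missing from gene totals")
        if gene_totals[dom.metagenome_id] <= 0:
            raise ValueError(f"metagenome {dom.metagenome_id} has zero total gene copies")
        try:
            cluster = cluster_of[dom.domain_id]
        except KeyError:
            raise ValueError(f"domain {dom.domain_id} is not in the cluster assignment") from None
        key = (dom.metagenome_id, dom.gene_id, cluster)
        if key in seen_gene_cluster:
            continue  # same gene, same cluster: count the gene once
        seen_gene_cluster.add(key)
        mc = (dom.metagenome_id, cluster)
        contributions[mc] = contributions.get(mc, 0.0) + dom.copy_number
    rows = list(gene_totals.index)
    cols = sorted({c for _, c in contributions})
    values = pd.DataFrame(0.0, index=rows, columns=cols)
    for (mid, cluster), copies in contributions.items():
        values.loc[mid, cluster] = copies / gene_totals[mid]
    if meta is not None and "metagenome_id" in meta.columns:
        meta = meta.set_index("metagenome_id")
    return SensorProfileMatrix(values, meta, gene_totals)


def filter_clusters(m: SensorProfileMatrix, min_prevalence: int = 100) -> SensorProfileMatrix:
    """Keep clusters present (value > 0) in at least ``min_prevalence`` samples.

    Row values are left untouched — no renormalisation — so dropped rare
    clusters simply disappear from the feature set.
    """
    if min_prevalence < 1:
        raise ValueError("min_prevalence must be >= 1")
    prevalence = (m.values > 0).sum(axis=0)
    keep = prevalence.index[prevalence >= min_prevalence]
    if len(keep) == 0:
        warnings.warn("prevalence filter removed every cluster", stacklevel=2)
    logger.info("prevalence filter: %d -> %d clusters", m.n_clusters, len(keep))
    return SensorProfileMatrix(m.values[list(keep)], m.meta, m.totals)


def filter_samples(
    m: SensorProfileMatrix,
    min_per_class: int = 30,
    drop_labels: frozenset[str] | set[str] = frozenset({"Unclassified"}),
    label_field: str = "ecosystem",
) -> SensorProfileMatrix:
    """Keep samples whose label class has STRICTLY more than ``min_per_class`` members.

    Labels in ``drop_labels`` are removed regardless of class size (class sizes
    are counted after that removal).  Raises if nothing survives.
    """
    if label_field not in m.meta.columns:
        raise ValueError(f"metadata lacks a {label_field!r} column")
    labels = m.meta[label_field]
    if labels.isna().any():
        raise ValueError(f"{label_field} label missing for some samples")
    keep_mask = ~labels.isin(drop_labels)
    sizes = labels[keep_mask].value_counts()
    big_enough = set(sizes.index[sizes > min_per_class])
    keep_mask &= labels.isin(big_enough)
    if not keep_mask.any():
        raise ValueError("sample filter removed every metagenome")
    rows = list(m.values.index[keep_mask])
    logger.info(
        "sample filter (%s > %d): %d -> %d samples, %d classes",
        label_field, min_per_class, m.n_samples, len(rows), len(big_enough),
    )
    return m.subset_rows(rows)


def sensor_fraction(m: SensorProfileMatrix) -> pd.Series:
    """Per-metagenome sensor fraction: the row sum of the (unfiltered) matrix.

    Meaningful on the full matrix only — on a prevalence-filtered matrix it is
    the fraction covered by the retained clusters.
    """
    frac = m.values.sum(axis=1)
    frac.name = "sensor_fraction"
    return frac


def pfam_feature_matrix(
    m: SensorProfileMatrix, pfam_of_cluster: Mapping[str, str]
) -> SensorProfileMatrix:
    """Collapse cluster columns to Pfam-level features by summation.

    The coarse feature set used as the baseline in cluster-vs-Pfam model
    comparisons; unknown clusters raise.
    """
    missing = [c for c in m.values.columns if c not in pfam_of_cluster]
    if missing:
        raise ValueError(f"no Pfam mapping for clusters: {missing[:5]}")
    grouped = m.values.T.groupby(lambda c: pfam_of_cluster[c]).sum().T
    return SensorProfileMatrix(grouped, m.meta, m.totals)


def pfam_of_clusters(
    assignment: ClusterAssignment, domains: Sequence[SensorDomain]
) -> dict[str, str]:
    """Majority Pfam accession per cluster (ties broken alphabetically)."""
    counts: dict[str, dict[str, int]] = {}
    cluster_of = assignment.expand_members()
    for dom in domains:
        cl = cluster_of[dom.domain_id]
        counts.setdefault(cl, {}).setdefault(dom.pfam_acc, 0)
        counts[cl][dom.pfam_acc] += 1
    return {
        cl: max(sorted(accs), key=lambda a: accs[a])
        for cl, accs in counts.items()
    }
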