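"""Identification of histidine-kinase (HK) proteins and excision of their sensory domains.

Prokaryotic sensor histidine kinases are recognised here by the co-occurrence of
their two conserved Pfam domains, the HATPase domain (PF02518) and the HisKA
dimerisation/phosphoacceptor domain (PF00512).  Everything upstream of those two
domains on the protein — PAS, Cache, GAF and the rest of the curated sensor-domain
vocabulary — is the part of the molecule that actually detects the environmental
signal, and it is those sensory regions that the rest of the pipeline clusters
and profiles.

Coordinates follow the Pfam/HMMER alignment convention: 1-based and inclusive on
both ends, so a hit ``start=5, end=64`` covers 60 residues.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Conserved domains whose co-occurrence defines a histidine kinase.
HATPASE = "PF02518"
HISKA = "PF00512"
DEFAULT_CONSERVED = frozenset({HATPASE, HISKA})


class AnnotationError(ValueError):
    """A gene record violates the coordinate/copy-number contract."""


@dataclass(frozen=True)
class DomainHit:
    """One Pfam domain hit on a protein (1-based, inclusive coordinates)."""

    pfam_acc: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneRecord:
    """One protein-coding gene in one metagenome with its domain annotations.

    ``copy_number`` is the read-mapping abundance estimate of the gene within its
    metagenome and is the weight used in every downstream fraction.
    """

    metagenome_id: str
    gene_id: str
    protein_length: int
    domain_hits: list[DomainHit] = field(default_factory=list)
    copy_number: float = 1.0

    def validate(self) -> None:
        if self.copy_number < 0:
            raise AnnotationError(f"gene {self.gene_id}: negative copy number")
        if self.protein_length < 1:
            raise AnnotationError(f"gene {self.gene_id}: non-positive protein length")
        for hit in self.domain_hits:
            if not (1 <= hit.start <= hit.end <= self.protein_length):
                raise AnnotationError(
                    f"gene {self.gene_id}: hit {hit.pfam_acc} "
                    f"[{hit.start},{hit.end}] outside protein of length "
                    f"{self.protein_length}"
                )

    def accessions(self) -> set[str]:
        return {h.pfam_acc for h in self.domain_hits}


@dataclass
class HKConfig:
    """Which accessions mark the conserved HK core and which mark sensors.

    The two sets must be disjoint: a domain is either part of the kinase
    machinery or part of the input-sensing repertoire, never both.
    """

    conserved_accs: frozenset[str] = DEFAULT_CONSERVED
    sensor_accs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.conserved_accs = frozenset(self.conserved_accs)
        self.sensor_accs = frozenset(self.sensor_accs)
        overlap = self.conserved_accs & self.sensor_accs
        if overlap:
            raise ValueError(f"accessions both conserved and sensor: {sorted(overlap)}")


@dataclass(frozen=True)
class SensorDomain:
    """An excised sensory-domain amino-acid sequence with its provenance."""

    gene_id: str
    metagenome_id: str
    domain_index: int
    pfam_acc: str
    start: int
    end: int
    sequence: str
    copy_number: float = 1.0

    @property
    def domain_id(self) -> str:
        """Stable id used in FASTA headers and cluster assignments."""
        return f"{self.gene_id}|{self.domain_index}|{self.pfam_acc}"


def identify_hk(genes: Iterable[GeneRecord], cfg: HKConfig | None = None) -> list[GeneRecord]:
    """Return the genes carrying at least one hit of EACH conserved accession.

    Order-stable: output preserves input order.  Records are validated first so
    a malformed coordinate fails loudly with its gene id rather than corrupting
    downstream fractions.
    """
    cfg = cfg or HKConfig()
    out = []
    for gene in genes:
        gene.validate()
        accs = gene.accessions()
        if all(acc in accs for acc in cfg.conserved_accs):
            out.append(gene)
    return out


def excise_sensors(hk: GeneRecord, protein_seq: str, cfg: HKConfig) -> list[SensorDomain]:
    """Cut the sensory-domain subsequences out of one HK protein.

    One :class:`SensorDomain` is produced per hit whose accession is in
    ``cfg.sensor_accs``; conserved-domain hits and accessions outside both sets
    are never excised.  Domains come back in coordinate order.  Overlapping
    sensor hits cannot both be excised as disjoint substrings; the shorter of an
    overlapping pair is dropped and logged (ties keep the earlier hit).
    """
    if len(protein_seq) != hk.protein_length:
        raise AnnotationError(
            f"gene {hk.gene_id}: protein sequence length {len(protein_seq)} "
            f"!= annotated length {hk.protein_length}"
        )
    hits = sorted(
        (h for h in hk.domain_hits if h.pfam_acc in cfg.sensor_accs),
        key=lambda h: (h.start, h.end),
    )
    kept: list[DomainHit] = []
    for hit in hits:
        if hit.end > len(protein_seq):
            raise AnnotationError(
                f"gene {hk.gene_id}: hit {hit.pfam_acc} ends at {hit.end} "
                f"beyond sequence of length {len(protein_seq)}"
            )
        if kept and hit.start <= kept[-1].end:
            prev = kept[-1]
            if hit.length > prev.length:
                logger.warning(
                    "gene %s: dropping sensor hit %s [%d,%d] overlapping %s",
                    hk.gene_id, prev.pfam_acc, prev.start, prev.end, hit.pfam_acc,
                )
                kept[-1] = hit
            else:
                logger.warning(
                    "gene %s: dropping sensor hit %s [%d,%d] overlapping %s",
                    hk.gene_id, hit.pfam_acc, hit.start, hit.end, prev.pfam_acc,
                )
            continue
        kept.append(hit)
    return [
        SensorDomain(
            gene_id=hk.gene_id,
            metagenome_id=hk.metagenome_id,
            domain_index=i,
            pfam_acc=hit.pfam_acc,
            start=hit.start,
            end=hit.end,
            sequence=protein_seq[hit.start - 1 : hit.end],
            copy_number=hk.copy_number,
        )
        for i, hit in enumerate(kept)
    ]


def count_sensor_domains(
    hks: Sequence[GeneRecord], cfg: HKConfig
) -> dict[int, int]:
    """Histogram: number of sensory domains per HK protein -> protein count.

    Counts annotation hits (not excised substrings), so overlapping hits each
    count; the counts sum to ``len(hks)``.
    """
    counter: Counter[int] = Counter()
    for hk in hks:
        n = sum(1 for h in hk.domain_hits if h.pfam_acc in cfg.sensor_accs)
        counter[n] += 1
    return dict(counter)


def pfam_cluster_crosstab(
    cluster_of: Mapping[str, str], domains: Sequence[SensorDomain]
) -> pd.Series:
    """For each sensor Pfam accession, the number of distinct clusters containing it.

    ``cluster_of`` maps domain ids (``gene|index|pfam``) to cluster ids and must
    cover every domain; a cluster containing two Pfams increments both counts.
    """
    clusters_per_pfam: dict[str, set[str]] = {}
    for dom in domains:
        try:
            cluster = cluster_of[dom.domain_id]
        except KeyError:
            raise KeyError(f"domain {dom.domain_id} has no cluster assignment") from None
        clusters_per_pfam.setdefault(dom.pfam_acc, set()).add(cluster)
    counts = {acc: len(cl) for acc, cl in sorted(clusters_per_pfam.items())}
    return pd.Series(counts, dtype=int, name="n_clusters")
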