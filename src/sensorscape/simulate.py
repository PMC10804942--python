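"""Synthetic metagenome corpora with planted sensor-family structure.

Real inputs to the pipeline are per-metagenome gene/domain annotation exports:
every gene row carries Pfam hits with coordinates and a read-mapping copy-number
estimate, and each metagenome carries a three-level GOLD-style ecosystem label
(``Host-associated:Human:Large Intestine``).  This module emulates exactly that
shape with known ground truth so that every downstream stage — extraction,
clustering, profiling, richness statistics, classification — can be tested
against planted answers.

The generative model, per ecosystem:

* a shared pool of sensor *families* (rejection-sampled centroid sequences,
  pairwise identity < 0.5, so families are separable at the clustering
  threshold); each family carries a Pfam accession;
* per metagenome, family abundances are Dirichlet-distributed around the
  ecosystem's ``cluster_weights`` (the concentration parameter sets
  sample-to-sample variability; the Dirichlet choice is this module's, the
  simplest exchangeable model of compositional noise);
* HK genes carry the two conserved domains plus 0-3 sensor domains by default
  (heavier multi-domain architectures come from :func:`inject_multidomain_hk`,
  up to the 32-domain extreme observed in nature);
* gene copy numbers are geometric with mean 2, standing in for read-mapping
  abundance estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .cluster import pairwise_identity
from .extract import DEFAULT_CONSERVED, HATPASE, HISKA, DomainHit, GeneRecord, HKConfig, SensorDomain

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_LINKER = 5          # residues between adjacent domains
_HISKA_LEN = 60      # synthetic conserved-domain spans
_HATPASE_LEN = 100
_INJECT_DOMAIN_LEN = 30

#: default distribution of sensor-domain counts per HK gene
_SENSOR_COUNT_VALUES = (0, 1, 2, 3)
_SENSOR_COUNT_PROBS = (0.15, 0.50, 0.25, 0.10)


class SeparabilityError(ValueError):
    """The requested family pool cannot be made pairwise-separable."""


@dataclass
class EcosystemSpec:
    """Declarative description of one ecosystem's metagenomes.

    ``cluster_weights`` are expected abundance weights over the shared family
    pool (normalised to sum to 1); per-sample weights are Dirichlet draws with
    concentration ``dirichlet_concentration`` restricted to the support.
    """

    name: str
    n_metagenomes: int
    cluster_weights: Sequence[float]
    sensor_fraction_mean: float = 0.10
    background_genes_mean: int = 300
    physical_params: Mapping[str, tuple[float, float]] | None = None
    conditions: Mapping[str, float] | None = None
    dirichlet_concentration: float = 50.0

    def __post_init__(self) -> None:
        if self.n_metagenomes < 0:
            raise ValueError(f"ecosystem {self.name}: negative n_metagenomes")
        w = np.asarray(self.cluster_weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError(f"ecosystem {self.name}: cluster_weights must be nonnegative, not all zero")
        if not (0 < self.sensor_fraction_mean < 1):
            raise ValueError(f"ecosystem {self.name}: sensor_fraction_mean outside (0,1)")
        if self.background_genes_mean < 1:
            raise ValueError(f"ecosystem {self.name}: background_genes_mean < 1")
        self.cluster_weights = w / w.sum()


@dataclass
class FamilyPool:
    """Centroid sequence, Pfam accession and mutation model per planted family."""

    centroids: list[str]
    pfam_of_family: list[str]
    mutation_rate: float
    seq_len_range: tuple[int, int]

    @property
    def n_families(self) -> int:
        return len(self.centroids)

    def variant(self, family: int, rng: np.random.Generator) -> str:
        """A family member: identity to its centroid is >= 1 - mutation_rate.

        The substitution count is binomial but hard-capped at
        ``floor(mutation_rate * length)`` so the identity guarantee is exact,
        not just in expectation.
        """
        centroid = self.centroids[family]
        n = len(centroid)
        cap = int(self.mutation_rate * n)
        k = min(int(rng.binomial(n, self.mutation_rate)), cap)
        if k == 0:
            return centroid
        positions = rng.choice(n, size=k, replace=False)
        seq = list(centroid)
        for pos in positions:
            choices = [a for a in AMINO_ACIDS if a != seq[pos]]
            seq[pos] = choices[int(rng.integers(len(choices)))]
        return "".join(seq)


def make_family_pool(
    n_families: int,
    seq_len_range: tuple[int, int] = (60, 120),
    mutation_rate: float = 0.05,
    seed: int = 0,
    pfam_names: Sequence[str] | None = None,
    max_identity: float = 0.5,
    max_tries: int = 500,
) -> FamilyPool:
    """Rejection-sample a pool of pairwise-dissimilar family centroids.

    Each accepted centroid has global-alignment identity < ``max_identity`` to
    every previously accepted one; if a slot cannot be filled within
    ``max_tries`` draws a :class:`SeparabilityError` is raised (too many
    families for too short sequences).
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not (0 <= mutation_rate < 0.5):
        raise ValueError("mutation_rate must be in [0, 0.5)")
    lo, hi = seq_len_range
    if lo < 10 or hi < lo:
        raise ValueError(f"bad seq_len_range {seq_len_range}")
    if pfam_names is not None and len(pfam_names) != n_families:
        raise ValueError("pfam_names must have one entry per family")
    rng = np.random.default_rng(seed)
    centroids: list[str] = []
    for fam in range(n_families):
        for _ in range(max_tries):
            length = int(rng.integers(lo, hi + 1))
            cand = "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length))
            if all(pairwise_identity(cand, c)[0] < max_identity for c in centroids):
                centroids.append(cand)
                break
        else:
            raise SeparabilityError(
                f"could not place family {fam}: {n_families} families are not "
                f"separable at identity {max_identity} with lengths {seq_len_range}"
            )
    pfams = list(pfam_names) if pfam_names is not None else [f"PF9{fam:04d}" for fam in range(n_families)]
    return FamilyPool(centroids, pfams, mutation_rate, (lo, hi))


@dataclass
class GroundTruth:
    """Planted answers recorded while the corpus is generated."""

    family_of_sequence: dict[str, int]
    ecosystem_of_sample: dict[str, str]
    planted_fractions: pd.DataFrame
    realized_sensor_fraction: pd.Series
    n_unique_sequences: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "family_of_sequence": self.family_of_sequence,
            "ecosystem_of_sample": self.ecosystem_of_sample,
            "planted_fractions": {
                sample: {str(fam): float(v) for fam, v in row.items() if v > 0}
                for sample, row in self.planted_fractions.iterrows()
            },
            "realized_sensor_fraction": {k: float(v) for k, v in self.realized_sensor_fraction.items()},
            "n_unique_sequences": self.n_unique_sequences,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticCorpus:
    """Everything :func:`generate_corpus` produces, plus file writers."""

    genes: list[GeneRecord]
    proteins: dict[str, str]
    domains: list[SensorDomain]
    metadata: pd.DataFrame
    truth: GroundTruth
    hk_config: HKConfig
    pool: FamilyPool

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotations": outdir / "annotations.tsv",
            "sensors": outdir / "sensors.faa",
            "proteins": outdir / "proteins.faa",
            "metadata": outdir / "metadata.tsv",
            "truth": outdir / "ground_truth.json",
            "sensor_accs": outdir / "sensor_accessions.txt",
        }
        _io.write_annotations(self.genes, paths["annotations"])
        _io.write_sensor_fasta(self.domains, paths["sensors"])
        _io.write_fasta(sorted(self.proteins.items()), paths["proteins"])
        _io.write_metadata(self.metadata, paths["metadata"])
        self.truth.to_json(paths["truth"])
        paths["sensor_accs"].write_text("\n".join(sorted(self.hk_config.sensor_accs)) + "\n")
        return paths


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length))


def _assemble_hk(
    gene_id: str,
    metagenome_id: str,
    sensor_seqs: Sequence[str],
    sensor_accs: Sequence[str],
    copy_number: float,
    rng: np.random.Generator,
) -> tuple[GeneRecord, str, list[DomainHit]]:
    """Lay out a synthetic HK protein: sensors N-terminal, then HisKA, HATPase."""
    parts: list[str] = []
    hits: list[DomainHit] = []
    sensor_hits: list[DomainHit] = []
    pos = 1
    for seq, acc in zip(sensor_seqs, sensor_accs):
        hit = DomainHit(acc, pos, pos + len(seq) - 1)
        hits.append(hit)
        sensor_hits.append(hit)
        parts.append(seq)
        pos += len(seq)
        parts.append(_random_seq(rng, _LINKER))
        pos += _LINKER
    hits.append(DomainHit(HISKA, pos, pos + _HISKA_LEN - 1))
    parts.append(_random_seq(rng, _HISKA_LEN))
    pos += _HISKA_LEN
    parts.append(_random_seq(rng, _LINKER))
    pos += _LINKER
    hits.append(DomainHit(HATPASE, pos, pos + _HATPASE_LEN - 1))
    parts.append(_random_seq(rng, _HATPASE_LEN))
    pos += _HATPASE_LEN
    protein = "".join(parts)
    gene = GeneRecord(metagenome_id, gene_id, len(protein), hits, copy_number)
    return gene, protein, sensor_hits


def _planted_fractions(
    genes: Sequence[GeneRecord],
    family_of_domain: Mapping[str, int],
    domains: Sequence[SensorDomain],
    n_families: int,
) -> pd.DataFrame:
    """True per-sample fractional abundances under per-cluster accounting.

    A gene carrying domains from k distinct families contributes its full copy
    number to each of the k families — the same accounting the profile builder
    uses, so perfect clustering reproduces this table exactly.
    """
    fams_of_gene: dict[tuple[str, str], set[int]] = {}
    for d in domains:
        fams_of_gene.setdefault((d.metagenome_id, d.gene_id), set()).add(
            family_of_domain[d.domain_id]
        )
    totals: dict[str, float] = {}
    sums: dict[str, np.ndarray] = {}
    copy_of_gene: dict[tuple[str, str], float] = {}
    order: list[str] = []
    for g in genes:
        if g.metagenome_id not in totals:
            totals[g.metagenome_id] = 0.0
            sums[g.metagenome_id] = np.zeros(n_families)
            order.append(g.metagenome_id)
        totals[g.metagenome_id] += g.copy_number
        copy_of_gene[(g.metagenome_id, g.gene_id)] = g.copy_number
    for key, fams in fams_of_gene.items():
        for fam in fams:
            sums[key[0]][fam] += copy_of_gene[key]
    data = np.array(
        [sums[m] / totals[m] if totals[m] > 0 else sums[m] for m in order]
    ).reshape(len(order), n_families)
    return pd.DataFrame(data, index=order, columns=list(range(n_families)))


def generate_corpus(
    specs: Sequence[EcosystemSpec],
    pool: FamilyPool,
    global_seed: int = 0,
) -> SyntheticCorpus:
    """Generate annotation tables, sensor sequences, metadata and ground truth.

    Deterministic: a single PRNG seeded with ``global_seed`` drives every draw
    in a fixed order, so equal seeds give byte-identical written corpora.
    """
    if not specs:
        raise ValueError("need at least one EcosystemSpec")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("ecosystem names must be distinct")
    for s in specs:
        if len(s.cluster_weights) != pool.n_families:
            raise ValueError(
                f"ecosystem {s.name}: {len(s.cluster_weights)} weights for "
                f"{pool.n_families} families"
            )
    rng = np.random.default_rng(global_seed)
    sensor_accs = frozenset(pool.pfam_of_family)
    cfg = HKConfig(conserved_accs=DEFAULT_CONSERVED, sensor_accs=sensor_accs)
    genes: list[GeneRecord] = []
    proteins: dict[str, str] = {}
    domains: list[SensorDomain] = []
    family_of_domain: dict[str, int] = {}
    eco_of_sample: dict[str, str] = {}
    realized: dict[str, float] = {}
    meta_rows: list[dict] = []
    param_names = sorted({p for s in specs for p in (s.physical_params or {})})
    sample_counter = 0
    for spec in specs:
        support = np.flatnonzero(np.asarray(spec.cluster_weights) > 0)
        alpha = spec.dirichlet_concentration * np.asarray(spec.cluster_weights)[support]
        for _ in range(spec.n_metagenomes):
            mid = f"MG{sample_counter:05d}"
            sample_counter += 1
            eco_of_sample[mid] = spec.name
            n_bg = max(1, int(rng.poisson(spec.background_genes_mean)))
            sf = spec.sensor_fraction_mean
            n_hk = int(rng.poisson(n_bg * sf / (1.0 - sf)))
            weights = np.zeros(pool.n_families)
            if len(support) == 1:
                weights[support[0]] = 1.0
            else:
                weights[support] = rng.dirichlet(alpha)
            hk_copies = 0.0
            total_copies = 0.0
            for gi in range(n_hk):
                gene_id = f"{mid}_hk{gi:04d}"
                n_sensors = int(
                    rng.choice(_SENSOR_COUNT_VALUES, p=_SENSOR_COUNT_PROBS)
                )
                fams = [int(rng.choice(pool.n_families, p=weights)) for _ in range(n_sensors)]
                seqs = [pool.variant(f, rng) for f in fams]
                accs = [pool.pfam_of_family[f] for f in fams]
                copy = float(rng.geometric(0.5))
                gene, protein, sensor_hits = _assemble_hk(gene_id, mid, seqs, accs, copy, rng)
                genes.append(gene)
                proteins[gene_id] = protein
                for di, (hit, fam) in enumerate(zip(sensor_hits, fams)):
                    dom = SensorDomain(
                        gene_id=gene_id,
                        metagenome_id=mid,
                        domain_index=di,
                        pfam_acc=hit.pfam_acc,
                        start=hit.start,
                        end=hit.end,
                        sequence=protein[hit.start - 1 : hit.end],
                        copy_number=copy,
                    )
                    domains.append(dom)
                    family_of_domain[dom.domain_id] = fam
                hk_copies += copy
                total_copies += copy
            for gi in range(n_bg):
                gene_id = f"{mid}_bg{gi:04d}"
                length = int(rng.integers(100, 400))
                copy = float(rng.geometric(0.5))
                hits: list[DomainHit] = []
                draw = rng.random()
                if draw < 0.05:  # lone conserved domain: must NOT count as HK
                    acc = HISKA if rng.random() < 0.5 else HATPASE
                    hits = [DomainHit(acc, 1, min(_HISKA_LEN, length))]
                elif draw < 0.50:
                    hits = [DomainHit("PF00001", 1, min(50, length))]
                genes.append(GeneRecord(mid, gene_id, length, hits, copy))
                total_copies += copy
            realized[mid] = hk_copies / total_copies if total_copies else 0.0
            row: dict = {"metagenome_id": mid, "ecosystem": spec.name}
            if spec.conditions:
                labels = sorted(spec.conditions)
                probs = np.array([spec.conditions[c] for c in labels], dtype=float)
                probs = probs / probs.sum()
                row["condition"] = labels[int(rng.choice(len(labels), p=probs))]
            else:
                row["condition"] = ""
            for p in param_names:
                if spec.physical_params and p in spec.physical_params:
                    mu, sd = spec.physical_params[p]
                    row[p] = float(rng.normal(mu, sd))
                else:
                    row[p] = np.nan
            meta_rows.append(row)
    metadata = pd.DataFrame(meta_rows, columns=["metagenome_id", "ecosystem", "condition", *param_names])
    samples = list(eco_of_sample)
    planted = _planted_fractions(genes, family_of_domain, domains, pool.n_families)
    planted = planted.reindex(samples, fill_value=0.0)
    truth = GroundTruth(
        family_of_sequence=family_of_domain,
        ecosystem_of_sample=eco_of_sample,
        planted_fractions=planted,
        realized_sensor_fraction=pd.Series(realized, name="sensor_fraction").reindex(samples),
        n_unique_sequences=len({d.sequence for d in domains}),
    )
    return SyntheticCorpus(genes, proteins, domains, metadata, truth, cfg, pool)


class OverlapError(ValueError):
    """Injected domain intervals would overlap."""


def validate_nonoverlapping(hits: Iterable[DomainHit]) -> None:
    ordered = sorted(hits, key=lambda h: (h.start, h.end))
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start <= prev.end:
            raise OverlapError(
                f"hits {prev.pfam_acc}[{prev.start},{prev.end}] and "
                f"{nxt.pfam_acc}[{nxt.start},{nxt.end}] overlap"
            )


def inject_multidomain_hk(
    corpus: SyntheticCorpus,
    max_domains: int,
    seed: int = 0,
    n_genes: int = 5,
    max_protein_length: int = 5000,
) -> tuple[SyntheticCorpus, dict[str, int]]:
    """Raise some HK genes' sensor-domain counts, up to ``max_domains``.

    Mimics the heavy multi-sensor architectures seen in real HKs (up to 32
    domains on one protein).  Only genes that already carry at least one sensor
    domain are touched, so ``max_domains=1`` is a no-op.  The first rewritten
    gene reaches exactly ``max_domains``; proteins, domain lists and ground
    truth are rebuilt consistently.  Returns the new corpus and a record of
    final per-gene domain counts for the rewritten genes.

    Raises ``ValueError`` if the requested count cannot fit inside
    ``max_protein_length`` and :class:`OverlapError` if (by construction bug)
    intervals would overlap — checked explicitly after layout.
    """
    if max_domains < 1:
        raise ValueError("max_domains must be >= 1")
    need = max_domains * (corpus.pool.seq_len_range[1] + _LINKER) + _HISKA_LEN + _HATPASE_LEN + _LINKER
    if need > max_protein_length:
        raise ValueError(
            f"{max_domains} domains need up to {need} residues, exceeding the "
            f"{max_protein_length}-residue gene length limit"
        )
    rng = np.random.default_rng(seed)
    candidates = sorted(
        {(d.metagenome_id, d.gene_id) for d in corpus.domains}
    )
    current: dict[tuple[str, str], int] = {}
    for d in corpus.domains:
        key = (d.metagenome_id, d.gene_id)
        current[key] = current.get(key, 0) + 1
    candidates = [k for k in candidates if current[k] < max_domains]
    if not candidates:
        return corpus, {}
    chosen_idx = rng.choice(len(candidates), size=min(n_genes, len(candidates)), replace=False)
    chosen = [candidates[int(i)] for i in sorted(chosen_idx)]
    targets = {chosen[0]: max_domains}
    for key in chosen[1:]:
        targets[key] = int(rng.integers(current[key] + 1, max_domains + 1))

    genes = {(g.metagenome_id, g.gene_id): replace(g, domain_hits=list(g.domain_hits)) for g in corpus.genes}
    proteins = dict(corpus.proteins)
    domains = list(corpus.domains)
    family_map = dict(corpus.truth.family_of_sequence)
    dom_index: dict[tuple[str, str], list[int]] = {}
    for i, d in enumerate(domains):
        dom_index.setdefault((d.metagenome_id, d.gene_id), []).append(i)

    record: dict[str, int] = {}
    for key in chosen:
        mid, gene_id = key
        old_domains = [domains[i] for i in dom_index[key]]
        fams = [family_map[d.domain_id] for d in old_domains]
        seqs = [d.sequence for d in old_domains]
        n_extra = targets[key] - len(old_domains)
        extra_fams = [int(rng.integers(corpus.pool.n_families)) for _ in range(n_extra)]
        fams += extra_fams
        seqs += [corpus.pool.variant(f, rng) for f in extra_fams]
        accs = [corpus.pool.pfam_of_family[f] for f in fams]
        gene, protein, sensor_hits = _assemble_hk(
            gene_id, mid, seqs, accs, genes[key].copy_number, rng
        )
        validate_nonoverlapping(gene.domain_hits)
        genes[key] = gene
        proteins[gene_id] = protein
        for i in dom_index[key]:
            family_map.pop(domains[i].domain_id, None)
        new_doms = [
            SensorDomain(gene_id, mid, di, hit.pfam_acc, hit.start, hit.end,
                         protein[hit.start - 1 : hit.end], gene.copy_number)
            for di, hit in enumerate(sensor_hits)
        ]
        for i, slot in enumerate(dom_index[key]):
            domains[slot] = new_doms[i]
        domains.extend(new_doms[len(dom_index[key]):])
        for dom, fam in zip(new_doms, fams):
            family_map[dom.domain_id] = fam
        record[gene_id] = targets[key]

    new_genes = [genes[(g.metagenome_id, g.gene_id)] for g in corpus.genes]
    planted = _planted_fractions(new_genes, family_map, domains, corpus.pool.n_families)
    planted = planted.reindex(corpus.truth.planted_fractions.index, fill_value=0.0)
    truth = GroundTruth(
        family_of_sequence=family_map,
        ecosystem_of_sample=dict(corpus.truth.ecosystem_of_sample),
        planted_fractions=planted,
        realized_sensor_fraction=corpus.truth.realized_sensor_fraction.copy(),
        n_unique_sequences=len({d.sequence for d in domains}),
    )
    new_corpus = SyntheticCorpus(
        new_genes, proteins, domains, corpus.metadata.copy(), truth, corpus.hk_config, corpus.pool
    )
    return new_corpus, record


def linear_physical_target(
    planted: pd.DataFrame,
    families: Sequence[int],
    coefficients: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """A physical parameter that is linear in chosen planted-family abundances.

    Used to exercise the regression models: the target is recoverable from the
    profile matrix exactly (noise_sd=0) or approximately.
    """
    rng = np.random.default_rng(seed)
    y = np.zeros(len(planted.index))
    for fam, coef in zip(families, coefficients):
        y = y + coef * planted[fam].to_numpy()
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    return pd.Series(y, index=planted.index, name="target")
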