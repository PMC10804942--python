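"""Deduplication and identity-based clustering of sensor-domain sequences.

The clustering unit of the whole pipeline is the excised sensory domain: two
domains land in the same cluster when a global alignment of their amino-acid
sequences reaches a configurable identity and coverage.  The built-in algorithm
is greedy incremental centroid clustering in the CD-HIT / linclust tradition:
sequences are visited longest-first and each either joins the first existing
centroid it matches or founds a new cluster.  An adapter for an external
MMseqs2-style tool exposes the same assignment contract.

Identity is defined on a Needleman-Wunsch global alignment scored
match=1 / mismatch=0 / gap=-1.  Among score-optimal alignments the one with the
most matches (and, next, the most aligned residue pairs, i.e. fewest columns)
is used, which makes the value deterministic without a traceback tie-break:

    identity = matches / alignment_columns
    coverage (bidirectional) = min(pairs/len(a), pairs/len(b))

where ``pairs`` counts columns in which both sequences place a residue and
``alignment_columns = len(a) + len(b) - pairs``.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .extract import SensorDomain

COVERAGE_MODES = ("bidirectional", "target", "query")


@dataclass
class ClusterParams:
    """Identity/coverage thresholds for sensor-domain clustering.

    Defaults (identity 0.5, bidirectional coverage 0.8) are the package's
    documented defaults for desk-scale corpora and are configurable everywhere
    they are used.
    """

    min_identity: float = 0.5
    coverage_mode: str = "bidirectional"
    coverage_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError(f"min_identity {self.min_identity} outside (0, 1]")
        if not (0.0 < self.coverage_fraction <= 1.0):
            raise ValueError(f"coverage_fraction {self.coverage_fraction} outside (0, 1]")
        if self.coverage_mode not in COVERAGE_MODES:
            raise ValueError(f"coverage_mode must be one of {COVERAGE_MODES}")


@dataclass
class ClusterAssignment:
    """Partition of sequence ids into clusters with one representative each."""

    cluster_of: dict[str, str] = field(default_factory=dict)
    centroid_of: dict[str, str] = field(default_factory=dict)
    multiplicity: dict[str, list[str]] = field(default_factory=dict)

    def n_clusters(self) -> int:
        return len(self.centroid_of)

    def expand_members(self) -> dict[str, str]:
        """Map every member id (via the multiplicity map) to its cluster id."""
        full = dict(self.cluster_of)
        for unique_id, members in self.multiplicity.items():
            cluster = self.cluster_of[unique_id]
            for member in members:
                full[member] = cluster
        return full

    def validate(self) -> None:
        for cluster, rep in self.centroid_of.items():
            if self.cluster_of.get(rep) != cluster:
                raise ValueError(f"centroid {rep} is not a member of its cluster {cluster}")


def dedup(domains: Sequence[SensorDomain]) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Collapse exact duplicate sequences.

    Returns ``(unique, multiplicity)`` where ``unique`` maps the first-seen
    domain id of each distinct sequence to that sequence, and ``multiplicity``
    maps it to ALL member domain ids (itself included).  Multiplicities sum to
    the input count.
    """
    unique: dict[str, str] = {}
    by_seq: dict[str, str] = {}
    multiplicity: dict[str, list[str]] = {}
    for dom in domains:
        if not dom.sequence:
            raise ValueError(f"domain {dom.domain_id} has an empty sequence")
        rep = by_seq.get(dom.sequence)
        if rep is None:
            by_seq[dom.sequence] = dom.domain_id
            unique[dom.domain_id] = dom.sequence
            multiplicity[dom.domain_id] = [dom.domain_id]
        else:
            multiplicity[rep].append(dom.domain_id)
    return unique, multiplicity


def _align_stats(a: str, b: str) -> tuple[int, int, int]:
    """Global-alignment statistics ``(score, matches, pairs)``.

    Needleman-Wunsch with match=1, mismatch=0, gap=-1, maximising the tuple
    lexicographically.  Implemented as a single composite-integer DP: with
    K > min(len) the composite score*K^2 + matches*K + pairs orders exactly
    lexicographically because every move adds a non-negative amount to the two
    low-order fields.
    """
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        raise ValueError("cannot align an empty sequence")
    K = min(m, n) + 2
    K2 = K * K
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    # diagonal move gain: match -> K2 + K + 1, mismatch -> 1
    jidx = np.arange(n + 1, dtype=np.int64)
    prev = -K2 * jidx  # row 0: leading gaps in a
    for i in range(1, m + 1):
        gain = np.where(bv == av[i - 1], K2 + K + 1, 1).astype(np.int64)
        cand = np.empty(n + 1, dtype=np.int64)
        cand[0] = -K2 * i
        cand[1:] = np.maximum(prev[:-1] + gain, prev[1:] - K2)
        # left-gap closure: cur[j] = max_{k<=j} cand[k] - K2*(j-k)
        prev = np.maximum.accumulate(cand + K2 * jidx) - K2 * jidx
    composite = int(prev[n])
    rest, pairs = divmod(composite, K)
    score, matches = divmod(rest, K)
    return score, matches, pairs


def pairwise_identity(a: str, b: str, mode: str = "bidirectional") -> tuple[float, float]:
    """Identity and coverage of the optimal global alignment of two sequences."""
    if mode not in COVERAGE_MODES:
        raise ValueError(f"unknown coverage mode {mode!r}")
    if a == b:
        return 1.0, 1.0
    _, matches, pairs = _align_stats(a, b)
    columns = len(a) + len(b) - pairs
    identity = matches / columns
    if mode == "bidirectional":
        coverage = min(pairs / len(a), pairs / len(b))
    elif mode == "target":
        coverage = pairs / len(b)
    else:
        coverage = pairs / len(a)
    return identity, coverage


class GreedySequenceClusterer(BaseEstimator):
    """Greedy incremental centroid clustering of amino-acid sequences.

    scikit-learn-style estimator: ``fit`` takes a list of sequences (optionally
    with ids) and exposes ``labels_`` (integer cluster index per input) and
    ``centroid_indices_`` (input index of each cluster's representative).

    Sequences are visited longest-first, ties broken lexicographically by id so
    the partition is deterministic without any randomness.  Each sequence joins
    the first (oldest) centroid reaching both thresholds, else founds a new
    cluster — the representative of a cluster is therefore always at least as
    long as its members.

    Parameters
    ----------
    min_identity : float
        Minimum alignment identity to a centroid, in (0, 1].
    coverage_mode : {"bidirectional", "target", "query"}
        How alignment coverage is measured; the centroid is the target.
    coverage_fraction : float
        Minimum coverage, in (0, 1].
    """

    def __init__(
        self,
        min_identity: float = 0.5,
        coverage_mode: str = "bidirectional",
        coverage_fraction: float = 0.8,
    ):
        self.min_identity = min_identity
        self.coverage_mode = coverage_mode
        self.coverage_fraction = coverage_fraction

    def fit(self, sequences: Sequence[str], ids: Sequence[str] | None = None):
        ClusterParams(self.min_identity, self.coverage_mode, self.coverage_fraction)
        if len(sequences) == 0:
            raise ValueError("cannot cluster an empty sequence set")
        if ids is None:
            ids = [str(i) for i in range(len(sequences))]
        if len(ids) != len(sequences):
            raise ValueError("ids and sequences length mismatch")
        order = sorted(range(len(sequences)), key=lambda i: (-len(sequences[i]), ids[i]))
        centroid_indices: list[int] = []
        labels = np.empty(len(sequences), dtype=int)
        for i in order:
            seq = sequences[i]
            assigned = False
            for ci, c in enumerate(centroid_indices):
                identity, coverage = pairwise_identity(seq, sequences[c], self.coverage_mode)
                if identity >= self.min_identity and coverage >= self.coverage_fraction:
                    labels[i] = ci
                    assigned = True
                    break
            if not assigned:
                labels[i] = len(centroid_indices)
                centroid_indices.append(i)
        self.labels_ = labels
        self.centroid_indices_ = np.asarray(centroid_indices, dtype=int)
        self.n_clusters_ = len(centroid_indices)
        return self

    def fit_predict(self, sequences: Sequence[str], ids: Sequence[str] | None = None) -> np.ndarray:
        return self.fit(sequences, ids).labels_


def _assignment_from_labels(
    ids: Sequence[str],
    labels: np.ndarray,
    centroid_indices: Sequence[int],
    multiplicity: Mapping[str, list[str]] | None,
) -> ClusterAssignment:
    cluster_names = {ci: f"C{ci:06d}" for ci in range(len(centroid_indices))}
    cluster_of = {ids[i]: cluster_names[int(labels[i])] for i in range(len(ids))}
    centroid_of = {cluster_names[ci]: ids[c] for ci, c in enumerate(centroid_indices)}
    mult = {k: list(v) for k, v in multiplicity.items()} if multiplicity else {i: [i] for i in ids}
    return ClusterAssignment(cluster_of=cluster_of, centroid_of=centroid_of, multiplicity=mult)


def cluster_greedy(
    unique_seqs: Mapping[str, str],
    params: ClusterParams | None = None,
    seed: int = 0,
    multiplicity: Mapping[str, list[str]] | None = None,
) -> ClusterAssignment:
    """Cluster unique sequences with the built-in greedy algorithm.

    ``seed`` is accepted for interface symmetry with stochastic backends but the
    greedy ordering rule makes the result fully deterministic.
    """
    del seed
    params = params or ClusterParams()
    ids = list(unique_seqs)
    seqs = [unique_seqs[i] for i in ids]
    est = GreedySequenceClusterer(
        params.min_identity, params.coverage_mode, params.coverage_fraction
    ).fit(seqs, ids)
    return _assignment_from_labels(ids, est.labels_, est.centroid_indices_, multiplicity)


class ExternalToolError(RuntimeError):
    """The external clustering binary is missing or failed."""


def parse_cluster_tsv(path: str | Path) -> ClusterAssignment:
    """Parse the 2-column (representative, member) TSV dialect of MMseqs2."""
    cluster_of: dict[str, str] = {}
    reps: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            rep, member = parts
            if rep not in reps:
                reps[rep] = f"C{len(reps):06d}"
            cluster_of[member] = reps[rep]
    centroid_of = {cl: rep for rep, cl in reps.items()}
    for rep, cl in reps.items():
        cluster_of.setdefault(rep, cl)
    asn = ClusterAssignment(
        cluster_of=cluster_of,
        centroid_of=centroid_of,
        multiplicity={i: [i] for i in cluster_of},
    )
    asn.validate()
    return asn


def cluster_external(
    fasta_path: str | Path,
    params: ClusterParams | None = None,
    tool_path: str = "mmseqs",
) -> ClusterAssignment:
    """Cluster a FASTA with an external MMseqs2-compatible tool.

    Raises :class:`ExternalToolError` when the binary is unavailable — there is
    deliberately no silent fallback to the built-in algorithm, so that results
    are never attributed to the wrong backend.
    """
    params = params or ClusterParams()
    if shutil.which(tool_path) is None:
        raise ExternalToolError(f"external clustering tool not found on PATH: {tool_path!r}")
    cov_mode = {"bidirectional": "0", "target": "1", "query": "2"}[params.coverage_mode]
    with tempfile.TemporaryDirectory() as tmp:
        prefix = Path(tmp) / "clu"
        cmd = [
            tool_path, "easy-cluster", str(fasta_path), str(prefix), str(Path(tmp) / "work"),
            "--min-seq-id", str(params.min_identity),
            "--cov-mode", cov_mode, "-c", str(params.coverage_fraction),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ExternalToolError(f"{tool_path} failed: {proc.stderr[-500:]}")
        return parse_cluster_tsv(f"{prefix}_cluster.tsv")


def write_cluster_tsv(assignment: ClusterAssignment, path: str | Path) -> None:
    """Write (representative, member) rows, sorted for reproducible bytes."""
    rows = sorted(
        (assignment.centroid_of[cl], member)
        for member, cl in assignment.expand_members().items()
    )
    with open(path, "w") as fh:
        for rep, member in rows:
            fh.write(f"{rep}\t{member}\n")
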