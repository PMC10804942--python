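"""Shared fixtures: small synthetic corpora and independent oracles.

Heavy fixtures are session-scoped; every corpus is generated programmatically
with fixed seeds so the suite needs no data files.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

import sensorscape as ss
from sensorscape.profile import build_matrix, gene_totals_from_records


def nw_oracle(a: str, b: str) -> tuple[int, int, int]:
    """Reference global aligner: plain recursion maximising (score, matches, pairs).

    Match=1, mismatch=0, gap=-1; lexicographic tuple maximum.  Independent of
    the vectorised implementation under test.
    """

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> tuple[int, int, int]:
        if i == 0 and j == 0:
            return (0, 0, 0)
        best = None
        if i > 0 and j > 0:
            s, m, p = go(i - 1, j - 1)
            hit = 1 if a[i - 1] == b[j - 1] else 0
            best = (s + hit, m + hit, p + 1)
        if i > 0:
            s, m, p = go(i - 1, j)
            cand = (s - 1, m, p)
            best = cand if best is None or cand > best else best
        if j > 0:
            s, m, p = go(i, j - 1)
            cand = (s - 1, m, p)
            best = cand if best is None or cand > best else best
        return best

    return go(len(a), len(b))


def identity_oracle(a: str, b: str) -> float:
    _, matches, pairs = nw_oracle(a, b)
    return matches / (len(a) + len(b) - pairs)


def greedy_oracle(unique: dict[str, str], params: ss.ClusterParams) -> dict[str, int]:
    """Brute-force greedy clustering: full pairwise matrix first, same rule.

    Returns sequence id -> cluster index (founding order), for comparison with
    the incremental implementation's partition.
    """
    ids = sorted(unique, key=lambda i: (-len(unique[i]), i))
    pairid = {}
    for i in ids:
        for j in ids:
            if i < j:
                pairid[(i, j)] = ss.pairwise_identity(unique[i], unique[j], params.coverage_mode)
    centroids: list[str] = []
    out: dict[str, int] = {}
    for sid in ids:
        for ci, c in enumerate(centroids):
            if sid == c:
                identity, cov = 1.0, 1.0
            else:
                key = (sid, c) if sid < c else (c, sid)
                identity, cov = pairid[key]
            if identity >= params.min_identity and cov >= params.coverage_fraction:
                out[sid] = ci
                break
        else:
            out[sid] = len(centroids)
            centroids.append(sid)
    return out


@pytest.fixture(scope="session")
def pool():
    return ss.make_family_pool(5, (60, 90), mutation_rate=0.05, seed=1)


@pytest.fixture(scope="session")
def two_eco_specs():
    return [
        ss.EcosystemSpec(
            "Host-associated:Human:Large Intestine", 12, [4, 3, 1, 0, 0],
            sensor_fraction_mean=0.10, background_genes_mean=80,
            conditions={"normal": 0.6, "adenoma": 0.4},
        ),
        ss.EcosystemSpec(
            "Environmental:Aquatic:Marine", 12, [0, 0, 1, 3, 4],
            sensor_fraction_mean=0.10, background_genes_mean=80,
            physical_params={"temperature": (15.0, 3.0)},
        ),
    ]


@pytest.fixture(scope="session")
def corpus(pool, two_eco_specs):
    return ss.generate_corpus(two_eco_specs, pool, global_seed=42)


@pytest.fixture(scope="session")
def assignment(corpus):
    unique, mult = ss.dedup(corpus.domains)
    return ss.cluster_greedy(
        unique, ss.ClusterParams(0.8, "bidirectional", 0.8), multiplicity=mult
    )


@pytest.fixture(scope="session")
def matrix(corpus, assignment):
    totals = gene_totals_from_records(corpus.genes)
    return build_matrix(corpus.domains, assignment, totals, corpus.metadata)


@pytest.fixture(scope="session")
def disjoint_corpus():
    """4 ecosystems with disjoint family supports, 30 samples each."""
    pool = ss.make_family_pool(8, (60, 90), mutation_rate=0.05, seed=2)
    w = np.eye(4).repeat(2, axis=1)
    specs = [
        ss.EcosystemSpec(f"Environmental:Aquatic:Zone{i}", 30, list(w[i]),
                         sensor_fraction_mean=0.10, background_genes_mean=80)
        for i in range(4)
    ]
    return ss.generate_corpus(specs, pool, global_seed=5)


@pytest.fixture(scope="session")
def disjoint_matrix(disjoint_corpus):
    c = disjoint_corpus
    unique, mult = ss.dedup(c.domains)
    asn = ss.cluster_greedy(
        unique, ss.ClusterParams(0.8, "bidirectional", 0.8), multiplicity=mult
    )
    return build_matrix(c.domains, asn, gene_totals_from_records(c.genes), c.metadata)
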