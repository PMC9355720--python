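"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from birwrls.io import AssociationMatrix, DiseaseRecord, SimilarityMatrix
from birwrls.semantic import DiseaseDAG, build_dag


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)


def all_paths_contribution(dag: DiseaseDAG, node_factor) -> dict[str, float]:
    """Brute-force semantic contributions: max over all downward paths from
    each term to the disease of the product of per-node factors (the factor
    of every node on the path except the disease itself)."""
    children = dag.children_map()

    def paths(t):
        if t == dag.disease:
            yield [t]
            return
        for c in children.get(t, ()):  # pragma: no branch
            for tail in paths(c):
                yield [t] + tail

    out = {}
    for t in dag.nodes:
        best = 0.0
        for path in paths(t):
            v = 1.0
            for node in path[:-1]:
                v *= node_factor(node)
            best = max(best, v)
        out[t] = best if t != dag.disease else 1.0
    return out


def pairwise_auc(pos, neg) -> float:
    """O(n^2) pair-counting AUC with half-credit ties."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_disease_records(rng: np.random.Generator, n: int = 6) -> list[DiseaseRecord]:
    """Small random ontology with heavy code sharing (DAGs stay tiny)."""
    roots = ["A", "B"]
    records = []
    for i in range(n):
        codes = set()
        for _ in range(int(rng.integers(1, 3))):
            depth = int(rng.integers(1, 4))
            segs = [roots[int(rng.integers(0, len(roots)))]] + [
                str(int(rng.integers(0, 3))) for _ in range(depth - 1)
            ]
            codes.add(".".join(segs))
        records.append(DiseaseRecord(name=f"d{i}", tree_numbers=frozenset(codes)))
    return records


# ---------------------------------------------------------------------------
# small concrete fixtures


@pytest.fixture
def chain_records():
    """Disease 'a' sits at the bottom of the 3-level chain r -> p -> a;
    disease 'b' is the middle term 'p' itself."""
    return [
        DiseaseRecord(name="a", tree_numbers=frozenset({"r.p.a"})),
        DiseaseRecord(name="b", tree_numbers=frozenset({"r.p"})),
    ]


@pytest.fixture
def chain_dag(chain_records):
    return build_dag(chain_records[0], chain_records[0:1])


@pytest.fixture
def diamond_dag():
    """Two parents p1, p2 under one root r, both leading to the disease."""
    rec = DiseaseRecord(name="a", tree_numbers=frozenset({"r.p1.a", "r.p2.a"}))
    return build_dag(rec, [rec])


@pytest.fixture
def small_Y():
    return AssociationMatrix(
        ["u", "v", "w"],
        ["da", "db", "dc"],
        np.array([[1, 1, 0], [0, 1, 1], [0, 0, 0]]),
    )


@pytest.fixture
def small_Sd():
    return SimilarityMatrix(
        ["da", "db", "dc"],
        np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.4], [0.2, 0.4, 1.0]]),
    )


def random_similarity(rng: np.random.Generator, n: int) -> SimilarityMatrix:
    A = rng.random((n, n))
    S = (A + A.T) / 2
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix([f"x{i}" for i in range(n)], np.clip(S, 0, 1))
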