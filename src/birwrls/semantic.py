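"""Ontology-based disease semantic similarity.

Each disease's hierarchy DAG is reconstructed from its tree numbers by
prefix closure: the code ``C04.588.894`` contributes ancestors ``C04`` and
``C04.588``. Codes owned by a dataset disease are identified with that
disease (so a disease with several tree numbers is a single multi-parent
node); remaining codes are anonymous intermediate terms that still
participate in contribution sums and corpus frequency counts.

Three semantic-contribution recursions are supported:

SV1   decays by a fixed factor alpha per edge away from the disease.
SV2   pure information content, -log(Dags(t)/D), ignoring topology.
SV3   decays by (alpha + beta(t)) per edge, where beta is a corpus-frequency
      correction: rarer terms decay less, i.e. contribute more.

The pairwise similarity is the contribution mass of the shared terms over
the total semantic value of both diseases.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import DiseaseRecord, ModelParams, SimilarityMatrix

__all__ = [
    "DiseaseDAG",
    "ContributionTable",
    "DiseaseProfile",
    "build_dag",
    "build_corpus",
    "dag_counts",
    "sv1_contributions",
    "sv2_contribution",
    "beta_factor",
    "sv3_contributions",
    "semantic_value",
    "semantic_similarity",
    "disease_similarity_matrix",
]


@dataclass(frozen=True)
class DiseaseDAG:
    """The DAG of a disease: its ancestors (including itself) and edges.

    Node identities are disease names where some dataset disease owns the
    code, raw codes otherwise. ``disease`` is always a node and is reachable
    from every other node along parent->child edges.
    """

    disease: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.disease not in self.nodes:
            raise ValueError("disease must be one of its DAG nodes")
        for p, c in self.edges:
            if p not in self.nodes or c not in self.nodes:
                raise ValueError(f"edge ({p!r}, {c!r}) leaves the node set")
        # acyclicity + reachability of the disease from every node
        children = self.children_map()
        order: dict[str, int] = {}
        visiting: set[str] = set()

        def depth(t: str) -> int:
            if t in order:
                return order[t]
            if t in visiting:
                raise ValueError(f"cycle through {t!r} in disease DAG")
            visiting.add(t)
            if t == self.disease:
                d = 0
            else:
                kids = children.get(t, ())
                if not kids:
                    raise ValueError(
                        f"node {t!r} cannot reach the disease {self.disease!r}"
                    )
                d = 1 + min(depth(c) for c in kids)
            visiting.discard(t)
            order[t] = d
            return d

        for t in self.nodes:
            depth(t)

    def children_map(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p, c in self.edges:
            out.setdefault(p, set()).add(c)
        return out


@dataclass(frozen=True)
class ContributionTable:
    """Per-term semantic contributions to one disease, for one variant."""

    disease: str
    variant: str
    contributions: Mapping[str, float]

    def __post_init__(self) -> None:
        for t, v in self.contributions.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"contribution of {t!r} must be finite and >= 0")
        if self.variant in ("SV1", "SV3") and self.contributions.get(self.disease) != 1.0:
            raise ValueError("the disease's own contribution must be 1")


def _prefixes(code: str) -> list[str]:
    segs = code.split(".")
    return [".".join(segs[: i + 1]) for i in range(len(segs))]


def build_dag(record: DiseaseRecord, universe: Sequence[DiseaseRecord]) -> DiseaseDAG:
    """Prefix-closure DAG of one disease against the dataset's code universe."""
    owner: dict[str, str] = {}
    for rec in universe:
        for code in rec.tree_numbers:
            # deterministic tie-break if two diseases share a code
            if code not in owner or rec.name < owner[code]:
                owner[code] = rec.name

    def key(code: str) -> str:
        if code in record.tree_numbers:
            return record.name
        return owner.get(code, code)

    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for code in record.tree_numbers:
        chain = _prefixes(code)
        for c in chain:
            nodes.add(key(c))
        for parent, child in zip(chain, chain[1:]):
            kp, kc = key(parent), key(child)
            if kp != kc:
                edges.add((kp, kc))
    return DiseaseDAG(record.name, frozenset(nodes), frozenset(edges))


def build_corpus(records: Sequence[DiseaseRecord]) -> dict[str, DiseaseDAG]:
    """DAGs for every dataset disease, keyed by name."""
    return {rec.name: build_dag(rec, records) for rec in records}


def dag_counts(corpus: Mapping[str, DiseaseDAG]) -> Counter:
    """Dags(t): in how many disease DAGs each term appears (each disease once)."""
    counts: Counter = Counter()
    for dag in corpus.values():
        counts.update(dag.nodes)
    return counts


def _sweep(dag: DiseaseDAG, edge_factor) -> dict[str, float]:
    """Max-product of per-edge factors over all downward paths to the disease.

    ``edge_factor(t)`` is the multiplier applied when stepping from a node
    one level closer to the disease up to ``t``.
    """
    children = dag.children_map()
    memo: dict[str, float] = {dag.disease: 1.0}

    def value(t: str) -> float:
        if t not in memo:
            memo[t] = edge_factor(t) * max(value(c) for c in children[t])
        return memo[t]

    for t in dag.nodes:
        value(t)
    return memo


def sv1_contributions(dag: DiseaseDAG, alpha: float) -> ContributionTable:
    """Fixed-decay contributions: SV(A)=1, SV(t)=alpha * max over children."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return ContributionTable(dag.disease, "SV1", _sweep(dag, lambda t: alpha))


def sv2_contribution(term: str, dag_count: int, total_diseases: int) -> float:
    """Information content -log(Dags(t)/D), natural log."""
    if dag_count <= 0:
        raise ValueError(f"term {term!r} must occur in at least one DAG")
    if dag_count > total_diseases:
        raise ValueError("dag_count cannot exceed the number of diseases")
    return -math.log(dag_count / total_diseases)


def beta_factor(term: str, counts: Mapping[str, int], total_diseases: int) -> float:
    """Corpus-frequency correction (max_k Dags(k) - Dags(t)) / D, in [0, 1)."""
    if not counts:
        raise ValueError("empty corpus")
    return (max(counts.values()) - counts[term]) / total_diseases


def sv3_contributions(
    dag: DiseaseDAG,
    alpha: float,
    counts: Mapping[str, int],
    total_diseases: int,
    beta_at_child: bool = False,
) -> ContributionTable:
    """Frequency-corrected decay: SV(t) = (alpha + beta) * max over children.

    beta is evaluated at the node being scored by default; ``beta_at_child``
    evaluates it at the best child instead. No clamping is applied when
    alpha + beta >= 1.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    children = dag.children_map()
    memo: dict[str, float] = {dag.disease: 1.0}

    def beta(t: str) -> float:
        return beta_factor(t, counts, total_diseases)

    def value(t: str) -> float:
        if t not in memo:
            if beta_at_child:
                memo[t] = max((alpha + beta(c)) * value(c) for c in children[t])
            else:
                memo[t] = (alpha + beta(t)) * max(value(c) for c in children[t])
        return memo[t]

    for t in dag.nodes:
        value(t)
    return ContributionTable(dag.disease, "SV3", memo)


def semantic_value(table: ContributionTable) -> float:
    """SV(A): total contribution of all DAG terms to the disease."""
    return float(sum(table.contributions.values()))


@dataclass(frozen=True)
class DiseaseProfile:
    """A disease's DAG, contribution table and total semantic value."""

    dag: DiseaseDAG
    table: ContributionTable
    sv: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.sv == 0.0:
            object.__setattr__(self, "sv", semantic_value(self.table))


def semantic_similarity(a: DiseaseProfile, b: DiseaseProfile) -> float:
    """Shared-term contribution mass over total semantic value, in [0, 1]."""
    if a.table.variant != b.table.variant:
        raise ValueError("profiles built with different contribution variants")
    shared = a.dag.nodes & b.dag.nodes
    if not shared:
        return 0.0
    num = sum(a.table.contributions[t] + b.table.contributions[t] for t in shared)
    return float(num / (a.sv + b.sv))


def _profile(
    dag: DiseaseDAG,
    params: ModelParams,
    counts: Mapping[str, int],
    total: int,
) -> DiseaseProfile:
    if params.contribution_variant == "SV1":
        table = sv1_contributions(dag, params.alpha)
    elif params.contribution_variant == "SV2":
        contrib = {t: sv2_contribution(t, counts[t], total) for t in dag.nodes}
        table = ContributionTable(dag.disease, "SV2", contrib)
    else:
        table = sv3_contributions(
            dag, params.alpha, counts, total, beta_at_child=params.beta_at_child
        )
    return DiseaseProfile(dag, table)


def disease_similarity_matrix(
    records: Sequence[DiseaseRecord], params: ModelParams | None = None
) -> SimilarityMatrix:
    """Pairwise semantic similarity over the dataset's diseases.

    Computed once per unordered pair; the diagonal is forced to 1 (it equals
    1 analytically for SV1/SV3 but can differ for degenerate SV2 tables).
    """
    params = params or ModelParams()
    corpus = build_corpus(records)
    counts = dag_counts(corpus)
    total = len(records)
    profiles = [_profile(corpus[rec.name], params, counts, total) for rec in records]

    n = len(records)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = semantic_similarity(profiles[i], profiles[j])
    return SimilarityMatrix([rec.label for rec in records], values)
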