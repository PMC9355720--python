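import math

import numpy as np
import pytest

from birwrls.io import DiseaseRecord, ModelParams
from birwrls.semantic import (
    DiseaseDAG,
    beta_factor,
    build_corpus,
    build_dag,
    dag_counts,
    disease_similarity_matrix,
    semantic_similarity,
    semantic_value,
    sv1_contributions,
    sv2_contribution,
    sv3_contributions,
    DiseaseProfile,
)

from conftest import all_paths_contribution, random_disease_records


class TestBuildDag:
    def test_prefix_closure(self):
        rec = DiseaseRecord(name="x", tree_numbers=frozenset({"C04.588"}))
        dag = build_dag(rec, [rec])
        assert dag.nodes == {"C04", "x"}
        assert dag.edges == {("C04", "x")}

    def test_two_roots(self):
        rec = DiseaseRecord(name="x", tree_numbers=frozenset({"C04.588", "C08.381"}))
        dag = build_dag(rec, [rec])
        assert dag.nodes == {"C04", "C08", "x"}  # both leaves map to the disease
        assert dag.edges == {("C04", "x"), ("C08", "x")}

    def test_multi_parent_leaf(self, diamond_dag):
        parents = {p for p, c in diamond_dag.edges if c == "a"}
        assert len(parents) == 2

    def test_codes_map_to_owning_disease(self, chain_records):
        dag = build_dag(chain_records[0], chain_records)
        # "r.p" is owned by disease b, so it appears as node "b"
        assert dag.nodes == {"r", "b", "a"}

    def test_unreachable_node_rejected(self):
        with pytest.raises(ValueError):
            DiseaseDAG("a", frozenset({"a", "orphan"}), frozenset())


class TestContributions:
    def test_sv1_chain(self, chain_dag):
        table = sv1_contributions(chain_dag, 0.5).contributions
        assert table == {"a": 1.0, "r.p": 0.5, "r": 0.25}

    def test_sv1_singleton(self):
        rec = DiseaseRecord(name="a", tree_numbers=frozenset({"C04"}))
        dag = build_dag(rec, [rec])
        assert sv1_contributions(dag, 0.5).contributions == {"a": 1.0}

    def test_sv1_diamond_matches_bruteforce(self, diamond_dag):
        table = sv1_contributions(diamond_dag, 0.5).contributions
        oracle = all_paths_contribution(diamond_dag, lambda t: 0.5)
        assert table == oracle
        assert table["r"] == 0.25

    def test_sv2_values(self):
        assert sv2_contribution("t", 5, 5) == 0.0
        assert sv2_contribution("t", 2, 8) == pytest.approx(-math.log(0.25))
        assert sv2_contribution("t", 1, 100) == pytest.approx(math.log(100))
        with pytest.raises(ValueError):
            sv2_contribution("t", 0, 5)

    def test_beta_factor(self):
        counts = {"root": 4, "t": 1}
        assert beta_factor("root", counts, 4) == 0.0
        assert beta_factor("t", counts, 4) == pytest.approx(0.75)
        assert beta_factor("t", {"t": 1}, 1) == 0.0  # single-disease corpus

    def test_sv3_prescribed_betas(self, chain_dag):
        # beta(p)=0.2, beta(r)=0.4 via counts over D=10 with max count 10
        counts = {"r.p": 8, "r": 6, "a": 10, "filler": 10}
        table = sv3_contributions(chain_dag, 0.5, counts, 10).contributions
        assert table["r.p"] == pytest.approx(0.7)
        assert table["r"] == pytest.approx(0.9 * 0.7)

    def test_sv3_no_clamping_above_one(self, chain_dag):
        # alpha + beta > 1 for every node: beta = (10 - 1)/10 = 0.9
        counts = {"r.p": 1, "r": 1, "a": 1, "filler": 10}
        table = sv3_contributions(chain_dag, 0.9, counts, 10).contributions
        assert table["r.p"] == pytest.approx(0.9 + 0.9)  # beta = 9/10

    def test_sv3_reduces_to_sv1_when_beta_zero(self, diamond_dag):
        counts = {t: 3 for t in diamond_dag.nodes}  # all terms equally frequent
        sv3 = sv3_contributions(diamond_dag, 0.5, counts, 3).contributions
        sv1 = sv1_contributions(diamond_dag, 0.5).contributions
        assert sv3 == sv1


class TestSemanticValue:
    def test_chain(self, chain_dag):
        assert semantic_value(sv1_contributions(chain_dag, 0.5)) == pytest.approx(1.75)

    def test_singleton(self):
        rec = DiseaseRecord(name="a", tree_numbers=frozenset({"C04"}))
        table = sv1_contributions(build_dag(rec, [rec]), 0.5)
        assert semantic_value(table) == 1.0

    def test_diamond(self, diamond_dag):
        assert semantic_value(sv1_contributions(diamond_dag, 0.5)) == pytest.approx(2.25)


class TestSemanticSimilarity:
    def _profiles(self, records, alpha=0.5):
        corpus = build_corpus(records)
        return {
            name: DiseaseProfile(dag, sv1_contributions(dag, alpha))
            for name, dag in corpus.items()
        }

    def test_chain_pair_value(self, chain_records):
        prof = self._profiles(chain_records)
        # shared nodes {r, b}: ((0.5+1)+(0.25+0.5)) / (1.75+1.5)
        assert semantic_similarity(prof["a"], prof["b"]) == pytest.approx(2.25 / 3.25)

    def test_identical_disease_is_one(self, chain_records):
        prof = self._profiles(chain_records)
        assert semantic_similarity(prof["a"], prof["a"]) == 1.0

    def test_disjoint_dags_are_zero(self):
        records = [
            DiseaseRecord(name="a", tree_numbers=frozenset({"C01.1"})),
            DiseaseRecord(name="b", tree_numbers=frozenset({"C02.2"})),
        ]
        prof = self._profiles(records)
        assert semantic_similarity(prof["a"], prof["b"]) == 0.0


class TestMatrixAssembly:
    @pytest.mark.parametrize("variant", ["SV1", "SV2", "SV3"])
    def test_matrix_invariants(self, variant):
        rng = np.random.default_rng(11)
        records = random_disease_records(rng, n=8)
        params = ModelParams(contribution_variant=variant)
        Sd = disease_similarity_matrix(records, params)
        V = Sd.values
        assert np.allclose(V, V.T)
        assert np.allclose(np.diag(V), 1.0)
        assert V.min() >= 0 and V.max() <= 1 + 1e-12

    def test_sv3_equals_sv1_under_uniform_counts(self):
        # every disease shares the same single chain -> all Dags counts equal
        records = [
            DiseaseRecord(name=f"d{i}", tree_numbers=frozenset({"R.x"})) for i in range(3)
        ]
        s1 = disease_similarity_matrix(records, ModelParams(contribution_variant="SV1"))
        s3 = disease_similarity_matrix(records, ModelParams(contribution_variant="SV3"))
        assert np.array_equal(s1.values, s3.values)


class TestSweepOracle:
    """Sweep-based contributions equal the brute-force all-paths maximum."""

    @pytest.mark.parametrize("seed", range(20))
    def test_random_dags_sv1_sv3(self, seed):
        rng = np.random.default_rng(seed)
        records = random_disease_records(rng, n=int(rng.integers(3, 7)))
        corpus = build_corpus(records)
        counts = dag_counts(corpus)
        D = len(records)
        alpha = 0.3 + 0.4 * rng.random()
        for dag in corpus.values():
            assert len(dag.nodes) <= 12
            sv1 = sv1_contributions(dag, alpha).contributions
            assert sv1 == all_paths_contribution(dag, lambda t: alpha)
            sv3 = sv3_contributions(dag, alpha, counts, D).contributions
            oracle3 = all_paths_contribution(
                dag, lambda t: alpha + beta_factor(t, counts, D)
            )
            assert sv3 == oracle3

    def test_shared_ancestor_monotonicity(self):
        """Adding a shared anonymous ancestor to both DAGs never lowers Sd."""
        rng = np.random.default_rng(5)
        for trial in range(20):
            records = random_disease_records(rng, n=2)
            a, b = records
            a2 = DiseaseRecord(name=a.name, tree_numbers=a.tree_numbers | {"Q.qa"})
            b2 = DiseaseRecord(name=b.name, tree_numbers=b.tree_numbers | {"Q.qb"})

            def sd(recs):
                corpus = build_corpus(recs)
                profs = [
                    DiseaseProfile(corpus[r.name], sv1_contributions(corpus[r.name], 0.5))
                    for r in recs
                ]
                return semantic_similarity(profs[0], profs[1])

            assert sd([a2, b2]) >= sd([a, b]) - 1e-12
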