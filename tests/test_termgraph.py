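"""Wang similarity, term simplification, kappa network and grouping."""

import numpy as np
import pandas as pd
import pytest

from mucoseq.termgraph import (
    OntologyDAG,
    cohen_kappa,
    fuse_related_terms,
    group_terms,
    kappa_edges,
    simplify_terms,
    wang_similarity,
)


class TestDagValidation:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            OntologyDAG.from_edges([("A", "B", "is_a"), ("B", "A", "is_a")])

    def test_two_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            OntologyDAG.from_edges([("A", "R1", "is_a"), ("B", "R2", "is_a")])

    def test_unknown_relation_rejected(self):
        with pytest.raises(ValueError, match="relation"):
            OntologyDAG.from_edges([("A", "R", "regulates")])


class TestWangSimilarity:
    def test_identity_is_one(self, toy_dag):
        assert wang_similarity(toy_dag, "A", "A") == pytest.approx(1.0)

    def test_siblings_under_root_hand_value(self):
        dag = OntologyDAG.from_edges([("A", "R", "is_a"), ("B", "R", "is_a")])
        # S-values: {A:1, R:0.8} and {B:1, R:0.8}; shared = {R}
        assert wang_similarity(dag, "A", "B") == pytest.approx(1.6 / 3.6)

    def test_disjoint_branches_decrease_with_depth(self):
        # chains of depth d on both sides of the root
        sims = []
        for d in (1, 2, 3):
            edges = []
            for i in range(d):
                edges.append((f"L{i+1}", f"L{i}" if i else "R", "is_a"))
                edges.append((f"M{i+1}", f"M{i}" if i else "R", "is_a"))
            dag = OntologyDAG.from_edges(edges)
            sims.append(wang_similarity(dag, f"L{d}", f"M{d}"))
        # depth 1 reduces to the siblings case; deeper terms share only a
        # fainter root: depth 2 gives (0.64+0.64)/(2.44+2.44)
        assert sims[0] == pytest.approx(1.6 / 3.6)
        assert sims[1] == pytest.approx(1.28 / 4.88)
        assert sims[0] > sims[1] > sims[2]

    def test_symmetry_and_range(self, toy_dag):
        terms = ["A", "B", "C", "D", "E", "M1"]
        for a in terms:
            for b in terms:
                s1 = wang_similarity(toy_dag, a, b)
                s2 = wang_similarity(toy_dag, b, a)
                assert s1 == pytest.approx(s2, abs=1e-12)
                assert 0 < s1 <= 1

    def test_part_of_weight_lower(self, toy_dag):
        # D is_a A, E part_of A: E's ancestors carry weaker S-values
        assert wang_similarity(toy_dag, "D", "B") > wang_similarity(toy_dag, "E", "B")

    def test_missing_term_raises(self, toy_dag):
        with pytest.raises(KeyError):
            wang_similarity(toy_dag, "A", "nope")


class TestSimplify:
    def test_duplicate_terms_keep_most_significant(self):
        dag = OntologyDAG.from_edges([("A", "R", "is_a"), ("B", "A", "is_a")])
        # A vs A is similarity 1; feed the same term id set twice via p-map
        terms = pd.Series({"A": 0.02, "B": 0.01})
        # B is child of A: sim(A,B) = (0.8+1 ... compute: keep both unless > 0.7
        kept = simplify_terms(terms, dag, cutoff=0.7)
        sim = wang_similarity(dag, "A", "B")
        expected = ["B"] if sim > 0.7 else ["B", "A"]
        assert kept == expected

    def test_all_below_cutoff_identity(self, toy_dag):
        terms = pd.Series({"D": 0.01, "C": 0.02})
        assert set(simplify_terms(terms, toy_dag, 0.99)) == {"D", "C"}

    def test_chain_sweep(self, monkeypatch):
        """A~B and B~C redundant, A~C not: ascending-p sweep keeps {A, C}."""
        import mucoseq.termgraph as tg

        dag = OntologyDAG.from_edges(
            [("A", "R", "is_a"), ("B", "R", "is_a"), ("C", "R", "is_a")]
        )
        sims = {
            frozenset({"A", "B"}): 0.8,
            frozenset({"B", "C"}): 0.8,
            frozenset({"A", "C"}): 0.3,
        }
        monkeypatch.setattr(
            tg,
            "wang_similarity",
            lambda d, a, b, w=None: 1.0 if a == b else sims[frozenset({a, b})],
        )
        terms = pd.Series({"A": 0.01, "B": 0.02, "C": 0.03})
        assert tg.simplify_terms(terms, dag, 0.7) == ["A", "C"]

    def test_idempotent(self, toy_dag):
        terms = pd.Series({"A": 0.01, "B": 0.02, "D": 0.03, "C": 0.04})
        once = simplify_terms(terms, toy_dag, 0.4)
        twice = simplify_terms(terms.loc[once], toy_dag, 0.4)
        assert once == twice


class TestKappa:
    def test_identical_memberships(self):
        u = set("abcd")
        assert cohen_kappa({"a", "b"}, {"a", "b"}, u) == pytest.approx(1.0)

    def test_hand_zero(self):
        u = {"g1", "g2", "g3", "g4"}
        k = cohen_kappa({"g1", "g2"}, {"g1", "g3"}, u)
        assert k == pytest.approx(0.0)  # po = pe = 0.5

    def test_disjoint_halves_minus_one(self):
        u = {"g1", "g2", "g3", "g4"}
        assert cohen_kappa({"g1", "g2"}, {"g3", "g4"}, u) == pytest.approx(-1.0)

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        u = [f"g{i}" for i in range(30)]
        for _ in range(50):
            a = {g for g in u if rng.random() < 0.4}
            b = {g for g in u if rng.random() < 0.4}
            if not a or not b:
                continue
            va = [int(g in a) for g in u]
            vb = [int(g in b) for g in u]
            if len(set(va)) == 1 and len(set(vb)) == 1:
                continue
            assert cohen_kappa(a, b, set(u)) == pytest.approx(
                sk.cohen_kappa_score(va, vb), abs=1e-12
            )

    def test_random_memberships_centered_at_zero(self):
        rng = np.random.default_rng(1)
        u = [f"g{i}" for i in range(40)]
        ks = []
        for _ in range(500):
            a = {g for g in u if rng.random() < 0.5}
            b = {g for g in u if rng.random() < 0.5}
            if a and b:
                ks.append(cohen_kappa(a, b, set(u)))
        assert abs(np.mean(ks)) < 0.02
        assert all(-1 <= k <= 1 for k in ks)

    def test_edges_threshold_and_exclusion(self):
        members = {"t1": {"a", "b"}, "t2": {"a", "b"}, "t3": {"c"}, "t4": set()}
        edges = kappa_edges(members, threshold=0.2)
        pairs = set(map(tuple, edges[["term_a", "term_b"]].values))
        assert ("t1", "t2") in pairs
        assert not any("t4" in p for p in pairs)


class TestGrouping:
    def _edges(self, pairs):
        return pd.DataFrame(
            [{"term_a": a, "term_b": b, "kappa": 1.0} for a, b in pairs]
        )

    def test_clique_single_group(self):
        terms = pd.Series({"a": 0.01, "b": 0.02, "c": 0.03})
        edges = self._edges([("a", "b"), ("a", "c"), ("b", "c")])
        g = group_terms(edges, terms)
        assert g["group_label"].nunique() == 1
        assert (g["group_label"] == "a").all()

    def test_two_components_two_groups(self):
        terms = pd.Series({"a": 0.01, "b": 0.02, "x": 0.03, "y": 0.04})
        g = group_terms(self._edges([("a", "b"), ("x", "y")]), terms)
        assert g["group_label"].nunique() == 2

    def test_shared_node_triangles_merge_threshold(self):
        terms = pd.Series({t: 0.01 * (i + 1) for i, t in enumerate("abcde")})
        # two triangles a-b-c and c-d-e sharing only c
        edges = self._edges(
            [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("c", "e"), ("d", "e")]
        )
        strict = group_terms(edges, terms, merge_overlap=0.5)
        loose = group_terms(edges, terms, merge_overlap=0.2)
        assert strict["group_label"].nunique() == 2
        assert loose["group_label"].nunique() == 1

    def test_isolated_terms_singletons(self):
        terms = pd.Series({"a": 0.01, "b": 0.02, "z": 0.03})
        g = group_terms(self._edges([("a", "b")]), terms)
        assert g.loc["z", "group_label"] == "z"

    def test_order_invariance(self):
        terms = pd.Series({"a": 0.03, "b": 0.01, "c": 0.02, "d": 0.04})
        pairs = [("a", "b"), ("b", "c"), ("c", "d")]
        g1 = group_terms(self._edges(pairs), terms)
        g2 = group_terms(self._edges(pairs[::-1]), terms.iloc[::-1])
        assert g1.sort_index().equals(g2.sort_index())


class TestFusion:
    def _dag(self):
        return OntologyDAG.from_edges(
            [("P", "R", "is_a"), ("C", "P", "is_a"), ("GC", "C", "is_a"),
             ("Q", "R", "is_a")]
        )

    def test_child_with_smaller_p_retained(self):
        dag = self._dag()
        terms = pd.Series({"P": 0.02, "C": 0.01})
        members = {"P": {"g1", "g2"}, "C": {"g1", "g2"}}
        assert fuse_related_terms(terms, dag, members) == ["C"]

    def test_unrelated_terms_identity(self):
        dag = self._dag()
        terms = pd.Series({"P": 0.02, "Q": 0.01})
        members = {"P": {"g1"}, "Q": {"g1"}}
        assert set(fuse_related_terms(terms, dag, members)) == {"P", "Q"}

    def test_low_share_not_fused(self):
        dag = self._dag()
        terms = pd.Series({"P": 0.02, "C": 0.01})
        members = {"P": {"g1", "g2", "g3", "g4"}, "C": {"g4", "g5", "g6", "g7"}}
        assert set(fuse_related_terms(terms, dag, members)) == {"P", "C"}

    def test_three_term_chain_hand_walk(self):
        # GC (p=.001) fuses with C (p=.01); the surviving GC then does not
        # touch P (p=.02) because GC and P are not parent-child
        dag = self._dag()
        terms = pd.Series({"P": 0.02, "C": 0.01, "GC": 0.001})
        members = {
            "P": {"g1", "g2", "g3"},
            "C": {"g1", "g2"},
            "GC": {"g1", "g2"},
        }
        assert fuse_related_terms(terms, dag, members) == ["GC", "P"]

    def test_p_cutoff_applied_first(self):
        dag = self._dag()
        terms = pd.Series({"P": 0.04, "C": 0.001})
        members = {"P": {"g1"}, "C": {"g1"}}
        assert fuse_related_terms(terms, dag, members, p_cutoff=0.01) == ["C"]
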