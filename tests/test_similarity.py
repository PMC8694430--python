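import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import midgae as mg
from midgae.io_formats import DiseaseDag, EntityRegistry

from conftest import random_associations


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def gip_oracle(values, raw_bandwidth=1.0):
    """Double-loop GIP kernel over the rows of a binary matrix."""
    n = values.shape[0]
    rho = raw_bandwidth / np.mean([np.dot(values[i], values[i]) for i in range(n)])
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            diff = values[i] - values[j]
            out[i, j] = math.exp(-rho * float(np.dot(diff, diff)))
    return out


def nw_oracle(s1, s2, match=1.0, mismatch=0.0, gap=0.0):
    """Quadratic-space global-alignment DP with linear (end-scored) gaps."""
    n1, n2 = len(s1), len(s2)
    dp = np.zeros((n1 + 1, n2 + 1))
    for i in range(1, n1 + 1):
        dp[i][0] = i * gap
    for j in range(1, n2 + 1):
        dp[0][j] = j * gap
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            diag = dp[i - 1][j - 1] + (match if s1[i - 1] == s2[j - 1] else mismatch)
            dp[i][j] = max(diag, dp[i - 1][j] + gap, dp[i][j - 1] + gap)
    return dp[n1][n2]


def wang_oracle(dag: DiseaseDag, d1: str, d2: str, decay: float) -> float:
    """Memo-free recursive evaluation of the DAG semantic similarity."""

    def contribution(disease, term):
        if term == disease:
            return 1.0
        closure = dag.ancestor_closure(disease)
        kids = [c for c in dag.children(term) if c in closure]
        return decay * max(contribution(disease, c) for c in kids)

    t1, t2 = dag.ancestor_closure(d1), dag.ancestor_closure(d2)
    shared = t1 & t2
    if not shared:
        return 0.0
    num = sum(contribution(d1, t) + contribution(d2, t) for t in shared)
    dv1 = sum(contribution(d1, t) for t in t1)
    dv2 = sum(contribution(d2, t) for t in t2)
    return num / (dv1 + dv2)


def random_dag(rng, n_nodes=10, p_edge=0.35):
    """Random DAG via a topological order with forward edges only."""
    names = [f"n{i}" for i in range(n_nodes)]
    edges = [("n0", names[i]) for i in range(1, n_nodes)]  # keep it connected
    for i in range(1, n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                edges.append((names[i], names[j]))
    return DiseaseDag.from_edges(edges)


# ---------------------------------------------------------------------------
# GIP kernel
# ---------------------------------------------------------------------------


class TestGip:
    def test_bandwidth_hand_values(self):
        rng = np.random.default_rng(0)
        a = random_associations(rng, 2, 2)
        a = a.with_values(np.eye(2))
        assert mg.gip_bandwidth(a, "miRNA") == pytest.approx(1.0)
        assert mg.gip_bandwidth(a.with_values(np.ones((2, 2))), "miRNA") == pytest.approx(0.5)

    def test_all_zero_matrix_raises(self):
        rng = np.random.default_rng(0)
        a = random_associations(rng, 2, 2).with_values(np.zeros((2, 2)))
        with pytest.raises(ZeroDivisionError, match="no verified links"):
            mg.gip_bandwidth(a, "miRNA")

    def test_kernel_hand_value_identity_profiles(self):
        rng = np.random.default_rng(0)
        a = random_associations(rng, 2, 2).with_values(np.eye(2))
        s = mg.gip_kernel(a, "miRNA")
        assert s.values[0, 1] == pytest.approx(math.exp(-2.0), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_kernel_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_associations(rng, 6, 4)
        for axis, values in (("miRNA", a.values), ("disease", a.values.T)):
            got = mg.gip_kernel(a, axis).values
            assert np.abs(got - gip_oracle(values)).max() <= 1e-12

    def test_unit_diagonal_and_identical_profiles(self):
        rng = np.random.default_rng(1)
        a = random_associations(rng, 5, 3)
        values = a.values.copy()
        values[1] = values[0]
        s = mg.gip_kernel(a.with_values(values), "miRNA")
        assert np.all(np.diag(s.values) == 1.0)
        assert s.values[0, 1] == pytest.approx(1.0)

    def test_row_permutation_conjugates_kernel(self):
        rng = np.random.default_rng(2)
        a = random_associations(rng, 6, 4)
        perm = rng.permutation(6)
        s = mg.gip_kernel(a, "miRNA").values
        s_perm = mg.gip_kernel(a.with_values(a.values[perm]), "miRNA").values
        assert np.abs(s_perm - s[np.ix_(perm, perm)]).max() <= 1e-12


# ---------------------------------------------------------------------------
# Sequence similarity
# ---------------------------------------------------------------------------


def seq_set(seqs):
    registry = EntityRegistry.from_names("miRNA", [f"m{i}" for i in range(len(seqs))])
    return mg.SequenceSet(registry=registry, sequences=dict(zip(registry.names, seqs)))


class TestSequenceSimilarity:
    def test_identical_sequences_score_one(self):
        s = mg.sequence_similarity(seq_set(["ACGU", "ACGU"]))
        assert s.values[0, 1] == 1.0

    @pytest.mark.parametrize(
        "scoring",
        [mg.AlignmentScoring(), mg.AlignmentScoring(match=1.0, mismatch=-0.5, gap=-1.0),
         mg.AlignmentScoring(match=2.0, mismatch=0.0, gap=-0.5)],
    )
    def test_matches_dp_oracle_on_random_pairs(self, scoring):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGU"))
        for _ in range(50):
            n1, n2 = rng.integers(1, 12, size=2)
            s1 = "".join(rng.choice(bases, n1))
            s2 = "".join(rng.choice(bases, n2))
            sim = mg.sequence_similarity(seq_set([s1, s2]), scoring)
            raw = nw_oracle(s1, s2, scoring.match, scoring.mismatch, scoring.gap)
            expected = min(max(raw, 0.0) / (scoring.match * max(n1, n2)), 1.0)
            assert sim.values[0, 1] == expected
            assert sim.values[1, 0] == expected

    def test_gapped_alignment_hand_case(self):
        scoring = mg.AlignmentScoring(match=1.0, mismatch=0.0, gap=-1.0)
        s = mg.sequence_similarity(seq_set(["AAAA", "AAA"]), scoring)
        # best alignment: 3 matches + 1 end gap = 2, over max length 4
        assert s.values[0, 1] == pytest.approx(0.5)

    def test_empty_sequence_names_the_entity(self):
        with pytest.raises(ValueError, match="m1"):
            mg.sequence_similarity(seq_set(["ACGU", ""]))


# ---------------------------------------------------------------------------
# Semantic similarity
# ---------------------------------------------------------------------------


class TestSemanticSimilarity:
    def test_self_similarity_is_one_and_disjoint_is_zero(self):
        dag = DiseaseDag.from_edges([("r1", "a"), ("r2", "b")])
        reg = EntityRegistry.from_names("disease", ["a", "b"])
        s = mg.semantic_similarity(dag, registry=reg)
        assert s.values[0, 0] == 1.0
        assert s.values[0, 1] == 0.0

    def test_chain_hand_value(self):
        dag = DiseaseDag.from_edges([("root", "a"), ("a", "b")])
        reg = EntityRegistry.from_names("disease", ["a", "b"])
        s = mg.semantic_similarity(dag, mg.WangConfig(decay=0.5), registry=reg)
        assert s.values[0, 1] == pytest.approx(2.25 / 3.25, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_recursive_oracle_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        dag = random_dag(rng)
        s = mg.semantic_similarity(dag, mg.WangConfig(decay=0.5))
        names = dag.registry.names
        for i in range(len(names)):
            for j in range(i, len(names)):
                expected = wang_oracle(dag, names[i], names[j], 0.5)
                assert abs(s.values[i, j] - expected) <= 1e-12

    def test_unknown_disease_raises(self):
        dag = DiseaseDag.from_edges([("root", "a")])
        reg = EntityRegistry.from_names("disease", ["a", "zzz"])
        with pytest.raises(KeyError, match="zzz"):
            mg.semantic_similarity(dag, registry=reg)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


class TestIntegrate:
    def build(self, p, g):
        reg = EntityRegistry.from_names("miRNA", ["m1", "m2"])
        pm = np.array([[1.0, p], [p, 1.0]])
        gm = np.array([[1.0, g], [g, 1.0]])
        return (mg.SimilarityMatrix(pm, reg, "sequence"),
                mg.SimilarityMatrix(gm, reg, "gip"))

    def test_nonzero_primary_averages(self):
        p, g = self.build(0.4, 0.6)
        assert mg.integrate(p, g).values[0, 1] == pytest.approx(0.5)

    def test_zero_primary_falls_back_to_gip(self):
        p, g = self.build(0.0, 0.7)
        assert mg.integrate(p, g).values[0, 1] == pytest.approx(0.7)

    def test_unit_diagonal_is_preserved(self):
        p, g = self.build(0.2, 0.9)
        assert np.all(np.diag(mg.integrate(p, g).values) == 1.0)

    def test_registry_mismatch_raises(self):
        p, _ = self.build(0.4, 0.6)
        other = EntityRegistry.from_names("miRNA", ["x1", "x2"])
        g = mg.SimilarityMatrix(np.eye(2), other, "gip")
        with pytest.raises(ValueError, match="registries"):
            mg.integrate(p, g)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_output_bounded_by_inputs_where_primary_nonzero(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        reg = EntityRegistry.from_names("miRNA", [f"m{i}" for i in range(n)])

        def sym(raw, zero_frac=0.0):
            raw = (raw + raw.T) / 2
            raw[rng.random((n, n)) < zero_frac] = 0.0
            raw = np.minimum(raw, raw.T)
            np.fill_diagonal(raw, 1.0)
            return raw

        p = mg.SimilarityMatrix(sym(rng.random((n, n)), 0.3), reg, "sequence")
        g = mg.SimilarityMatrix(sym(rng.random((n, n))), reg, "gip")
        out = mg.integrate(p, g).values
        mask = p.values != 0
        lo = np.minimum(p.values, g.values)[mask]
        hi = np.maximum(p.values, g.values)[mask]
        assert np.all(out[mask] >= lo - 1e-12)
        assert np.all(out[mask] <= hi + 1e-12)
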