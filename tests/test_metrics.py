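"""Structural indices against definitional oracles and algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from plonet import (ModulePartition, barber_modularity, connectance,
                    optimize_modularity, weighted_nodf)
from plonet.metrics import _q_from_labels
from conftest import make_net, random_net


# ---------------------------------------------------------------------------
# independent oracles (plain loops; no shared code with the implementation)


def wnodf_oracle(w):
    """Literal weighted-NODF definition: ordered pairs with strictly
    decreasing marginal totals; overlap share of the poorer member."""
    w = np.asarray(w, dtype=float)

    def pair_sum(mat):
        totals = [sum(row) for row in mat]
        s = 0.0
        for i in range(len(mat)):
            for j in range(len(mat)):
                if i == j or totals[i] <= totals[j]:
                    continue
                cnt = sum(1 for a, b in zip(mat[i], mat[j]) if 0 < b < a)
                fill = sum(1 for b in mat[j] if b > 0)
                s += 100.0 * cnt / fill
        return s

    m, n = w.shape
    pairs = m * (m - 1) / 2 + n * (n - 1) / 2
    return (pair_sum(w.tolist()) + pair_sum(w.T.tolist())) / pairs


def exhaustive_q_oracle(w):
    """Max Barber Q over ALL set partitions of the plant+pollinator vertex
    set (restricted-growth enumeration over every vertex)."""
    w = np.asarray(w, dtype=float)
    n_r, n_c = w.shape
    n = n_r + n_c
    best = -np.inf
    # restricted growth strings enumerate set partitions of n items
    def grow(labels, max_lab):
        nonlocal best
        k = len(labels)
        if k == n:
            lab = np.asarray(labels)
            best = max(best, _q_from_labels(w, lab[:n_r], lab[n_r:]))
            return
        for lab in range(max_lab + 2):
            grow(labels + [lab], max(max_lab, lab))

    grow([0], 0)
    return best


# ---------------------------------------------------------------------------


class TestConnectance:
    @pytest.mark.parametrize("w, expected", [
        (np.eye(3), 1 / 3),
        (np.ones((2, 4)), 1.0),
        ([[2, 0, 1], [0, 3, 0]], 0.5),
    ])
    def test_examples(self, w, expected):
        assert connectance(make_net(w)) == pytest.approx(expected)

    @given(arrays(np.int_, (3, 4), elements=st.integers(0, 5)),
           st.floats(0.1, 100))
    def test_invariant_to_weight_rescaling(self, w, scale):
        if not ((w.sum(1) > 0).all() and (w.sum(0) > 0).all()):
            return
        assert connectance(make_net(w)) == pytest.approx(
            connectance(make_net(w * scale)))


class TestWeightedNodf:
    def test_all_equal_marginals_score_zero(self):
        assert weighted_nodf(make_net([[1, 1], [1, 1]])) == 0.0

    def test_perfectly_nested_scores_100(self):
        assert weighted_nodf(make_net([[3, 2, 1], [2, 1, 0], [1, 0, 0]])) == 100.0

    def test_matches_definitional_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            net = random_net(rng, int(rng.integers(2, 5)), int(rng.integers(2, 5)))
            assert weighted_nodf(net) == pytest.approx(
                wnodf_oracle(net.weights), abs=1e-9)

    @given(arrays(np.int_, (4, 4), elements=st.integers(0, 6)),
           st.permutations(range(4)), st.permutations(range(4)))
    def test_invariant_to_row_and_column_permutation(self, w, rp, cp):
        if not ((w.sum(1) > 0).all() and (w.sum(0) > 0).all()):
            return
        base = weighted_nodf(make_net(w))
        perm = weighted_nodf(make_net(w[np.ix_(list(rp), list(cp))]))
        assert perm == pytest.approx(base, abs=1e-9)


class TestBarberModularity:
    def test_single_module_is_zero(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            net = random_net(rng, 4, 5)
            part = ModulePartition({p: 0 for p in net.plant_ids},
                                   {a: 0 for a in net.pollinator_ids})
            assert barber_modularity(net, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_block_diagonal_is_half(self):
        net = make_net([[1, 1, 0, 0], [1, 1, 0, 0],
                        [0, 0, 1, 1], [0, 0, 1, 1]])
        part = ModulePartition({"p0": 0, "p1": 0, "p2": 1, "p3": 1},
                               {"a0": 0, "a1": 0, "a2": 1, "a3": 1})
        assert barber_modularity(net, part) == pytest.approx(0.5)

    def test_missing_vertex_raises(self, identity3):
        part = ModulePartition({"p0": 0, "p1": 0}, {f"a{j}": 0 for j in range(3)})
        with pytest.raises(KeyError, match="p2"):
            barber_modularity(identity3, part)


class TestOptimizeModularity:
    def test_recovers_blocks(self):
        net = make_net([[2, 3, 0, 0], [1, 1, 0, 0],
                        [0, 0, 4, 1], [0, 0, 2, 2]])
        part, q = optimize_modularity(net, seed=0)
        assert q == pytest.approx(exhaustive_q_oracle(net.weights), abs=1e-9)
        assert part.plant_modules["p0"] == part.plant_modules["p1"]
        assert part.plant_modules["p0"] != part.plant_modules["p2"]

    def test_exhaustive_matches_full_vertex_partition_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            net = random_net(rng, 3, int(rng.integers(3, 5)))
            _, q = optimize_modularity(net, method="exhaustive")
            assert q == pytest.approx(exhaustive_q_oracle(net.weights), abs=1e-9)

    def test_exhaustive_size_guard(self):
        net = make_net(np.ones((7, 7)))
        with pytest.raises(ValueError, match="exhaustive"):
            optimize_modularity(net, method="exhaustive")

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        net = random_net(rng, 6, 8)
        p1, q1 = optimize_modularity(net, seed=11)
        p2, q2 = optimize_modularity(net, seed=11)
        assert q1 == q2 and p1.assignment == p2.assignment

    def test_never_negative(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            net = random_net(rng, 3, 3)
            _, q = optimize_modularity(net, seed=0, n_restarts=2)
            assert q >= 0.0
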