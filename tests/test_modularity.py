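"""Signed modularity Q*: scoring, Louvain-type maximisation, consensus."""

import numpy as np
import pytest

from signedfcn import (
    Partition,
    SignedNetwork,
    consensus_partition,
    maximize_modularity,
    modularity_score,
    network_from_fc,
    partition_mi,
)
from signedfcn.simulate import true_partition

from conftest import random_signed_network


def score_oracle(w, aff, convention="asymmetric"):
    """Independent straight-loop evaluation of the signed modularity."""
    n = len(w)
    wp = np.clip(w, 0, None)
    wn = np.clip(-w, 0, None)
    vp, vn = wp.sum(), wn.sum()

    def layer(mat, v):
        if v == 0:
            return 0.0
        s = mat.sum(axis=1)
        total = 0.0
        for i in range(n):
            for j in range(n):
                if aff[i] == aff[j]:
                    total += mat[i, j] - s[i] * s[j] / v
        return total / v

    qp, qn = layer(wp, vp), layer(wn, vn)
    if convention == "asymmetric":
        return qp - vn / (vp + vn) * qn
    return (vp * qp - vn * qn) / (vp + vn)


def enumerate_partitions(n):
    """All set partitions of n items as restricted growth strings."""
    a = [0] * n

    def rec(i, maxv):
        if i == n:
            yield tuple(a)
            return
        for v in range(maxv + 2):
            a[i] = v
            yield from rec(i + 1, max(maxv, v))

    yield from rec(0, -1)


def brute_force_best(net, convention="asymmetric"):
    best = -np.inf
    for p in enumerate_partitions(net.n_nodes):
        q, _, _ = modularity_score(net, np.asarray(p), convention=convention)
        best = max(best, q)
    return best


class TestPartition:
    def test_canonical_relabels_by_first_appearance(self):
        assert Partition((3, 3, 1, 2, 1)).canonical() == Partition((1, 1, 2, 3, 2))

    def test_module_count(self):
        assert Partition((1, 2, 2, 3)).n_modules == 3


class TestModularityScore:
    def test_one_module_all_positive_is_zero(self):
        w = np.array([[0, 1, 0.5], [1, 0, 2.0], [0.5, 2.0, 0]])
        q, qp, qn = modularity_score(SignedNetwork(weights=w), np.array([1, 1, 1]))
        assert q == pytest.approx(0.0, abs=1e-14)
        assert qn == 0.0

    def test_two_cliques_true_partition_scores_half(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        q, _, _ = modularity_score(SignedNetwork(weights=w), np.array([1, 1, 2, 2]))
        assert q == pytest.approx(0.5, abs=1e-14)

    @pytest.mark.parametrize("convention", ["asymmetric", "symmetric"])
    def test_matches_straight_loop_oracle(self, convention):
        rng = np.random.default_rng(12)
        for _ in range(10):
            w = random_signed_network(rng, 6)
            aff = rng.integers(1, 4, size=6)
            q, _, _ = modularity_score(
                SignedNetwork(weights=w), aff, convention=convention
            )
            assert q == pytest.approx(score_oracle(w, aff, convention), abs=1e-12)

    def test_all_negative_network_reduces_to_minus_qneg(self):
        rng = np.random.default_rng(4)
        w = -np.abs(random_signed_network(rng, 5))
        aff = np.array([1, 1, 2, 2, 2])
        q, qp, qn = modularity_score(SignedNetwork(weights=w), aff)
        assert qp == 0.0
        assert q == pytest.approx(-qn, abs=1e-14)

    def test_all_zero_network_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            modularity_score(SignedNetwork(weights=np.zeros((3, 3))), np.array([1, 1, 2]))

    def test_invariant_under_uniform_rescaling(self):
        rng = np.random.default_rng(8)
        w = random_signed_network(rng, 7)
        aff = rng.integers(1, 4, size=7)
        q1, _, _ = modularity_score(SignedNetwork(weights=w), aff)
        q2, _, _ = modularity_score(SignedNetwork(weights=3.7 * w), aff)
        assert q1 == pytest.approx(q2, abs=1e-12)

    def test_separating_positive_clique_never_raises_qpos(self):
        # pulling endpoints of strongly positive within-module edges apart
        # can only lose positive within-module weight
        rng = np.random.default_rng(21)
        for _ in range(5):
            w = np.full((6, 6), -0.1)
            w[:3, :3] = 1.0
            w[3:, 3:] = 1.0
            w += rng.normal(0, 0.01, (6, 6))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            net = SignedNetwork(weights=w)
            _, qp_joined, _ = modularity_score(net, np.array([1, 1, 1, 2, 2, 2]))
            _, qp_split, _ = modularity_score(net, np.array([1, 1, 3, 2, 2, 2]))
            assert qp_split <= qp_joined


class TestMaximizeModularity:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(31)
        for trial in range(8):
            n = 5 + trial % 3
            net = SignedNetwork(weights=random_signed_network(rng, n))
            best = brute_force_best(net)
            res = maximize_modularity(net, n_restarts=50, seed=trial)
            assert res.q_star == pytest.approx(best, abs=1e-10)

    def test_returned_score_matches_rescoring(self):
        rng = np.random.default_rng(2)
        net = SignedNetwork(weights=random_signed_network(rng, 10))
        res = maximize_modularity(net, n_restarts=20, seed=0)
        q, qp, qn = modularity_score(net, res.partition)
        assert res.q_star == pytest.approx(q, abs=1e-14)
        assert res.q_pos == pytest.approx(qp, abs=1e-14)
        assert res.q_neg == pytest.approx(qn, abs=1e-14)

    def test_never_below_trivial_baselines(self):
        rng = np.random.default_rng(14)
        for trial in range(5):
            n = 8
            net = SignedNetwork(weights=random_signed_network(rng, n))
            res = maximize_modularity(net, n_restarts=10, seed=trial)
            one, _, _ = modularity_score(net, np.ones(n, dtype=int))
            singletons, _, _ = modularity_score(net, np.arange(1, n + 1))
            assert res.q_star >= one - 1e-12
            assert res.q_star >= singletons - 1e-12

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        w = random_signed_network(rng, 9)
        perm = rng.permutation(9)
        res = maximize_modularity(SignedNetwork(weights=w), n_restarts=30, seed=3)
        res_p = maximize_modularity(
            SignedNetwork(weights=w[np.ix_(perm, perm)]), n_restarts=30, seed=3
        )
        assert res_p.q_star == pytest.approx(res.q_star, abs=1e-10)
        aff = res.partition.as_array()
        expected = Partition(tuple(aff[perm])).canonical()
        assert res_p.partition == expected

    def test_recovers_planted_partition(self, default_spec, default_mean_fc):
        res = maximize_modularity(network_from_fc(default_mean_fc), n_restarts=100, seed=1)
        truth = Partition(tuple(true_partition(default_spec)))
        assert res.partition.n_modules == 6
        assert partition_mi(res.partition, truth) == pytest.approx(1.0)

    def test_restart_count_validated(self):
        net = SignedNetwork(weights=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            maximize_modularity(net, n_restarts=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(17)
        net = SignedNetwork(weights=random_signed_network(rng, 12))
        a = maximize_modularity(net, n_restarts=10, seed=5)
        b = maximize_modularity(net, n_restarts=10, seed=5)
        assert a.partition == b.partition
        assert a.q_star == b.q_star


class TestConsensusPartition:
    def test_unanimous_input_returned_unchanged(self):
        p = Partition((1, 1, 2, 2, 3))
        assert consensus_partition([p, p, p]) == p

    def test_label_names_do_not_matter(self):
        a = Partition((1, 1, 2, 2))
        b = Partition((7, 7, 3, 3))
        assert consensus_partition([a, b]) == a.canonical()

    def test_complementary_partitions_fragment(self):
        a = Partition((1, 1, 2, 2))
        b = Partition((1, 2, 1, 2))
        # co-assignment is 0.5 everywhere off-diagonal; thresholding at 0.75
        # leaves nothing, so every node becomes its own module
        result = consensus_partition([a, b], threshold=0.75)
        assert result.n_modules >= 2
        assert result == Partition((1, 2, 3, 4))

    def test_majority_structure_wins(self):
        good = Partition((1, 1, 1, 2, 2, 2))
        noisy = Partition((1, 1, 3, 2, 2, 3))
        result = consensus_partition([good, good, good, noisy], threshold=0.5, seed=1)
        assert result == good

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            consensus_partition([Partition((1, 2))], threshold=1.5)
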