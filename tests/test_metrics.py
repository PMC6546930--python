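import numpy as np
import pytest

from liquidens import (
    ConnectivitySpec,
    DegenerateDispersionError,
    IncompatibleStatesError,
    InsufficientClassDataError,
    NumericalStateError,
    SingularScatterError,
    SpikeRecord,
    build_liquid,
    discriminant_ratio,
    filtered_state,
    fisher_ratio,
    generalization_rank,
    numerical_rank,
    pairwise_separation,
    scatter_matrices,
    separation_rank,
)
from liquidens.metrics import ScatterStats
from conftest import rng_spikes


class TestFilteredState:
    def test_no_spikes_zero(self):
        x = filtered_state(SpikeRecord.empty(4, 100.0), 50.0)
        np.testing.assert_array_equal(x, np.zeros(4))

    def test_single_spike_closed_form(self):
        rec = SpikeRecord(np.array([2]), np.array([10.0]), 100.0, 4)
        x = filtered_state(rec, 40.0, tau_filter=30.0)
        assert x[2] == pytest.approx(np.exp(-(40.0 - 10.0) / 30.0))
        assert x[[0, 1, 3]].sum() == 0

    def test_two_spikes_additive(self):
        rec = SpikeRecord(np.array([0, 0]), np.array([5.0, 20.0]), 100.0, 1)
        x = filtered_state(rec, 50.0, tau_filter=30.0)
        expected = np.exp(-45.0 / 30.0) + np.exp(-30.0 / 30.0)
        assert x[0] == pytest.approx(expected)

    def test_future_spikes_excluded(self):
        rec = SpikeRecord(np.array([0]), np.array([80.0]), 100.0, 1)
        assert filtered_state(rec, 50.0)[0] == 0.0

    def test_out_of_range_time(self):
        with pytest.raises(ValueError):
            filtered_state(SpikeRecord.empty(1, 10.0), 11.0)


class TestPairwiseSeparation:
    def test_identical_zero(self):
        x = np.random.default_rng(0).random((5, 3))
        assert pairwise_separation(x, x) == 0.0

    def test_single_sample_hand(self):
        assert pairwise_separation([[1.0, 0.0]], [[0.0, 1.0]]) == pytest.approx(np.sqrt(2))

    def test_mean_of_norms(self):
        xu = np.array([[1.0, 0.0], [3.0, 0.0]])
        xv = np.zeros((2, 2))
        assert pairwise_separation(xu, xv) == pytest.approx(2.0)

    def test_shape_mismatch(self):
        with pytest.raises(IncompatibleStatesError):
            pairwise_separation(np.zeros((2, 3)), np.zeros((2, 4)))


class TestNumericalRank:
    def test_identical_columns_rank_one(self):
        col = np.arange(1.0, 6.0)
        M = np.tile(col[:, None], (1, 7))
        assert numerical_rank(M).rank == 1

    def test_identity_full_rank(self):
        assert numerical_rank(np.eye(5)).rank == 5

    def test_constructed_low_rank(self):
        rng = np.random.default_rng(0)
        M = rng.random((20, 3)) @ rng.random((3, 40))
        assert numerical_rank(M, rel_tol=1e-6).rank == 3

    def test_zero_matrix_rank_zero(self):
        assert numerical_rank(np.zeros((4, 4))).rank == 0

    def test_nonfinite_raises(self):
        M = np.ones((3, 3))
        M[0, 0] = np.inf
        with pytest.raises(NumericalStateError):
            numerical_rank(M)

    def test_column_append_monotone(self):
        rng = np.random.default_rng(1)
        M = rng.random((10, 4))
        r0 = numerical_rank(M).rank
        for _ in range(5):
            M = np.column_stack([M, rng.random(10)])
            r1 = numerical_rank(M).rank
            assert r1 >= r0
            r0 = r1


@pytest.fixture(scope="module")
def small_system():
    return build_liquid(20, ConnectivitySpec(p_in_e=50), n_inputs=10, seed=0)


class TestSystemRanks:
    def test_identical_inputs_rank_one(self, small_system):
        u = rng_spikes(10, 50.0, 300.0, seed=1)
        res = separation_rank(small_system, [u, u, u])
        assert res.rank <= 1

    def test_rank_bounded(self, small_system):
        inputs = [rng_spikes(10, 50.0, 300.0, seed=s) for s in range(6)]
        res = separation_rank(small_system, inputs)
        assert 0 <= res.rank <= min(20, 6)

    def test_zero_jitter_single_base_rank_one(self, small_system):
        u = rng_spikes(10, 50.0, 300.0, seed=2)
        res = generalization_rank(small_system, [u], sigma=0.0, m=4)
        assert res.rank <= 1

    def test_generalization_not_above_separation_on_average(self, small_system):
        bases = [rng_spikes(10, 50.0, 300.0, seed=s) for s in range(3)]
        distinct = [rng_spikes(10, 50.0, 300.0, seed=100 + s) for s in range(9)]
        r_sep = separation_rank(small_system, distinct).rank
        r_gen = generalization_rank(small_system, bases, sigma=2.0, m=9, seed=0).rank
        assert r_gen <= r_sep + 1


class TestScatterMatrices:
    def test_one_d_toy_hand_values(self):
        # class A = {0, 2}, class B = {4, 6}: mu_A=1, mu_B=5, mu_g=3
        states = np.array([[0.0], [2.0], [4.0], [6.0]])
        labels = np.array([0, 0, 1, 1])
        stats = scatter_matrices(states, labels)
        assert stats.class_means[0, 0] == pytest.approx(1.0)
        assert stats.class_means[1, 0] == pytest.approx(5.0)
        assert stats.global_mean[0] == pytest.approx(3.0)
        assert stats.tr_sb == pytest.approx(4.0)
        assert stats.tr_sw == pytest.approx(2.0)  # (n-1)-denominator covariance

    def test_samples_at_class_means_zero_sw(self):
        states = np.array([[1.0, 2.0]] * 3 + [[5.0, 5.0]] * 3)
        labels = np.array([0] * 3 + [1] * 3)
        assert scatter_matrices(states, labels).tr_sw == pytest.approx(0.0)

    def test_single_class_zero_sb(self):
        states = np.random.default_rng(0).random((6, 3))
        stats = scatter_matrices(states, np.zeros(6, dtype=int))
        assert stats.tr_sb == pytest.approx(0.0, abs=1e-12)

    def test_class_with_one_sample_raises(self):
        with pytest.raises(InsufficientClassDataError):
            scatter_matrices(np.zeros((3, 2)), np.array([0, 0, 1]))

    def test_priors_sum_to_one_and_symmetry(self):
        rng = np.random.default_rng(2)
        states = rng.random((30, 4))
        labels = rng.integers(0, 3, 30)
        stats = scatter_matrices(states, labels)
        assert stats.priors.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(stats.s_w, stats.s_w.T)
        np.testing.assert_allclose(stats.s_b, stats.s_b.T)


class TestDiscriminantRatio:
    def test_one_d_toy(self):
        states = np.array([[0.0], [2.0], [4.0], [6.0]])
        labels = np.array([0, 0, 1, 1])
        assert discriminant_ratio(scatter_matrices(states, labels)) == pytest.approx(2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        states = rng.random((20, 3))
        labels = rng.integers(0, 2, 20)
        while len(np.unique(labels)) < 2 or min(np.bincount(labels)) < 2:
            labels = rng.integers(0, 2, 20)
        dr1 = discriminant_ratio(scatter_matrices(states, labels))
        dr2 = discriminant_ratio(scatter_matrices(states * 7.3, labels))
        assert dr1 == pytest.approx(dr2)

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        states = rng.random((20, 3))
        labels = np.array([0, 1] * 10)
        shift = np.array([5.0, -2.0, 11.0])
        dr1 = discriminant_ratio(scatter_matrices(states, labels))
        dr2 = discriminant_ratio(scatter_matrices(states + shift, labels))
        assert dr1 == pytest.approx(dr2)

    def test_zero_sw_raises(self):
        states = np.array([[1.0]] * 2 + [[2.0]] * 2)
        labels = np.array([0, 0, 1, 1])
        with pytest.raises(DegenerateDispersionError):
            discriminant_ratio(scatter_matrices(states, labels))

    def test_two_pass_recomputation(self):
        # independent two-pass formula for tr(S_w), tr(S_b)
        rng = np.random.default_rng(5)
        states = rng.random((40, 6))
        labels = rng.integers(0, 4, 40)
        while min(np.bincount(labels, minlength=4)) < 2:
            labels = rng.integers(0, 4, 40)
        stats = scatter_matrices(states, labels)
        n = len(labels)
        tr_sw = tr_sb = 0.0
        mu_g = states.mean(axis=0)
        for c in np.unique(labels):
            xc = states[labels == c]
            mu_c = xc.mean(axis=0)
            prior = len(xc) / n
            tr_sw += prior * np.sum((xc - mu_c) ** 2) / (len(xc) - 1)
            tr_sb += prior * np.sum((mu_c - mu_g) ** 2)
        dr = discriminant_ratio(stats)
        assert abs(dr - tr_sb / tr_sw) < 1e-10 * abs(dr)


class TestFisherRatio:
    def test_one_d_coincides_with_dr(self):
        states = np.array([[0.0], [2.0], [4.0], [6.0]])
        labels = np.array([0, 0, 1, 1])
        stats = scatter_matrices(states, labels)
        assert fisher_ratio(stats) == pytest.approx(2.0)

    def test_zero_sb_zero(self):
        stats = ScatterStats(
            classes=np.array([0, 1]),
            priors=np.array([0.5, 0.5]),
            class_means=np.zeros((2, 2)),
            global_mean=np.zeros(2),
            s_w=np.eye(2),
            s_b=np.zeros((2, 2)),
        )
        assert fisher_ratio(stats) == 0.0

    def test_diagonal_hand_example(self):
        stats = ScatterStats(
            classes=np.array([0, 1]),
            priors=np.array([0.5, 0.5]),
            class_means=np.zeros((2, 2)),
            global_mean=np.zeros(2),
            s_w=np.diag([1.0, 2.0]),
            s_b=np.diag([2.0, 2.0]),
        )
        assert fisher_ratio(stats) == pytest.approx(3.0)

    def test_singular_sw_raises(self):
        stats = ScatterStats(
            classes=np.array([0, 1]),
            priors=np.array([0.5, 0.5]),
            class_means=np.zeros((2, 2)),
            global_mean=np.zeros(2),
            s_w=np.array([[1.0, 1.0], [1.0, 1.0]]),
            s_b=np.eye(2),
        )
        with pytest.raises(SingularScatterError):
            fisher_ratio(stats)
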