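import numpy as np
import pytest

from liquidens import (
    ClusteredTrainingPlan,
    IncompatibleStatesError,
    InsufficientDataError,
    LabeledStateSet,
    SpikeRecord,
    TrainConfig,
    accuracy,
    clustered_division,
    concatenate_states,
    extract_state,
    mlmr_classify,
    predict,
    random_division,
    train_readout,
)
from liquidens.readout import LiquidStateVector, _target_matrix


class TestExtractState:
    def test_empty_record_zero(self):
        s = extract_state(SpikeRecord.empty(5, 100.0), n_e=4)
        np.testing.assert_array_equal(s.s, np.zeros(4))

    def test_max_normalization_hand(self):
        # counts (5, 0, 2) -> (1.0, 0.0, 0.4)
        ids = [0] * 5 + [2] * 2
        times = np.linspace(10, 90, 7)
        rec = SpikeRecord.from_events(ids, times, 100.0, 3)
        s = extract_state(rec, n_e=3)
        np.testing.assert_allclose(s.s, [1.0, 0.0, 0.4])

    def test_inhibitory_spikes_excluded(self):
        rec = SpikeRecord.from_events([0, 3, 3], [1.0, 2.0, 3.0], 10.0, 4)
        s = extract_state(rec, n_e=2)
        np.testing.assert_allclose(s.s, [1.0, 0.0])

    def test_entries_in_unit_interval(self):
        rng = np.random.default_rng(0)
        rec = SpikeRecord.from_events(
            rng.integers(0, 10, 200), rng.uniform(0, 100, 200), 100.0, 10
        )
        s = extract_state(rec, n_e=8)
        assert s.s.min() >= 0.0 and s.s.max() <= 1.0

    def test_fixed_normalization(self):
        rec = SpikeRecord.from_events([0] * 10, np.linspace(1, 99, 10), 100.0, 2)
        s = extract_state(rec, n_e=2, norm="fixed", denom=20.0)
        np.testing.assert_allclose(s.s, [0.5, 0.0])


class TestConcatenateStates:
    def test_single_identity(self):
        v = LiquidStateVector(np.array([0.1, 0.9]))
        np.testing.assert_array_equal(concatenate_states([v]), v.s)

    def test_length_sums(self):
        parts = [LiquidStateVector(np.full(200, 0.5), i) for i in range(4)]
        assert concatenate_states(parts).size == 800

    def test_permutation_preserves_norm(self):
        rng = np.random.default_rng(1)
        parts = [LiquidStateVector(rng.random(5), i) for i in range(3)]
        a = concatenate_states(parts)
        b = concatenate_states(parts[::-1])
        assert not np.array_equal(a, b)
        assert np.linalg.norm(a) == pytest.approx(np.linalg.norm(b))


class TestTrainReadout:
    def _gaussian_task(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        a = rng.normal([0, 0], 0.3, (n // 2, 2))
        b = rng.normal([3, 3], 0.3, (n // 2, 2))
        states = np.vstack([a, b])
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        return LabeledStateSet(states, labels, 2)

    def test_separable_task_perfect_training_accuracy(self):
        data = self._gaussian_task()
        model = train_readout(data, TrainConfig(lr=0.5, epochs=50, batch_size=16, seed=0))
        assert accuracy(model, data) == 1.0

    def test_loss_trace_decreasing_on_average(self):
        traces = []
        for seed in range(5):
            data = self._gaussian_task(seed=seed)
            model = train_readout(
                data, TrainConfig(lr=0.2, epochs=30, batch_size=16, seed=seed)
            )
            traces.append(model.loss_trace)
        mean_trace = np.mean(traces, axis=0)
        assert np.all(np.diff(mean_trace) <= 1e-6)

    def test_no_signal_chance_accuracy(self):
        states = np.ones((40, 3))
        labels = np.array([0, 1, 2, 3] * 10)
        data = LabeledStateSet(states, labels, 4)
        model = train_readout(data, TrainConfig(epochs=20, seed=0))
        assert abs(accuracy(model, data) - 0.25) <= 0.26

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            train_readout(LabeledStateSet(np.empty((0, 2)), np.empty(0), 2))

    def test_determinism(self):
        data = self._gaussian_task()
        m1 = train_readout(data, TrainConfig(seed=3))
        m2 = train_readout(data, TrainConfig(seed=3))
        np.testing.assert_array_equal(m1.W, m2.W)

    def test_soft_targets_accepted(self):
        states = np.random.default_rng(0).random((10, 2))
        targets = np.full((10, 4), 0.25)
        model = train_readout((states, targets, 4), TrainConfig(epochs=5))
        assert model.W.shape == (4, 2)


class TestPredict:
    def test_zero_model_uniform_tiebreak(self):
        from liquidens.readout import ReadoutModel

        model = ReadoutModel(W=np.zeros((3, 2)), b=np.zeros(3))
        scores, cls = predict(model, np.array([1.0, 2.0]))
        np.testing.assert_allclose(scores, 1 / 3)
        assert cls == 0

    def test_hand_two_class(self):
        from liquidens.readout import ReadoutModel

        model = ReadoutModel(W=np.eye(2), b=np.zeros(2))
        scores, cls = predict(model, np.array([2.0, 1.0]))
        assert cls == 0
        assert scores[0] > scores[1]

    def test_scores_sum_to_one(self):
        from liquidens.readout import ReadoutModel

        rng = np.random.default_rng(0)
        model = ReadoutModel(W=rng.random((5, 4)), b=rng.random(5))
        scores, _ = predict(model, rng.random((7, 4)))
        np.testing.assert_allclose(scores.sum(axis=1), 1.0)

    def test_dimension_mismatch(self):
        from liquidens.readout import ReadoutModel

        model = ReadoutModel(W=np.zeros((2, 3)), b=np.zeros(2))
        with pytest.raises(IncompatibleStatesError):
            predict(model, np.zeros(4))


class TestRandomDivision:
    def _data(self, n):
        return LabeledStateSet(np.arange(n, dtype=float)[:, None], np.zeros(n, dtype=int), 1)

    def test_single_subset_full(self):
        data = self._data(10)
        (sub,) = random_division(data, 1, seed=0)
        assert len(sub) == 10

    def test_remainder_rule(self):
        subsets = random_division(self._data(1594), 4, seed=0)
        assert [len(s) for s in subsets] == [399, 399, 398, 398]

    @pytest.mark.parametrize("seed", range(3))
    def test_disjoint_and_covering(self, seed):
        data = self._data(37)
        subsets = random_division(data, 5, seed=seed)
        all_vals = np.concatenate([s.states[:, 0] for s in subsets])
        assert len(all_vals) == 37
        assert len(np.unique(all_vals)) == 37


class TestClusteredDivision:
    def _clusters(self, per_cluster=40, n_clusters=4, L=10, d=3, seed=0):
        rng = np.random.default_rng(seed)
        return {
            f"c{i}": LabeledStateSet(
                rng.random((per_cluster, d)),
                rng.integers(0, L, per_cluster),
                L,
            )
            for i in range(n_clusters)
        }

    def test_foreign_fraction_23_percent(self):
        clusters = self._clusters()
        plan = ClusteredTrainingPlan(n_classes=10, x_f=10.0)
        division = clustered_division(clusters, plan, seed=0)
        for tset in division.values():
            assert round(100 * tset.foreign_fraction) == 23

    def test_inhibitory_label_entries(self):
        plan = ClusteredTrainingPlan(n_classes=10)
        np.testing.assert_allclose(plan.inhibitory_label, 0.1)
        division = clustered_division(self._clusters(), plan, seed=1)
        tset = division["c0"]
        foreign_targets = tset.targets[tset.is_foreign]
        np.testing.assert_allclose(foreign_targets, 0.1)

    def test_own_targets_one_hot(self):
        plan = ClusteredTrainingPlan(n_classes=10)
        division = clustered_division(self._clusters(), plan, seed=2)
        tset = division["c1"]
        own = tset.targets[~tset.is_foreign]
        np.testing.assert_allclose(own.sum(axis=1), 1.0)
        assert np.all(own.max(axis=1) == 1.0)

    def test_x_f_zero_pure(self):
        plan = ClusteredTrainingPlan(n_classes=10, x_f=0.0)
        division = clustered_division(self._clusters(), plan, seed=3)
        for tset in division.values():
            assert not tset.is_foreign.any()

    def test_foreign_sampled_without_replacement(self):
        clusters = self._clusters(per_cluster=10, d=1)
        plan = ClusteredTrainingPlan(n_classes=10, x_f=100.0)
        division = clustered_division(clusters, plan, seed=4)
        tset = division["c0"]
        # with x_f = 100 every foreign sample appears exactly once
        assert tset.is_foreign.sum() == 30


class TestInhibitionCriterion:
    def test_foreign_scores_suppressed(self):
        # CD-trained readout: max score on foreign-cluster inputs lower than
        # on own-cluster inputs, paired over 5 seeds
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            L = 4

            def blob_set(center_shift):
                means = rng.normal(center_shift, 1.5, (L, 6))
                labels = np.repeat(np.arange(L), 15)
                states = means[labels] + rng.normal(0.0, 0.3, (60, 6))
                return LabeledStateSet(states, labels, L)

            # two clusters, each with its own class-blob geometry
            own = blob_set(0.0)
            other = blob_set(6.0)
            plan = ClusteredTrainingPlan(n_classes=L, x_f=10.0)
            division = clustered_division({"a": own, "b": other}, plan, seed=seed)
            tset = division["a"]
            model = train_readout(
                (tset.states, tset.targets, L),
                TrainConfig(lr=0.3, epochs=80, batch_size=16, seed=seed),
            )
            own_scores, _ = predict(model, own.states)
            foreign_scores, _ = predict(model, other.states)
            wins += own_scores.max(axis=1).mean() > foreign_scores.max(axis=1).mean()
        assert wins == 5


class TestMlmrClassify:
    def test_single_classifier_own_argmax(self):
        assert mlmr_classify([np.array([0.1, 0.7, 0.2])]) == 1

    def test_hand_max_example(self):
        uniform = np.full(10, 0.1)
        peaked = np.full(10, 0.01)
        peaked[3] = 0.9
        assert mlmr_classify([uniform, peaked]) == 3

    def test_all_uniform_tiebreak_class_zero(self):
        assert mlmr_classify([np.full(4, 0.25), np.full(4, 0.25)]) == 0

    def test_majority_mode(self):
        a = np.array([0.6, 0.3, 0.1])
        b = np.array([0.1, 0.8, 0.1])
        c = np.array([0.2, 0.7, 0.1])
        assert mlmr_classify([a, b, c], mode="majority") == 1

    def test_target_matrix_one_hot(self):
        t = _target_matrix(np.array([0, 2]), 3)
        np.testing.assert_array_equal(t, [[1, 0, 0], [0, 0, 1]])
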