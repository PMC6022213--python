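import numpy as np
import pytest

from preictal import (
    add_label_noise,
    balance_training_set,
    build_split_plan,
    classifier_metrics,
    compute_lambda_ran,
    label_fraction_schedule,
    poisson_predictor,
    score_predictions,
)
from preictal.classify import ClassifierOutput


class TestSplitPlan:
    def test_iteration_count_equals_preictal_blocks(self):
        assert len(build_split_plan(75, 5).iterations) == 5
        assert len(build_split_plan(10, 2).iterations) == 2

    def test_first_iteration_pattern(self):
        plan = build_split_plan(80, 4)
        it1 = plan.iterations[0]
        assert it1.val_preictal == [1]
        assert it1.train_preictal == [2, 3, 4]
        assert it1.train_interictal == list(range(2, 81))

    def test_validation_never_leaks_into_training(self):
        plan = build_split_plan(30, 6)
        for it in plan.iterations:
            assert not set(it.val_preictal) & set(it.train_preictal)
            assert not set(it.val_interictal) & set(it.train_interictal)

    def test_too_few_preictal_blocks_rejected(self):
        with pytest.raises(ValueError):
            build_split_plan(10, 1)


class TestBalancing:
    def test_majority_class_undersampled_to_parity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(420, 3))
        y = np.array([0] * 400 + [1] * 20)
        Xb, yb = balance_training_set(X, y, seed=1)
        assert (yb == 0).sum() == 20 and (yb == 1).sum() == 20

    def test_already_balanced_set_is_preserved(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        y = np.array([0] * 20 + [1] * 20)
        Xb, yb = balance_training_set(X, y, seed=0)
        assert sorted(map(tuple, Xb)) == sorted(map(tuple, X))

    def test_twenty_to_one_imbalance_becomes_one_to_one(self):
        X = np.arange(210)[:, None].astype(float)
        y = np.array([0] * 200 + [1] * 10)
        _, yb = balance_training_set(X, y, seed=3)
        assert (yb == 0).sum() == (yb == 1).sum() == 10

    def test_balancing_is_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 2))
        y = (rng.random(100) < 0.2).astype(int)
        a = balance_training_set(X, y, seed=9)[0]
        b = balance_training_set(X, y, seed=9)[0]
        assert np.array_equal(a, b)


class TestLabelFractions:
    def test_schedule_for_five_blocks(self):
        sched = label_fraction_schedule(5)
        assert len(sched) == 5  # benchmark + 4 iterations
        assert sched[0]["train_preictal"] == [1, 2, 3, 4, 5]
        it3 = sched[3]
        assert it3["train_preictal"] == [1, 2]
        assert it3["val_preictal"] == [3, 4, 5]

    def test_fractions_strictly_decreasing(self):
        fracs = [e["label_fraction"] for e in label_fraction_schedule(6)]
        assert all(b < a for a, b in zip(fracs, fracs[1:]))

    def test_two_blocks_give_one_decreasing_iteration(self):
        assert len(label_fraction_schedule(2)) == 2


class TestLabelNoise:
    def test_zero_noise_is_identity(self):
        y = np.array([0, 1, 1, 0])
        assert np.array_equal(add_label_noise(y, 0.0, seed=0), y)

    def test_full_noise_flips_everything(self):
        y = np.array([0, 1, 1, 0])
        assert np.array_equal(add_label_noise(y, 1.0, seed=0), 1 - y)

    def test_flip_fraction_concentrates_on_eta(self):
        y = np.zeros(10000, dtype=int)
        noisy = add_label_noise(y, 0.3, seed=5)
        assert abs(noisy.mean() - 0.3) < 0.02

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            add_label_noise(np.array([0, 1]), 1.5)


class TestPoissonBaseline:
    def test_worked_inter_seizure_mean(self):
        assert compute_lambda_ran([1.4, 2.3, 3.6]) == pytest.approx(1.1)

    def test_two_seizures_give_their_gap(self):
        assert compute_lambda_ran([5.0, 5.75]) == pytest.approx(0.75)

    def test_matches_brute_force_mean_of_gaps(self):
        rng = np.random.default_rng(0)
        times = np.cumsum(rng.uniform(0.5, 3.0, 20))
        expected = sum(
            times[i + 1] - times[i] for i in range(len(times) - 1)
        ) / (len(times) - 1)
        assert compute_lambda_ran(list(times)) == pytest.approx(expected)

    def test_fewer_than_two_times_rejected(self):
        with pytest.raises(ValueError):
            compute_lambda_ran([1.0])

    def test_alarm_count_concentrates_on_duration_over_lambda(self):
        counts = [len(poisson_predictor(50.0, 2.0, seed=s)) for s in range(400)]
        expected = 50.0 / 2.0
        se = np.sqrt(expected / 400)
        assert abs(np.mean(counts) - expected) < 3 * se + 0.3

    def test_long_mean_rarely_alarms(self):
        assert len(poisson_predictor(1.0, 1000.0, seed=0)) == 0

    def test_seed_determinism(self):
        a = poisson_predictor(20.0, 1.5, seed=3)
        b = poisson_predictor(20.0, 1.5, seed=3)
        assert np.array_equal(a, b)


class TestScoring:
    def test_perfect_predictions(self):
        onsets = [7200.0, 14400.0, 21600.0]
        alarms = [t - 1200.0 for t in onsets]  # 20 min before each
        score = score_predictions(alarms, onsets, total_hours=6.0)
        assert score.tpr == 1.0
        assert score.fp_per_h == 0.0
        assert score.mean_horizon_s == pytest.approx(1200.0)
        assert score.clinically_applicable

    def test_no_alarms(self):
        score = score_predictions([], [3600.0], total_hours=2.0)
        assert score.tpr == 0.0 and score.fp_per_h == 0.0

    def test_false_alarms_counted_per_hour(self):
        score = score_predictions([100.0, 200.0, 300.0], [], total_hours=2.0)
        assert score.fp_per_h == pytest.approx(1.5)
        assert not score.clinically_applicable
        assert score.false_alarm_fraction == 1.0

    def test_alarm_credited_to_single_nearest_seizure(self):
        # one alarm inside two overlapping SPH windows -> credited once
        score = score_predictions([3500.0], [3600.0, 4000.0], total_hours=2.0)
        assert score.n_true_alarms == 1
        assert score.n_false_alarms == 0
        assert score.tpr == 0.5
        assert score.horizons_s == [100.0]

    def test_alarm_at_onset_is_not_predictive(self):
        score = score_predictions([3600.0], [3600.0], total_hours=2.0)
        assert score.tpr == 0.0 and score.n_false_alarms == 1


def test_classifier_metrics_fields():
    y = np.array([0, 0, 1, 1])
    out = ClassifierOutput(
        crisp=np.array([0, 1, 1, 0]),
        soft=np.array([0.95, 0.70, 0.85, 0.60]),
        p_preictal=np.array([0.05, 0.70, 0.85, 0.40]),
        window_index=np.arange(4),
    )
    m = classifier_metrics(y, out)
    assert m["fpr"] == pytest.approx(0.5)
    assert m["fnr"] == pytest.approx(0.5)
    assert m["accuracy"] == pytest.approx(0.5)
    assert m["ambiguous_fraction"] == pytest.approx(0.5)
    assert m["error_rate"] == pytest.approx(1 - m["accuracy"])
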