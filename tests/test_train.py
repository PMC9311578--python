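"""Loss, subject splits, optimizer loop, and evaluation aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rollgait as rg
from rollgait import _lstm
from rollgait.model import ClassifierModel


class TestMseLoss:
    def test_hand_computations(self):
        assert rg.mse_loss([1, 0], [1, 0]) == 0.0
        assert rg.mse_loss([1, 0], [0.5, 0.5]) == 0.25
        assert rg.mse_loss([1], [0]) == 1.0

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=1, max_size=50))
    def test_matches_brute_force_sum(self, pairs):
        y, yh = zip(*pairs)
        brute = sum((a - b) ** 2 for a, b in pairs) / len(pairs)
        assert rg.mse_loss(y, yh) == pytest.approx(brute, abs=1e-12)

    def test_mismatch_and_empty_rejected(self):
        with pytest.raises(rg.ParameterError):
            rg.mse_loss([1, 0], [1])
        with pytest.raises(rg.ParameterError):
            rg.mse_loss([], [])


def _dataset_of(n_dogs_sound, n_dogs_lame, windows_per_dog=3, seed=0):
    rng = np.random.default_rng(seed)
    windows, labels, groups = [], [], []
    for k in range(n_dogs_sound + n_dogs_lame):
        label = int(k >= n_dogs_sound)
        for _ in range(windows_per_dog):
            windows.append(rng.normal(0, 5, 250))
            labels.append(label)
            groups.append(f"dog{k:03d}")
    return rg.WindowedDataset(np.array(windows), labels, groups)


class TestSplitByDog:
    def test_fifteen_dogs_three_validation(self):
        dataset = _dataset_of(10, 5)
        train_set, val_set = rg.split_by_dog(dataset, 0.2, seed=1)
        assert len(val_set.dog_ids) == 3
        assert len(train_set.dog_ids) == 12
        assert set(train_set.dog_ids).isdisjoint(val_set.dog_ids)

    def test_stratified_balanced(self):
        dataset = _dataset_of(5, 5)
        _, val_set = rg.split_by_dog(dataset, 0.2, seed=3)
        _, val_labels = np.unique(val_set.labels, return_counts=True)
        assert list(val_labels) == [3, 3]  # 1 sound + 1 lame dog, 3 windows each

    def test_deterministic_under_seed(self):
        dataset = _dataset_of(6, 6)
        a = rg.split_by_dog(dataset, 0.25, seed=7)[1].dog_ids
        b = rg.split_by_dog(dataset, 0.25, seed=7)[1].dog_ids
        c = rg.split_by_dog(dataset, 0.25, seed=8)[1].dog_ids
        assert a == b
        assert sorted(a) != sorted(c) or a != c

    def test_leakage_free_across_seeds(self):
        dataset = _dataset_of(4, 4)
        for seed in range(20):
            train_set, val_set = rg.split_by_dog(dataset, 0.25, seed=seed)
            assert set(train_set.dog_ids).isdisjoint(val_set.dog_ids)
            assert len(train_set) + len(val_set) == len(dataset)

    def test_too_few_dogs_rejected(self):
        dataset = _dataset_of(1, 0)
        with pytest.raises(rg.SplitError):
            rg.split_by_dog(dataset, 0.2, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(rg.ParameterError):
            rg.split_by_dog(_dataset_of(2, 2), 0.0, seed=0)


class TestClipping:
    def test_norm_bounded_after_clip(self, rng):
        grads = {k: rng.normal(0, 3, (5, 7)).astype(np.float32) for k in "abc"}
        before = _lstm.global_norm(grads)
        returned = _lstm.clip_gradients(grads, 1.0)
        assert returned == pytest.approx(before)
        assert _lstm.global_norm(grads) <= 1.0 + 1e-5

    def test_small_gradients_untouched(self, rng):
        grads = {"a": np.full((2, 2), 1e-4, dtype=np.float32)}
        _lstm.clip_gradients(grads, 1.0)
        np.testing.assert_array_equal(grads["a"], np.full((2, 2), 1e-4, np.float32))


class TestTrainLoop:
    def test_zero_epochs_is_identity(self):
        dataset = _dataset_of(2, 2, windows_per_dog=1)
        model = rg.init_model(rg.ModelConfig(num_recurrent_layers=1, hidden_units=4))
        before = model.copy_params()
        model, history = rg.train(
            model, dataset, None, rg.TrainConfig(epochs=0)
        )
        assert history.epochs_run == 0
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])

    def test_training_is_deterministic_under_seed(self):
        dataset = _dataset_of(3, 3, windows_per_dog=1)
        config = rg.TrainConfig(learning_rate=0.05, epochs=3, seed=5,
                                early_stopping_patience=None)
        outs = []
        for _ in range(2):
            model = rg.init_model(
                rg.ModelConfig(num_recurrent_layers=1, hidden_units=8,
                               dropout_fraction=0.0, seed=2)
            )
            model, history = rg.train(model, dataset, None, config)
            outs.append((history.train_loss, model.predict_proba(dataset.windows[0])))
        assert outs[0] == outs[1]

    def test_memorizes_single_lame_window(self):
        params = rg.GaitSimParams(
            asymmetry_ratio=0.4, noise_sd=0.0, artifact_rate=0.0, n_samples=250, seed=3
        )
        lame = rg.simulate_trace(params, lame=True, dog_id="d0")
        sound = rg.simulate_trace(params, lame=False, dog_id="d1")
        dataset = rg.WindowedDataset(
            np.stack([lame.values, sound.values]), [1, 0], ["d0", "d1"]
        )
        model = rg.init_model(
            rg.ModelConfig(num_recurrent_layers=1, hidden_units=16,
                           dropout_fraction=0.0, seed=1)
        )
        config = rg.TrainConfig(learning_rate=0.02, epochs=200, batch_size=2,
                                early_stopping_patience=None, seed=1)
        model, history = rg.train(model, dataset, None, config)
        assert model.predict_proba(lame.values) > 0.9
        assert model.predict_proba(sound.values) < 0.1

    def test_non_finite_input_raises_training_error(self):
        dataset = _dataset_of(2, 2, windows_per_dog=1)
        dataset.windows[0, 0] = np.inf
        model = rg.init_model(rg.ModelConfig(num_recurrent_layers=1, hidden_units=4))
        with pytest.raises(rg.TrainingError, match="epoch"):
            rg.train(model, dataset, None, rg.TrainConfig(epochs=2))

    def test_empty_train_set_rejected(self):
        dataset = _dataset_of(2, 2, windows_per_dog=1).subset(np.zeros(4, dtype=bool))
        model = rg.init_model(rg.ModelConfig(num_recurrent_layers=1, hidden_units=4))
        with pytest.raises(rg.ParameterError):
            rg.train(model, dataset, None, rg.TrainConfig())

    def test_history_records_validation_curves(self, tiny_trained):
        history = tiny_trained["history"]
        assert history.epochs_run >= 1
        assert len(history.val_loss) == history.epochs_run
        assert len(history.val_accuracy) == history.epochs_run
        assert all(l >= 0 for l in history.train_loss)
        frame = history.to_dataframe()
        assert list(frame["epoch"]) == list(range(1, history.epochs_run + 1))


def _heldout_accuracy(asymmetry: float, seed: int) -> float:
    """Train a small model on a fresh cohort; return held-out dog accuracy."""
    ss = np.random.SeedSequence((seed, int(asymmetry * 100))).generate_state(
        4, dtype=np.uint32
    )
    params = rg.GaitSimParams(
        asymmetry_ratio=asymmetry, noise_sd=1.0, artifact_rate=0.01,
        n_samples=400, seed=int(ss[0]) % 2**31,
    )
    cohort = rg.simulate_cohort(10, 10, 2, params)
    dataset = rg.build_dataset(cohort)
    train_set, val_set = rg.split_by_dog(dataset, 0.2, seed=int(ss[1]) % 2**31)
    model = rg.init_model(
        rg.ModelConfig(num_recurrent_layers=1, hidden_units=32,
                       dropout_fraction=0.2, seed=int(ss[2]) % 2**31)
    )
    config = rg.TrainConfig(learning_rate=0.02, epochs=40, batch_size=3,
                            early_stopping_patience=6, seed=int(ss[3]) % 2**31)
    model, _ = rg.train(model, train_set, val_set, config)
    return rg.evaluate(model, val_set).dog_accuracy


def test_milder_asymmetry_is_not_easier():
    """Mean held-out accuracy at asymmetry 0.5 >= accuracy at 0.9 (5 seeds)."""
    clear = np.mean([_heldout_accuracy(0.5, s) for s in range(1, 6)])
    subtle = np.mean([_heldout_accuracy(0.9, s) for s in range(1, 6)])
    assert clear >= subtle


class _StubModel(ClassifierModel):
    """Returns the window's first value as its probability (test double)."""

    def __init__(self):
        super().__init__(rg.ModelConfig(num_recurrent_layers=1, hidden_units=1,
                                        sequence_length=3), {})

    def predict_proba_batch(self, windows, **kwargs):
        return np.asarray(windows, dtype=float)[:, 0]


def _stub_dataset(dog_probs, dog_labels):
    windows, labels, groups = [], [], []
    for k, (probs, label) in enumerate(zip(dog_probs, dog_labels)):
        for p in probs:
            windows.append([p, 0.0, 0.0])
            labels.append(label)
            groups.append(f"dog{k}")
    return rg.WindowedDataset(np.array(windows), labels, groups)


class TestEvaluate:
    def test_perfect_predictions(self):
        dataset = _stub_dataset([[0.9, 0.8], [0.1, 0.2]], [1, 0])
        report = rg.evaluate(_StubModel(), dataset)
        assert report.window_accuracy == 1.0
        assert report.dog_accuracy == 1.0
        assert (report.tp, report.fp, report.tn, report.fn) == (1, 0, 1, 0)

    def test_all_half_probabilities_tie_to_lame(self):
        dataset = _stub_dataset([[0.5], [0.5], [0.5], [0.5]], [1, 1, 0, 0])
        report = rg.evaluate(_StubModel(), dataset)
        assert report.dog_predictions == [1, 1, 1, 1]
        assert report.dog_accuracy == 0.5  # the lame fraction
        assert (report.tp, report.fp, report.tn, report.fn) == (2, 2, 0, 0)

    def test_six_of_seven_dogs_correct(self):
        probs = [[0.9], [0.95], [0.8], [0.1], [0.2], [0.3], [0.7]]
        labels = [1, 1, 1, 0, 0, 0, 0]  # last dog misclassified as lame
        report = rg.evaluate(_StubModel(), _stub_dataset(probs, labels))
        assert report.dog_accuracy == pytest.approx(6 / 7)
        assert report.tp + report.fp + report.tn + report.fn == 7

    def test_window_mean_aggregation_per_dog(self):
        dataset = _stub_dataset([[0.2, 0.8]], [1])  # mean 0.5 -> lame by tie
        report = rg.evaluate(_StubModel(), dataset)
        assert report.dog_probs == [pytest.approx(0.5)]
        assert report.dog_predictions == [1]

    def test_mse_matches_direct_computation(self):
        dataset = _stub_dataset([[0.25], [0.75]], [0, 1])
        report = rg.evaluate(_StubModel(), dataset)
        assert report.mse_loss == pytest.approx((0.25**2 + 0.25**2) / 2)

    def test_empty_dataset_rejected(self):
        dataset = _dataset_of(2, 2, windows_per_dog=1).subset(np.zeros(4, dtype=bool))
        with pytest.raises(rg.ParameterError):
            rg.evaluate(_StubModel(), dataset)

    def test_threshold_override(self):
        dataset = _stub_dataset([[0.6]], [1])
        assert rg.evaluate(_StubModel(), dataset, threshold=0.7).dog_predictions == [0]
        assert rg.evaluate(_StubModel(), dataset, threshold=0.5).dog_predictions == [1]
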