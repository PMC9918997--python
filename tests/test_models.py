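"""Model construction, early stopping semantics, training protocol."""

from dataclasses import replace

import numpy as np
import pytest

from shoulderload.datasets import SubtrialSample, fit_standardizer
from shoulderload.models import (
    EarlyStopper,
    ModelConfig,
    build_model,
    count_parameters,
    predict,
    run_iterations,
    train_model,
)


def reference_early_stopping(losses, patience, max_epochs):
    """Independent reference for patience-based stopping: returns the
    (1-based) stop epoch and best epoch for a given validation-loss
    schedule."""
    best, best_epoch, since = np.inf, 0, 0
    for epoch, loss in enumerate(losses[:max_epochs], start=1):
        if loss < best:
            best, best_epoch, since = loss, epoch, 0
        else:
            since += 1
        if since >= patience:
            return epoch, best_epoch
    return min(len(losses), max_epochs), best_epoch


def run_stopper(losses, patience=6, max_epochs=200):
    stopper = EarlyStopper(patience)
    for epoch, loss in enumerate(losses[:max_epochs], start=1):
        if stopper.update(epoch, loss):
            return epoch, stopper.best_epoch
    return min(len(losses), max_epochs), stopper.best_epoch


class TestModelConstruction:
    def test_linear_parameter_count_closed_form(self):
        # 20*250+250 + 250*100+100 + 100*3+3
        model = build_model(ModelConfig(architecture="linear"), n_inputs=20)
        assert count_parameters(model) == 30653

    def test_bilstm_first_layer_width_difference(self):
        """Widening the input from 20 to 32 adds exactly
        2 directions x 4 gates x 128 units x 12 inputs parameters."""
        cfg = ModelConfig(architecture="bilstm")
        n32 = count_parameters(build_model(cfg, n_inputs=32))
        n20 = count_parameters(build_model(cfg, n_inputs=20))
        assert n32 - n20 == 2 * 4 * 128 * 12

    def test_output_dimension_is_three(self, rng):
        for arch in ("bilstm", "linear"):
            cfg = replace(ModelConfig(architecture=arch), bilstm_units=4)
            model = build_model(cfg, n_inputs=6)
            x = rng.standard_normal((2, 9, 6))
            out = model.forward(x, np.array([9, 9]))
            assert out.shape == (2, 9, 3)

    def test_same_seed_identical_initial_parameters(self):
        cfg = ModelConfig(architecture="bilstm", bilstm_units=8, seed=5)
        a = build_model(cfg, n_inputs=6)
        b = build_model(cfg, n_inputs=6)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa, pb)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError, match="architecture"):
            ModelConfig(architecture="transformer")

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)
        with pytest.raises(ValueError):
            ModelConfig(patience=0)
        with pytest.raises(ValueError):
            ModelConfig(patience=300, max_epochs=200)


class TestEarlyStopping:
    def test_plateau_schedule_stops_after_patience(self):
        losses = [5, 4, 4.1, 4.2, 4.3, 4.4, 4.5, 4.6]
        stop, best = run_stopper(losses)
        assert (stop, best) == (8, 2)

    def test_monotone_decreasing_runs_to_max_epochs(self):
        losses = list(np.linspace(5, 1, 300))
        stop, best = run_stopper(losses, max_epochs=200)
        assert stop == 200
        assert best == 200

    def test_matches_reference_on_random_schedules(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 60))
            losses = rng.uniform(0.5, 5.0, n).tolist()
            assert run_stopper(losses, patience=6, max_epochs=50) == \
                reference_early_stopping(losses, patience=6, max_epochs=50)

    def test_improvement_resets_patience(self):
        losses = [5, 4.9, 4.9, 4.9, 4.0, 4.5, 4.5, 4.5, 4.5, 4.5, 3.9]
        stop, best = run_stopper(losses, patience=6)
        assert stop == 11
        assert best == 11


def _toy_samples(rng, n_sequences=6, n=40, c=5, noise=0.0):
    """Smooth sinusoid inputs whose target is a fixed linear+rectified map."""
    samples = []
    w = rng.standard_normal((c, 3))
    for k in range(n_sequences):
        t = np.arange(n) / 25.0
        phases = rng.uniform(0, 2 * np.pi, c)
        freqs = rng.uniform(0.3, 1.5, c)
        X = np.sin(2 * np.pi * freqs[None, :] * t[:, None] + phases[None, :])
        Y = X @ w + 0.5 * np.maximum(X[:, :3], 0) + noise * rng.standard_normal((n, 3))
        samples.append(SubtrialSample(1, "desk_work", k, X, Y, [f"c{i}" for i in range(c)]))
    return samples


@pytest.fixture(scope="module")
def toy_training():
    rng = np.random.default_rng(77)
    samples = _toy_samples(rng, n_sequences=8, n=60, c=4)
    # noise-free task: dropout off, early stopping effectively disabled
    cfg = ModelConfig(architecture="bilstm", bilstm_units=16, dropout=0.0,
                      max_epochs=150, patience=149, batch_size=2,
                      learning_rate=2e-3, seed=3)
    st = fit_standardizer(samples[:6])
    trained = train_model(samples[:6], samples[6:], st, cfg)
    return samples, trained


class TestTraining:
    def test_noise_free_task_reaches_low_train_loss(self, toy_training):
        _, trained = toy_training
        assert trained.train_loss[-1] < 0.05

    def test_history_and_best_epoch_consistency(self, toy_training):
        _, trained = toy_training
        assert len(trained.val_loss) <= trained.config.max_epochs
        assert trained.best_epoch == int(np.argmin(trained.val_loss)) + 1

    def test_prediction_shape_and_determinism(self, toy_training):
        samples, trained = toy_training
        sample = samples[-1]
        a = predict(trained, sample)
        b = predict(trained, sample)
        assert a.shape == (sample.n_samples, 3)
        np.testing.assert_array_equal(a, b)

    def test_save_load_round_trip(self, toy_training, tmp_path):
        from shoulderload.models import load_model, save_model

        samples, trained = toy_training
        save_model(trained, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        assert back.best_epoch == trained.best_epoch
        assert back.config == trained.config
        np.testing.assert_array_equal(predict(back, samples[-1]), predict(trained, samples[-1]))

    def test_prediction_width_mismatch_rejected(self, toy_training):
        samples, trained = toy_training
        s = samples[0]
        bad = SubtrialSample(1, "desk_work", 0, s.X[:, :3], s.Y, s.columns[:3])
        with pytest.raises(ValueError, match="columns"):
            predict(trained, bad)

    def test_seed_determinism_of_training(self):
        rng = np.random.default_rng(5)
        samples = _toy_samples(rng, n_sequences=5, n=30)
        cfg = ModelConfig(architecture="linear", max_epochs=10, patience=5, seed=9)
        st = fit_standardizer(samples[:4])
        a = train_model(samples[:4], samples[4:], st, cfg)
        b = train_model(samples[:4], samples[4:], st, cfg)
        assert a.best_epoch == b.best_epoch
        np.testing.assert_array_equal(a.val_loss, b.val_loss)

    def test_run_iterations_counts_and_degenerate_case(self):
        rng = np.random.default_rng(6)
        samples = _toy_samples(rng, n_sequences=5, n=25)
        cfg = ModelConfig(architecture="linear", max_epochs=3, patience=2, seed=1)
        st = fit_standardizer(samples[:4])
        two = run_iterations(samples[:4], samples[4:], st, cfg, n_iter=2)
        assert len(two) == 2
        assert two[0].config.seed != two[1].config.seed
        one = run_iterations(samples[:4], samples[4:], st, cfg, n_iter=1)
        assert len(one) == 1
        with pytest.raises(ValueError):
            run_iterations(samples[:4], samples[4:], st, cfg, n_iter=0)

    def test_empty_sets_rejected(self):
        rng = np.random.default_rng(2)
        samples = _toy_samples(rng, n_sequences=2, n=20)
        st = fit_standardizer(samples)
        cfg = ModelConfig(architecture="linear")
        with pytest.raises(ValueError):
            train_model([], samples, st, cfg)
        with pytest.raises(ValueError):
            train_model(samples, [], st, cfg)
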