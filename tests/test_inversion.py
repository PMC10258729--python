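"""Log-normalization, MLP training, prediction and persistence."""

import numpy as np
import pytest

from swirdos.inversion import (
    InverseModel,
    NormStats,
    evaluate_recovery,
    log_normalize,
    train,
)


def toy_problem(n=400, width=6, seed=0):
    """A smooth, identifiable inverse problem shaped like the real one:
    log-reflectance is a shared per-sample amplitude (scattering-like)
    minus a water-dependent attenuation with channel-specific slope."""
    rng = np.random.default_rng(seed)
    water = rng.uniform(0.0, 100.0, n)
    lipid = 100.0 - water
    amplitude = rng.normal(0.0, 0.3, n)  # shared across channels
    slopes = np.linspace(0.5, 2.0, width)
    log_rd = -6.0 + amplitude[:, None] - np.outer(water / 100.0, slopes)
    labels = np.column_stack([water, lipid])
    return np.exp(log_rd), labels


class TestLogNormalize:
    def test_fitted_stats_give_zero_mean_unit_sd(self):
        rd, _ = toy_problem()
        z, stats = log_normalize(rd)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0), 1.0, rtol=1e-12)

    def test_round_trip_recovers_inputs(self):
        rd, _ = toy_problem()
        z, stats = log_normalize(rd)
        back = np.exp(z * stats.sd + stats.mean)
        np.testing.assert_allclose(back, rd, rtol=1e-10)

    def test_constant_channel_sd_floor(self):
        x = np.column_stack([np.full(10, 2.0), np.linspace(1, 2, 10)])
        z, stats = log_normalize(x)
        assert stats.sd[0] > 0
        assert np.all(np.isfinite(z))

    def test_nonpositive_rd_rejected(self):
        with pytest.raises(ValueError):
            log_normalize(np.array([[1.0, -0.1]]))

    def test_apply_supplied_stats(self):
        rd, _ = toy_problem()
        _, stats = log_normalize(rd)
        z2 = log_normalize(rd[:5], stats)
        np.testing.assert_allclose(
            z2, (np.log(rd[:5]) - stats.mean) / stats.sd, rtol=1e-12
        )


class TestTraining:
    def test_overfits_tiny_noiseless_set(self):
        """Capacity check: 10 noiseless samples are fit to near-zero loss."""
        rd, labels = toy_problem(n=10)
        model = InverseModel(rd.shape[1], seed=0)
        report = train(model, rd, labels, epochs=4000, batch_size=10,
                       seed=1, early_stopping=False)
        assert report.loss[-1] < 1e-5

    def test_long_run_loss_trend_decreases(self):
        rd, labels = toy_problem(n=500)
        model = InverseModel(rd.shape[1], seed=0)
        report = train(model, rd, labels, epochs=500, seed=1, early_stopping=False)
        assert np.mean(report.loss[-200:]) < np.mean(report.loss[:200])

    def test_early_stopping_halts_on_plateaued_loss(self):
        """With noisy labels the loss floors at the label-noise level and the
        200-epoch moving-average rule halts training before the budget."""
        rng = np.random.default_rng(5)
        rd, labels = toy_problem(n=200)
        noisy_labels = labels + rng.normal(0.0, 5.0, labels.shape)
        model = InverseModel(rd.shape[1], seed=0)
        report = train(model, rd, noisy_labels, epochs=5000, batch_size=64,
                       seed=1, early_stopping=True)
        assert report.epochs_run < 5000
        assert "stopped decreasing" in report.stopping_reason

    def test_empty_training_set_rejected(self):
        model = InverseModel(4, seed=0)
        with pytest.raises(ValueError):
            train(model, np.empty((0, 4)), np.empty((0, 2)))


class TestPrediction:
    @pytest.fixture(scope="class")
    def trained(self):
        rd, labels = toy_problem(n=600)
        model = InverseModel(rd.shape[1], seed=0)
        train(model, rd, labels, epochs=800, seed=1, early_stopping=False)
        return model, rd, labels

    def test_training_samples_recovered_after_convergence(self, trained):
        model, rd, labels = trained
        pred = model.predict(rd)
        # median error ~1% once converged on a noiseless smooth problem
        assert np.median(np.abs(pred - labels)) < 2.0

    def test_identical_inputs_identical_outputs(self, trained):
        model, rd, _ = trained
        np.testing.assert_array_equal(model.predict(rd[:3]), model.predict(rd[:3]))

    def test_batch_equals_elementwise(self, trained):
        model, rd, _ = trained
        batch = model.predict(rd[:8])
        single = np.array([model.predict(rd[i]) for i in range(8)])
        np.testing.assert_allclose(batch, single, rtol=1e-12)

    def test_width_mismatch_rejected(self, trained):
        model, rd, _ = trained
        with pytest.raises(ValueError, match="width"):
            model.predict(rd[:, :-1])

    def test_channel_order_mismatch_rejected(self):
        rd, labels = toy_problem(n=50, width=3)
        model = InverseModel(3, channel_labels=["a", "b", "c"], seed=0)
        train(model, rd, labels, epochs=10, seed=1, early_stopping=False)
        with pytest.raises(ValueError, match="channel ordering"):
            model.predict(rd[:2], channel_labels=["b", "a", "c"])

    def test_serialization_round_trip_preserves_predictions(self, trained, tmp_path):
        model, rd, _ = trained
        path = tmp_path / "model.npz"
        model.save(path)
        reloaded = InverseModel.load(path)
        np.testing.assert_array_equal(reloaded.predict(rd), model.predict(rd))


class TestEvaluateRecovery:
    def test_perfect_predictor_zero_stats(self):
        rd, labels = toy_problem(n=10)

        class Perfect:
            def predict(self, x):
                return labels

        rep = evaluate_recovery(Perfect(), rd, labels)
        assert rep.mean_water == 0.0 and rep.sd_water == 0.0
        assert rep.mean_lipid == 0.0 and rep.sd_lipid == 0.0

    def test_error_sign_convention_estimated_minus_true(self):
        rd, labels = toy_problem(n=5)

        class Offset:
            def predict(self, x):
                return labels + np.array([2.0, -3.0])

        rep = evaluate_recovery(Offset(), rd, labels)
        assert rep.mean_water == pytest.approx(2.0)
        assert rep.mean_lipid == pytest.approx(-3.0)


class TestAgainstReferenceMLP:
    def test_comparable_fit_quality_to_sklearn(self):
        """Independent cross-check: scikit-learn's Adam-trained MLP with the
        same architecture reaches a comparable loss on the same data."""
        from sklearn.neural_network import MLPRegressor

        rd, labels = toy_problem(n=800)
        model = InverseModel(rd.shape[1], seed=0)
        train(model, rd, labels, epochs=600, seed=1, early_stopping=False)
        ours = float(np.mean((model.predict(rd) / 100.0 - labels / 100.0) ** 2))

        z, _ = log_normalize(rd)
        ref = MLPRegressor(
            hidden_layer_sizes=(20, 20, 20),
            activation="relu",
            solver="adam",
            learning_rate_init=1e-3,
            batch_size=256,
            max_iter=600,
            tol=0.0,
            random_state=1,
        )
        ref.fit(z, labels / 100.0)
        theirs = float(np.mean((ref.predict(z) - labels / 100.0) ** 2))
        # same order of magnitude: within a factor of 5 either way
        assert ours < theirs * 5 and theirs < ours * 5
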