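"""LS-SVM: kernel, dual-system solve, decision function, CV tuning."""

import numpy as np
import pytest

from watercore.exceptions import ConfigurationError, DegenerateInputError
from watercore.lssvm import (
    LSSVMConfig,
    fit,
    predict,
    rbf_kernel,
    decision_function,
    stratified_folds,
    system_residual,
    tune,
)


def blobs(rng, n_per_class=15, sep=6.0, d=2):
    X = np.vstack(
        [rng.normal(0, 1, (n_per_class, d)), rng.normal(sep, 1, (n_per_class, d))]
    )
    y = np.array([1] * n_per_class + [-1] * n_per_class)
    return X, y


class TestRBFKernel:
    def test_zero_distance_is_one(self):
        assert rbf_kernel([1.0, 2.0], [1.0, 2.0], 3.0) == 1.0

    def test_unit_scaled_distance_is_e_minus_one(self):
        x, z = np.zeros(2), np.array([1.0, 1.0])  # ||x-z||^2 = 2
        assert rbf_kernel(x, z, 2.0) == pytest.approx(np.exp(-1))

    def test_large_width_limit_approaches_one(self):
        assert rbf_kernel([0.0], [5.0], 1e12) == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ConfigurationError):
            rbf_kernel([0.0], [1.0], 0.0)


class TestFitPredict:
    def test_separable_blobs_train_perfectly(self, rng):
        X, y = blobs(rng)
        model = fit(X, y, gamma=100.0, sigma2=1.0)
        np.testing.assert_array_equal(predict(model, X), y)

    def test_xor_pattern_fit_with_nonlinear_kernel(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1, 1, -1, -1])
        model = fit(X, y, gamma=1e4, sigma2=0.3, standardize=False)
        np.testing.assert_array_equal(predict(model, X), y)

    def test_dual_system_residual_small(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.where(rng.uniform(size=20) > 0.5, 1, -1)
        y[:2] = [1, -1]
        model = fit(X, y, gamma=10.0, sigma2=2.0)
        assert system_residual(model) < 1e-8

    def test_alpha_y_balance_constraint(self, rng):
        X, y = blobs(rng, n_per_class=10)
        model = fit(X, y, gamma=5.0, sigma2=3.0)
        assert abs(np.sum(model.alpha * model.training_labels)) < 1e-8

    def test_decision_function_matches_naive_kernel_sum(self, rng):
        X, y = blobs(rng, n_per_class=8)
        model = fit(X, y, gamma=7.0, sigma2=1.5)
        X_new = rng.normal(2.0, 2.0, size=(5, 2))
        d = decision_function(model, X_new)
        Xs = (X_new - model.mean_) / model.scale_
        naive = np.array(
            [
                sum(
                    model.alpha[i]
                    * model.training_labels[i]
                    * rbf_kernel(x, model.training_inputs[i], model.sigma2)
                    for i in range(y.size)
                )
                + model.b
                for x in Xs
            ]
        )
        np.testing.assert_allclose(d, naive, rtol=1e-10, atol=1e-12)

    def test_training_error_vanishes_as_gamma_grows(self, rng):
        X, y = blobs(rng, n_per_class=10, sep=2.5)
        errors = []
        for gamma in (0.01, 1e6):
            model = fit(X, y, gamma=gamma, sigma2=2.0)
            errors.append(int((predict(model, X) != y).sum()))
        assert errors[1] == 0
        assert errors[1] <= errors[0]

    def test_dimension_mismatch_rejected(self, rng):
        X, y = blobs(rng, n_per_class=5)
        model = fit(X, y, gamma=1.0, sigma2=1.0)
        with pytest.raises(DegenerateInputError):
            predict(model, np.zeros((2, 3)))

    def test_single_class_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            fit(rng.normal(size=(4, 2)), np.ones(4, dtype=int), 1.0, 1.0)

    def test_standardization_uses_training_statistics_only(self, rng):
        X, y = blobs(rng, n_per_class=10)
        model = fit(X, y, gamma=10.0, sigma2=1.0)
        np.testing.assert_allclose(model.mean_, X.mean(axis=0))
        np.testing.assert_allclose(model.scale_, X.std(axis=0))
        # predictions on far-out-of-sample data use the stored parameters
        d1 = decision_function(model, X + 100.0)
        assert np.all(np.isfinite(d1))

    def test_json_round_trip_preserves_predictions(self, rng, tmp_path):
        X, y = blobs(rng, n_per_class=6)
        model = fit(X, y, gamma=3.0, sigma2=1.0)
        from watercore.lssvm import LSSVMModel

        path = model.to_json(tmp_path / "m.json")
        back = LSSVMModel.from_json(path)
        np.testing.assert_allclose(
            decision_function(model, X), decision_function(back, X), rtol=1e-12
        )


class TestTune:
    def test_single_candidate_grid_returned_verbatim(self, rng):
        X, y = blobs(rng, n_per_class=10)
        cfg = LSSVMConfig(gamma_grid=(5.0,), sigma2_grid=(2.0,), n_folds=4, refine=False)
        res = tune(X, y, cfg)
        assert (res.gamma, res.sigma2) == (5.0, 2.0)
        assert 0.0 <= res.cv_accuracy <= 1.0

    def test_stratified_folds_balance_classes(self):
        y = np.array([1] * 100 + [-1] * 100)
        folds = stratified_folds(y, 10, seed=0)
        for _, te in folds:
            assert te.size == 20
            assert (y[te] == 1).sum() == 10

    def test_cv_objective_matches_independent_reevaluation(self, rng):
        X, y = blobs(rng, n_per_class=15, sep=3.0)
        cfg = LSSVMConfig(
            gamma_grid=(0.1, 10.0), sigma2_grid=(0.5, 5.0), n_folds=5, refine=False, seed=3
        )
        res = tune(X, y, cfg)
        correct = 0
        for tr, te in stratified_folds(y, cfg.n_folds, cfg.seed):
            m = fit(X[tr], y[tr], res.gamma, res.sigma2, cfg.standardize)
            correct += int((predict(m, X[te]) == y[te]).sum())
        assert res.cv_accuracy == pytest.approx(correct / y.size)

    def test_deterministic_for_fixed_config(self, rng):
        X, y = blobs(rng, n_per_class=10)
        cfg = LSSVMConfig(gamma_grid=(1.0, 10.0), sigma2_grid=(1.0, 10.0), n_folds=5, seed=1)
        a = tune(X, y, cfg)
        b = tune(X, y, cfg)
        assert (a.gamma, a.sigma2, a.cv_accuracy) == (b.gamma, b.sigma2, b.cv_accuracy)
        assert a.trace == b.trace

    def test_fewer_samples_than_folds_rejected(self, rng):
        X, y = blobs(rng, n_per_class=3)
        with pytest.raises(DegenerateInputError):
            tune(X, y, LSSVMConfig(n_folds=10))
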