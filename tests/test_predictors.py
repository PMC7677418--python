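"""Predictor fits (ML, HB-MAP), prediction rules, and the MLP model."""

import numpy as np
import pytest

import moralsim as ms
from moralsim.choice import sigmoid
from moralsim.predictors import DecisionData


def _loglik_brute(w, X, y):
    """Independent per-term evaluation of the Bernoulli log-likelihood."""
    total = 0.0
    for xi, yi in zip(X, y):
        p = 1.0 / (1.0 + np.exp(-(xi @ w)))
        total += yi * np.log(p) + (1 - yi) * np.log(1 - p)
    return total


def _grid_argmax(objective, lim=2.0, step=0.01):
    g = np.arange(-lim, lim + step / 2, step)
    W = np.array(np.meshgrid(g, g)).reshape(2, -1).T
    vals = objective(W)
    return W[np.argmax(vals)]


# A dim=2, 3-scenario toy whose unpenalized MLE is finite (not separable).
TOY_X = np.array([[1.0, 0.0], [-1.0, 1.0], [1.0, 1.0]])
TOY_Y = np.array([1.0, 1.0, 0.0])


class TestLogLikelihood:
    def test_empty_records_give_zero(self):
        assert ms.log_likelihood(np.zeros(3), DecisionData(
            np.zeros((0, 3)), np.zeros(0))) == 0.0

    def test_equal_utilities_give_log_half(self):
        data = DecisionData(np.zeros((1, 4)), np.array([1.0]))
        assert ms.log_likelihood(np.ones(4), data) == pytest.approx(
            np.log(0.5))

    def test_matches_per_term_brute_force(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.integers(0, 2, 20).astype(float)
        w = rng.normal(size=6)
        assert ms.log_likelihood(w, DecisionData(X, y)) == pytest.approx(
            _loglik_brute(w, X, y))

    def test_never_positive(self, rng):
        for _ in range(20):
            X = rng.normal(size=(8, 3))
            y = rng.integers(0, 2, 8).astype(float)
            assert ms.log_likelihood(rng.normal(size=3),
                                     DecisionData(X, y)) <= 0.0


class TestFitML:
    def test_opposite_labels_on_same_features_give_zero(self):
        data = DecisionData(np.array([[1.0, 2.0], [1.0, 2.0]]),
                            np.array([1.0, 0.0]))
        res = ms.fit_ml(data)
        assert res.converged
        np.testing.assert_allclose(res.w_hat, 0.0, atol=1e-5)

    def test_positive_evidence_gives_positive_weight(self):
        data = DecisionData(np.array([[2.0]]), np.array([1.0]))
        assert ms.fit_ml(data).w_hat[0] > 0

    def test_zero_records_return_zero_vector(self):
        res = ms.fit_ml(DecisionData(np.zeros((0, 7)), np.zeros(0)))
        np.testing.assert_array_equal(res.w_hat, np.zeros(7))

    def test_matches_grid_search(self):
        penalty = 1e-6
        res = ms.fit_ml(DecisionData(TOY_X, TOY_Y), penalty=penalty)

        def objective(W):
            Z = W @ TOY_X.T
            ll = (TOY_Y * Z - np.logaddexp(0.0, Z)).sum(axis=1)
            return ll - penalty * (W ** 2).sum(axis=1)

        w_grid = _grid_argmax(objective)
        assert np.abs(w_grid).max() < 1.9  # optimum interior to the grid
        assert np.abs(res.w_hat - w_grid).max() <= 0.01 + 1e-9

    def test_recovers_weights_with_many_observations(self):
        rng = np.random.default_rng(13)
        w_true = np.array([0.8, -0.5, 1.2, 0.3])
        X = rng.integers(-3, 4, size=(200, 4)).astype(float)
        y = (rng.random(200) < sigmoid(X @ w_true)).astype(float)
        w_hat = ms.fit_ml(DecisionData(X, y)).w_hat
        rel_err = np.linalg.norm(w_hat - w_true) / np.linalg.norm(w_true)
        assert rel_err < 0.10


class TestFitHBMap:
    def _toy_spec(self):
        return ms.PopulationSpec(
            mode="toy2", group_mean=np.array([0.3, -0.2]),
            group_cov=np.array([[0.5, 0.1], [0.1, 0.4]]),
            kappa=np.zeros(2), features=("a", "b"))

    def test_zero_records_return_prior_mode(self):
        spec = self._toy_spec()
        res = ms.fit_hb_map(DecisionData(np.zeros((0, 2)), np.zeros(0)), spec)
        np.testing.assert_array_equal(res.w_hat, spec.group_mean)

    def test_flat_prior_converges_to_ml(self):
        # with a non-separable dataset both optima are finite and agree
        X = np.vstack([TOY_X, TOY_X])
        y = np.concatenate([TOY_Y, TOY_Y])
        spec = ms.PopulationSpec(
            mode="toy2", group_mean=np.zeros(2),
            group_cov=1e6 * np.eye(2), kappa=np.zeros(2),
            features=("a", "b"))
        w_hb = ms.fit_hb_map(DecisionData(X, y), spec).w_hat
        w_ml = ms.fit_ml(DecisionData(X, y)).w_hat
        assert np.abs(w_hb - w_ml).max() < 1e-3

    def test_matches_grid_search(self):
        spec = self._toy_spec()
        res = ms.fit_hb_map(DecisionData(TOY_X, TOY_Y), spec)
        prec = np.linalg.inv(spec.group_cov)

        def objective(W):
            Z = W @ TOY_X.T
            ll = (TOY_Y * Z - np.logaddexp(0.0, Z)).sum(axis=1)
            D = W - spec.group_mean
            return ll - 0.5 * np.einsum("ni,ij,nj->n", D, prec, D)

        w_grid = _grid_argmax(objective)
        assert np.abs(w_grid).max() < 1.9
        assert np.abs(res.w_hat - w_grid).max() <= 0.01 + 1e-9

    def test_optimum_beats_random_perturbations(self, rng):
        """Concavity: no perturbed candidate improves the posterior."""
        spec = self._toy_spec()
        data = DecisionData(TOY_X, TOY_Y)
        res = ms.fit_hb_map(data, spec)
        prec = np.linalg.inv(spec.group_cov)

        def posterior(w):
            d = w - spec.group_mean
            return ms.log_likelihood(w, data) - 0.5 * d @ prec @ d

        best = posterior(res.w_hat)
        for _ in range(200):
            cand = res.w_hat + rng.normal(scale=0.5, size=2)
            assert posterior(cand) <= best + 1e-9

    def test_singular_prior_rejected(self):
        spec = ms.PopulationSpec(
            mode="toy2", group_mean=np.zeros(2),
            group_cov=np.array([[1.0, 1.0], [1.0, 1.0]]),
            kappa=np.zeros(2), features=("a", "b"))
        with pytest.raises(ValueError):
            ms.fit_hb_map(DecisionData(TOY_X, TOY_Y), spec)


class TestPredictionRules:
    def test_predict_matches_deterministic_simulation(self, vocab, rng):
        proc = ms.DecisionProcess("deterministic")
        for _ in range(2000):
            s = ms.generate_scenario(rng)
            w = rng.normal(size=18)
            assert ms.predict_from_w(w, s, vocab) == \
                ms.simulate_decision(w, s, proc, vocab=vocab)

    def test_gt_predict_is_predict_from_w(self, vocab, rng):
        s = ms.generate_scenario(rng)
        w = rng.normal(size=18)
        assert ms.gt_predict(w, s, vocab) == ms.predict_from_w(w, s, vocab)

    def test_tie_goes_to_non_intervention(self):
        s = ms.Scenario(
            theta0=ms.OptionVector(np.array([1] + [0] * 15), "abstract"),
            theta1=ms.OptionVector(np.array([0, 1] + [0] * 14), "abstract"),
            mode="abstract")
        assert ms.predict_from_w(np.ones(16), s) == 0


class TestMoralMLP:
    def _toy_data(self, rng, n=200, dim=8):
        w = rng.normal(size=dim)
        X = rng.normal(size=(n, dim))
        y = (X @ w > 0).astype(float)
        return X, y

    def test_output_is_probability(self, rng):
        model = ms.build_dl(ms.DLModelSpec(seed=1), 10)
        p = model.predict_proba(rng.normal(size=(50, 10)))
        assert ((p > 0) & (p < 1)).all()

    def test_same_seed_identical_init(self):
        a = ms.build_dl(ms.DLModelSpec(seed=9), 12)
        b = ms.build_dl(ms.DLModelSpec(seed=9), 12)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_parameter_count_closed_form(self):
        spec = ms.DLModelSpec(hidden_widths=(7, 5), seed=0)
        model = ms.build_dl(spec, 4)
        # dense W+b plus batchnorm gain+shift per hidden unit, final dense
        expected = (4 * 7 + 7 + 2 * 7) + (7 * 5 + 5 + 2 * 5) + (5 * 1 + 1)
        assert model.n_parameters == expected

    def test_invalid_widths_rejected(self):
        with pytest.raises(ValueError):
            ms.DLModelSpec(hidden_widths=())

    def test_fits_linearly_separable_data(self, rng):
        X, y = self._toy_data(rng)
        spec = ms.DLModelSpec(seed=2, max_epochs=150)
        model = ms.build_dl(spec, X.shape[1])
        model, _ = ms.train_dl(model, (X, y), (X, y), spec)
        assert (model.predict(X) == y).mean() >= 0.95

    def test_returns_best_validation_epoch(self, rng):
        X, y = self._toy_data(rng)
        Xv, yv = self._toy_data(rng, n=100)
        spec = ms.DLModelSpec(seed=3, max_epochs=60)
        model = ms.build_dl(spec, X.shape[1])
        model, history = ms.train_dl(model, (X, y), (Xv, yv), spec)
        assert np.isfinite(history["val_loss"]).all()
        best = min(history["val_loss"])
        assert model.loss(Xv, yv) == pytest.approx(best, abs=1e-9)
        assert history["val_loss"][history["best_epoch"]] == best

    def test_training_deterministic_given_seed(self, rng):
        X, y = self._toy_data(rng)
        Xv, yv = self._toy_data(rng, n=80)
        losses = []
        for _ in range(2):
            spec = ms.DLModelSpec(seed=4, max_epochs=30)
            model = ms.build_dl(spec, X.shape[1])
            _, history = ms.train_dl(model, (X, y), (Xv, yv), spec)
            losses.append(history["val_loss"][-1])
        assert losses[0] == losses[1]

    def test_empty_training_set_rejected(self):
        spec = ms.DLModelSpec(seed=0)
        model = ms.build_dl(spec, 6)
        with pytest.raises(ValueError):
            model.fit(np.zeros((0, 6)), np.zeros(0), np.zeros((2, 6)),
                      np.zeros(2))


class TestFineTune:
    def test_zero_epochs_leaves_model_unchanged(self, rng):
        model = ms.build_dl(ms.DLModelSpec(seed=5, fine_tune_epochs=0), 8)
        X, y = rng.normal(size=(8, 8)), np.zeros(8)
        assert ms.fine_tune_dl(model, (X, y)) is model

    def test_fine_tune_ablation_is_mild_on_fitted_data(self, rng):
        X = rng.normal(size=(300, 8))
        w = rng.normal(size=8)
        y = (X @ w > 0).astype(float)
        spec = ms.DLModelSpec(seed=6, max_epochs=120, fine_tune_epochs=3)
        model = ms.build_dl(spec, 8)
        model, _ = ms.train_dl(model, (X, y), (X, y), spec)
        base_acc = (model.predict(X) == y).mean()
        tuned = ms.fine_tune_dl(model, (X[:8], y[:8]), spec)
        changed = any(not np.array_equal(tuned.params[k], model.params[k])
                      for k in model.params)
        assert changed
        tuned_acc = (tuned.predict(X) == y).mean()
        assert abs(tuned_acc - base_acc) < 0.10
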