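import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from metaboclass import (
    PLSDAClassifier,
    fit,
    permutation_p_value,
    permutation_test,
    q_squared,
    r_squared,
    scores_for_plot,
    vip,
)
from metaboclass.data_model import SampleClasses
from metaboclass.preprocessing import autoscale


def krylov_pls1_coefficients(X: np.ndarray, y01: np.ndarray, n_components: int) -> np.ndarray:
    """Independent PLS1 oracle: least squares restricted to the Krylov
    subspace span{s, Ss, ..., S^(A-1)s} with s = X'y and S = X'X (on the
    autoscaled X and centered y), which equals the PLS1 solution."""
    Xs, _, _ = autoscale(X)
    yc = y01 - y01.mean()
    s = Xs.T @ yc
    S = Xs.T @ Xs
    K = np.column_stack([np.linalg.matrix_power(S, a) @ s for a in range(n_components)])
    K, _ = np.linalg.qr(K)  # orthonormal basis for numerical stability
    alpha = np.linalg.solve(K.T @ S @ K, K.T @ s)
    return K @ alpha


def _binary_data(rng, n=12, p=13, effect=1.5):
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    X = rng.normal(size=(n, p))
    X[:, :3] += effect * y[:, None]
    return X, y


class TestFit:
    def test_perfect_linear_predictor_gives_r2_one(self, rng):
        # one component recovers y exactly when the remaining columns carry
        # no covariance with it
        y = np.array([0, 0, 0, 1, 1, 1])
        yc = y - y.mean()
        noise = rng.normal(size=(6, 3))
        noise -= np.outer(yc, yc @ noise) / (yc @ yc)
        X = np.column_stack([y.astype(float), noise])
        model = fit(X, y, n_components=1)
        assert r_squared(model, X, y).r2 == pytest.approx(1.0, abs=1e-9)

    def test_first_weight_proportional_to_xty(self, rng):
        X, y = _binary_data(rng)
        model = fit(X, y, n_components=2)
        Xs, _, _ = autoscale(X)
        yc = y - y.mean()
        direction = Xs.T @ yc
        direction /= np.linalg.norm(direction)
        np.testing.assert_allclose(model.weights_[:, 0], direction, atol=1e-9)

    def test_coefficients_match_krylov_oracle(self, rng):
        for _ in range(20):
            X, y = _binary_data(rng)
            model = fit(X, y, n_components=2)
            expected = krylov_pls1_coefficients(X, (y == 1).astype(float), 2)
            np.testing.assert_allclose(model.coef_, expected, atol=1e-6)

    def test_predictions_match_sklearn_pls(self, rng):
        X, y = _binary_data(rng)
        model = fit(X, y, n_components=2)
        sk = PLSRegression(n_components=2, scale=True).fit(X, (y == 1).astype(float))
        np.testing.assert_allclose(
            model.predict_value(X), sk.predict(X).ravel(), atol=1e-8
        )

    def test_scores_orthogonal_weights_unit_norm(self, rng):
        X, y = _binary_data(rng)
        model = fit(X, y, n_components=3)
        T = model.x_scores_
        gram = T.T @ T
        off_diag = gram - np.diag(np.diag(gram))
        assert np.abs(off_diag).max() < 1e-8
        np.testing.assert_allclose(np.linalg.norm(model.weights_, axis=0), 1.0, atol=1e-12)

    def test_training_predictions_reproduce_fitted_values(self, rng):
        X, y = _binary_data(rng)
        model = fit(X, y, n_components=2)
        np.testing.assert_allclose(model.predict_value(X), model.y_fitted_, atol=1e-9)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        with pytest.raises(ValueError, match="two classes"):
            fit(X, np.zeros(6, dtype=int))

    def test_too_many_components_rejected(self, rng):
        X, y = _binary_data(rng, n=6, p=4)
        with pytest.raises(ValueError, match="n_components"):
            fit(X, y, n_components=6)

    def test_string_labels_predict_string_classes(self, rng):
        X, y = _binary_data(rng)
        names = np.where(y == 0, "Thai", "Foreign")
        model = fit(X, names, n_components=2)
        assert set(model.predict(X)) <= {"Thai", "Foreign"}
        assert (model.predict(X) == names).mean() > 0.8

    def test_r2_non_decreasing_in_components(self, rng):
        X, y = _binary_data(rng)
        r2s = [r_squared(fit(X, y, n_components=a), X, y).r2 for a in (1, 2, 3, 4)]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))


class TestRSquared:
    def test_worked_arithmetic(self, rng):
        # y = {0,0,1,1}, yhat = {0.1, -0.1, 0.9, 1.1}: sse = 0.04, sst = 1
        X, y = _binary_data(rng, n=4, p=3)
        model = fit(X, y, n_components=1)
        model.coef_ = np.zeros(3)
        model.x_mean_ = np.zeros(3)
        model.x_std_ = np.ones(3)
        model.y_mean_ = 0.0
        X_probe = np.array([[0.1, 0, 0], [-0.1, 0, 0], [0.9, 0, 0], [1.1, 0, 0]])
        model.coef_[0] = 1.0
        stats = r_squared(model, X_probe, np.array([0, 0, 1, 1]))
        assert stats.sse == pytest.approx(0.04, abs=1e-12)
        assert stats.sst == pytest.approx(1.0, abs=1e-12)
        assert stats.r2 == pytest.approx(0.96, abs=1e-12)
        assert stats.r2 == 1 - stats.sse / stats.sst

    def test_mean_predictor_gives_zero(self, rng):
        X, y = _binary_data(rng)
        model = fit(X, y, n_components=2)
        model.coef_ = np.zeros_like(model.coef_)  # predicts ybar everywhere
        assert r_squared(model, X, y).r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_rejected(self, rng):
        X, y = _binary_data(rng)
        model = fit(X, y, n_components=2)
        with pytest.raises(ValueError, match="SST"):
            r_squared(model, X, np.ones_like(y))


class TestQSquared:
    def test_identity_holds_exactly(self, rng):
        X, y = _binary_data(rng)
        cv = q_squared(X, y, seed=3)
        assert cv.q2 == 1 - cv.press / cv.tss

    def test_folds_partition_samples_and_are_stratified(self, rng):
        X, y = _binary_data(rng)
        cv = q_squared(X, y, k=5, seed=3)
        assert sorted(cv.fold_assignments) == list(range(12))
        assert set(cv.fold_assignments.values()) == {1, 2, 3, 4, 5}

    def test_strong_signal_gives_high_q2(self, rng):
        X, y = _binary_data(rng, effect=4.0)
        assert q_squared(X, y, seed=1).q2 > 0.5

    def test_k_larger_than_n_rejected(self, rng):
        X, y = _binary_data(rng, n=4, p=3)
        with pytest.raises(ValueError, match="folds"):
            q_squared(X, y, k=10)

    def test_seed_determinism(self, rng):
        X, y = _binary_data(rng)
        assert q_squared(X, y, seed=7).q2 == q_squared(X, y, seed=7).q2

    def test_q2_at_most_r2_in_well_posed_regime(self, paper_like_filtered):
        _, X, y, _ = paper_like_filtered
        model = fit(X, y, n_components=2)
        assert q_squared(X, y, seed=5).q2 <= r_squared(model, X, y).r2


class TestPermutation:
    def test_literal_formula_on_constructed_distribution(self):
        permuted = np.concatenate([np.full(50, 0.9), np.full(950, -0.5)])
        assert permutation_p_value(permuted, observed_q2=0.5) == pytest.approx(0.05)

    def test_zero_attainable_with_literal_estimator(self):
        permuted = np.full(100, -0.5)
        assert permutation_p_value(permuted, observed_q2=0.5) == 0.0
        assert permutation_p_value(permuted, 0.5, plus_one=True) == pytest.approx(1 / 101)

    def test_null_data_gives_large_p(self, rng):
        X = rng.normal(size=(12, 13))
        y = np.array([0] * 6 + [1] * 6)
        result = permutation_test(X, y, n_runs=200, seed=11)
        assert result.p_value > 0.05
        lo, hi = np.quantile(result.permuted_q2, [0.025, 0.975])
        assert lo <= result.observed_q2 <= hi

    def test_signal_data_gives_small_p(self, paper_like_filtered):
        _, X, y, _ = paper_like_filtered
        result = permutation_test(X, y, n_runs=200, seed=11)
        assert result.p_value < 0.05

    def test_invalid_run_count_rejected(self, rng):
        X, y = _binary_data(rng)
        with pytest.raises(ValueError, match="n_runs"):
            permutation_test(X, y, n_runs=0)


class TestVIP:
    def test_mean_square_is_one(self, paper_like_filtered):
        _, X, y, _ = paper_like_filtered
        model = fit(X, y, n_components=2)
        scores = vip(model).scores
        assert np.mean(scores**2) == pytest.approx(1.0, abs=1e-9)

    def test_equal_weights_give_unit_vip(self):
        # X columns are identical copies of the response direction
        y = np.array([0, 0, 1, 1, 0, 1])
        base = np.array([0.1, -0.2, 1.1, 0.8, 0.05, 1.0])
        X = np.tile(base[:, None], (1, 5))
        model = fit(X, y, n_components=1)
        np.testing.assert_allclose(vip(model).scores, np.ones(5), atol=1e-9)

    def test_single_active_feature_gets_sqrt_p(self, rng):
        # only column 0 covaries with y; 12 others are exactly orthogonal to it
        y = np.array([0.0, 0.0, 1.0, 1.0])
        yc = y - y.mean()
        X = np.empty((4, 13))
        X[:, 0] = y
        patterns = rng.normal(size=(4, 12))
        # project out the centered response so X'yc = 0 for those columns
        patterns -= np.outer(yc, yc @ patterns) / (yc @ yc)
        X[:, 1:] = patterns
        model = fit(X, y.astype(int), n_components=1)
        scores = vip(model)
        assert scores.scores[0] == pytest.approx(np.sqrt(13), abs=1e-8)
        np.testing.assert_allclose(scores.scores[1:], 0.0, atol=1e-8)

    def test_planted_features_exceed_threshold_and_outrank_noise(self, paper_like_filtered):
        filtered, X, y, _ = paper_like_filtered
        model = fit(X, y, n_components=2)
        scores = vip(model)
        names = filtered.feature_ids
        planted = {"linoleic_acid_like", "clionasterol_like", "vitamin_E_like"}
        by_name = dict(zip(names, scores.scores))
        worst_planted = min(by_name[f] for f in planted)
        best_noise = max(v for f, v in by_name.items() if f not in planted)
        assert worst_planted > 1.0
        assert worst_planted > best_noise

    def test_unfitted_model_rejected(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            vip(PLSDAClassifier())


class TestScoresForPlot:
    def test_shape_and_class_names(self, paper_like_filtered):
        filtered, X, y, classes = paper_like_filtered
        model = fit(X, y, n_components=2)
        frame = scores_for_plot(model, classes, filtered.sample_ids)
        assert frame.shape == (12, 4)
        assert set(frame["class"]) == {"Thai", "Foreign"}

    def test_classes_separate_on_first_latent_variable(self, paper_like_filtered):
        filtered, X, y, classes = paper_like_filtered
        model = fit(X, y, n_components=2)
        frame = scores_for_plot(model, classes, filtered.sample_ids)
        lv1 = frame["LV1"].to_numpy()
        g0, g1 = lv1[y == 0], lv1[y == 1]
        pooled_sd = np.sqrt((g0.var(ddof=1) + g1.var(ddof=1)) / 2)
        assert abs(g0.mean() - g1.mean()) > 2 * pooled_sd

    def test_one_component_model_rejected(self, rng):
        X, y = _binary_data(rng)
        model = fit(X, y, n_components=1)
        classes = SampleClasses(
            labels={f"s{i}": int(v) for i, v in enumerate(y)},
            class_names={0: "Thai", 1: "Foreign"},
        )
        with pytest.raises(ValueError, match="two components"):
            scores_for_plot(model, classes, [f"s{i}" for i in range(12)])
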