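"""OPLS-DA core: equivalence with PLS, prediction symmetry, VIP, Q² under
permutation, and jack-knife confidence intervals."""

import numpy as np
import pytest

from oplskit import (
    SimConfig,
    cross_validate,
    fit_opls,
    generate_cohort,
    jackknife_ci,
    predict,
    predicted_y_test,
)
from oplskit.core_io import group_vector
from oplskit.opls import ModelError, assign_folds


def pls1_nipals(X, y, n_components):
    """Independent reference PLS1 (NIPALS with deflation of X and y).

    Returns per-component weights/scores/loadings and cumulative fitted
    values; written directly from the textbook recursion, sharing no code
    with the package implementation.
    """
    X = X.copy().astype(float)
    y = y.copy().astype(float)
    Z = (X - X.mean(0)) / X.std(0)
    u = y - y.mean()
    W, T, P, C = [], [], [], []
    yhat = np.full(y.shape, y.mean())
    for _ in range(n_components):
        w = Z.T @ u
        w /= np.linalg.norm(w)
        t = Z @ w
        p = Z.T @ t / (t @ t)
        c = (u @ t) / (t @ t)
        Z = Z - np.outer(t, p)
        u = u - c * t
        W.append(w); T.append(t); P.append(p); C.append(c)
        yhat = yhat + c * t
    return map(np.array, (W, T, P, C)), yhat


class TestFitOpls:
    def test_zero_orthogonal_equals_pls1(self, default_xy):
        """With no orthogonal filtering the model is one-component PLS1."""
        X, y = default_xy
        m = fit_opls(X, y, n_orthogonal=0)
        (W, T, P, C), yhat = pls1_nipals(X, y, 1)
        sign = np.sign(W[0] @ m.w)
        np.testing.assert_allclose(m.w, sign * W[0], atol=1e-8)
        np.testing.assert_allclose(m.t, sign * T[0], atol=1e-6)
        np.testing.assert_allclose(m.p, sign * P[0], atol=1e-8)
        np.testing.assert_allclose(predict(m, X), yhat, atol=1e-8)

    def test_opls_one_orthogonal_equals_two_component_pls(self, default_xy):
        """The O-PLS rotation property: 1 predictive + 1 orthogonal
        component fits the same ŷ as 2-component PLS."""
        X, y = default_xy
        m = fit_opls(X, y, n_orthogonal=1)
        _, yhat_pls = pls1_nipals(X, y, 2)
        np.testing.assert_allclose(predict(m, X), yhat_pls, atol=1e-6)

    def test_y_copy_column_has_perfect_pcorr(self, rng):
        """A column duplicating y is a perfect discriminator: its p(corr)
        is exactly 1 (the remaining variables carry no group signal)."""
        y = np.array([0.0] * 8 + [1.0] * 8)
        yc = y - y.mean()
        noise = rng.normal(size=(16, 5))
        noise -= np.outer(yc, yc @ noise) / (yc @ yc)
        Xa = np.column_stack([noise, y])
        m = fit_opls(Xa, y, n_orthogonal=0)
        assert m.pcorr[-1] == pytest.approx(1.0, abs=1e-8)
        assert np.argmax(m.pcorr) == 5

    def test_predictive_score_orthogonal_to_filtered_scores(self, default_xy):
        X, y = default_xy
        m = fit_opls(X, y, n_orthogonal=2)
        for a in range(2):
            assert abs(m.t @ m.t_o[:, a]) < 1e-8 * np.linalg.norm(m.t) * np.linalg.norm(m.t_o[:, a])

    def test_r2x_complement_is_residual_fraction(self, default_xy):
        X, y = default_xy
        m = fit_opls(X, y, n_orthogonal=1)
        Z = (X - X.mean(0)) / X.std(0)
        Zhat = (np.outer(m.t_o[:, 0], m.p_o[:, 0]) + np.outer(m.t, m.p))
        resid = ((Z - Zhat) ** 2).sum() / (Z ** 2).sum()
        assert m.r2x + resid == pytest.approx(1.0, abs=1e-8)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ModelError):
            fit_opls(rng.normal(size=(6, 3)), np.zeros(6))

    def test_sign_flip_equivariance(self, default_xy):
        """Negating one variable negates its pcorr, loading and weights but
        leaves VIP unchanged."""
        X, y = default_xy
        m0 = fit_opls(X, y)
        X2 = X.copy()
        X2[:, 5] = -X2[:, 5] + 2 * X2[:, 5].mean()  # mirror about the mean
        m1 = fit_opls(X2, y)
        assert m1.pcorr[5] == pytest.approx(-m0.pcorr[5], abs=1e-10)
        assert m1.p[5] == pytest.approx(-m0.p[5], abs=1e-10)
        assert m1.vip[5] == pytest.approx(m0.vip[5], abs=1e-10)
        np.testing.assert_allclose(m1.pcorr[:5], m0.pcorr[:5], atol=1e-10)

    def test_pcorr_sign_recovers_planted_directions(self):
        """Signed p(corr) matches the planted effect direction for >= 90%
        of affected metabolites, averaged over 20 seeds."""
        rates = []
        for seed in range(20):
            table, meta, _, truth = generate_cohort(SimConfig(seed=200 + seed))
            y = group_vector(table, meta)
            m = fit_opls(table.areas, y)
            ok = [(m.pcorr[i] < 0) == (truth.direction[met] == "DOWN")
                  for i, met in enumerate(table.metabolite_ids)
                  if truth.direction[met] != "NONE"]
            rates.append(np.mean(ok))
        assert np.mean(rates) >= 0.9, np.mean(rates)


class TestVip:
    def test_mean_squared_vip_is_one(self, default_xy):
        X, y = default_xy
        for n_orth in (0, 1, 2):
            m = fit_opls(X, y, n_orthogonal=n_orth)
            assert (m.vip ** 2).sum() == pytest.approx(X.shape[1], rel=1e-8)

    def test_single_variable_vip_is_one(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        m = fit_opls(X, y, n_orthogonal=0)
        assert m.vip[0] == pytest.approx(1.0)

    def test_identical_copies_all_vip_one(self, rng):
        x = rng.normal(size=12)
        X = np.tile(x[:, None], (1, 4))
        y = np.array([0.0] * 6 + [1.0] * 6)
        m = fit_opls(X, y, n_orthogonal=0)
        np.testing.assert_allclose(m.vip, 1.0, atol=1e-10)

    def test_three_variable_hand_computation(self):
        """With no orthogonal component VIP reduces to sqrt(k)·|w|; the
        weights are X'y normalised, evaluated here by hand."""
        X = np.array([[1.0, 2.0, 1.0],
                      [2.0, 1.0, 1.5],
                      [3.0, 5.0, 2.0],
                      [4.0, 4.0, 2.5]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        Z = (X - X.mean(0)) / X.std(0)
        yc = y - 0.5
        w = Z.T @ yc
        w = w / np.sqrt((w ** 2).sum())
        expected = np.sqrt(3.0 * w ** 2)
        m = fit_opls(X, y, n_orthogonal=0)
        np.testing.assert_allclose(m.vip, expected, atol=1e-10)


class TestPredict:
    def test_training_r2_matches_r2y(self, default_xy):
        X, y = default_xy
        m = fit_opls(X, y)
        yhat = predict(m, X)
        r2 = np.corrcoef(yhat, y)[0, 1] ** 2
        assert r2 == pytest.approx(m.r2y_cum, abs=1e-8)

    def test_mean_sample_predicts_mean_y(self, default_xy):
        X, y = default_xy
        m = fit_opls(X, y)
        assert predict(m, X.mean(0))[0] == pytest.approx(y.mean(), abs=1e-8)

    def test_class_swap_symmetry(self, default_xy):
        X, y = default_xy
        yhat = predict(fit_opls(X, y), X)
        yhat_sw = predict(fit_opls(X, 1 - y), X)
        np.testing.assert_allclose(yhat_sw, 1 - yhat, atol=1e-8)

    def test_variable_mismatch(self, default_xy):
        X, y = default_xy
        m = fit_opls(X, y)
        with pytest.raises(ModelError, match="mismatch"):
            predict(m, X[:, :-1])


class TestCrossValidate:
    def test_folds_partition_and_balance(self, default_xy):
        X, y = default_xy
        cv = cross_validate(X, y, n_folds=7)
        assert np.bincount(cv.folds).sum() == len(y)
        sizes = np.bincount(cv.folds)
        assert sizes.max() - sizes.min() <= 1

    def test_loo_structure(self, default_xy):
        X, y = default_xy
        n = len(y)
        cv = cross_validate(X, y, n_folds=n)
        assert len(np.unique(cv.folds)) == n  # each prediction excludes its own sample

    def test_deterministic_fold_assignment(self):
        y = np.array([0, 0, 1, 1, 0, 1], dtype=float)
        ids = ["c", "a", "f", "d", "b", "e"]
        f1 = assign_folds(y, ids, 3)
        f2 = assign_folds(y, ids, 3)
        np.testing.assert_array_equal(f1, f2)
        # sorted by (class, id): a,b,c placebo then d,e,f active, dealt round-robin
        assert f1[1] == 0 and f1[4] == 1 and f1[0] == 2

    def test_permuted_labels_kill_q2(self, default_xy):
        """Label permutation destroys predictive ability: Q² <= 0.1 in at
        least 90% of 100 permutations."""
        X, y = default_xy
        gen = np.random.default_rng(7)
        q2 = []
        for _ in range(100):
            yp = gen.permutation(y)
            q2.append(cross_validate(X, yp).q2)
        assert np.mean(np.asarray(q2) <= 0.1) >= 0.9

    def test_separable_data_high_q2(self):
        table, meta, _, _ = generate_cohort(
            SimConfig(seed=11, effect_down=0.5, effect_up=2.0, dilution_sd=0.0))
        y = group_vector(table, meta)
        assert cross_validate(table.areas, y).q2 > 0.5

    def test_too_few_folds(self, default_xy):
        X, y = default_xy
        with pytest.raises(ModelError):
            cross_validate(X, y, n_folds=1)


class TestPredictedYTest:
    def test_equal_means_give_p_one(self):
        from oplskit.opls import CrossValidation
        pred = np.array([0.2, 0.4, 0.6, 0.2, 0.4, 0.6])
        cv = CrossValidation(3, np.zeros(6, int), pred, 0.0, 0.0, [])
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        _, p = predicted_y_test(cv, y)
        assert p == pytest.approx(1.0)

    def test_affine_invariance(self, default_xy):
        from oplskit.opls import CrossValidation
        X, y = default_xy
        cv = cross_validate(X, y)
        _, p0 = predicted_y_test(cv, y)
        cv2 = CrossValidation(cv.n_folds, cv.folds, 5.0 * cv.cv_predicted_y - 2.0,
                              cv.press, cv.q2, [])
        _, p1 = predicted_y_test(cv2, y)
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_power_at_default_conditions(self):
        """Cross-validated predicted-Y Welch test rejects in >= 80% of 50
        default-condition cohorts."""
        from oplskit import is_normalize
        hits = 0
        for seed in range(50):
            table, meta, standards, _ = generate_cohort(SimConfig(seed=300 + seed))
            y = group_vector(table, meta)
            X = is_normalize(table, standards).normalized.areas
            _, p = predicted_y_test(cross_validate(X, y), y)
            hits += p < 0.05
        assert hits >= 40, hits


class TestJackknife:
    def test_ci_brackets_estimate_and_flags_match(self, default_xy):
        X, y = default_xy
        jk = jackknife_ci(X, y)
        assert np.all(jk.lower <= jk.statistic + 1e-12)
        assert np.all(jk.statistic <= jk.upper + 1e-12)
        np.testing.assert_array_equal(jk.significant, (jk.lower > 0) | (jk.upper < 0))

    def test_duplicate_variable_identical_ci(self, default_xy):
        X, y = default_xy
        Xd = np.column_stack([X, X[:, 3]])
        jk = jackknife_ci(Xd, y)
        assert jk.lower[-1] == pytest.approx(jk.lower[3], abs=1e-10)
        assert jk.upper[-1] == pytest.approx(jk.upper[3], abs=1e-10)

    def test_too_few_rounds(self, default_xy):
        X, y = default_xy
        with pytest.raises(ModelError):
            jackknife_ci(X, y, n_folds=2)

    def test_null_flag_rate_near_alpha(self):
        """Under a no-effect generator the per-variable significance rate
        stays within a factor two of the nominal 5%."""
        rates = []
        for rep in range(200):
            cfg = SimConfig(seed=10_000 + rep, affected_down=0.0, affected_up=0.0,
                            dilution_sd=0.0, batch_shift_sd=0.0)
            table, meta, _, _ = generate_cohort(cfg)
            y = group_vector(table, meta)
            rates.append(jackknife_ci(table.areas, y).significant.mean())
        assert 0.025 <= np.mean(rates) <= 0.10, np.mean(rates)

    def test_planted_down_metabolite_ci_negative(self):
        """A strongly lowered metabolite gets an entirely negative CI in
        >= 80% of seeds at n=9+9."""
        hits = 0
        for seed in range(20):
            cfg = SimConfig(seed=700 + seed, effect_down=0.6)
            table, meta, _, truth = generate_cohort(cfg)
            y = group_vector(table, meta)
            jk = jackknife_ci(table.areas, y)
            j = table.metabolite_ids.index(
                [m for m, d in truth.direction.items() if d == "DOWN"][0])
            hits += jk.upper[j] < 0
        assert hits >= 16, hits
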