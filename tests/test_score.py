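"""Score computation, discrimination and calibration metrics."""

import numpy as np
import pytest

from grabld import (
    calibrate_linear,
    calibration_by_decile,
    compute_score,
    evaluate_auc,
    evaluate_r2,
    hosmer_lemeshow,
    mean_abs_difference,
)
from grabld.exceptions import UndefinedMetricError, ValidationError


def all_pairs_auc(score, labels):
    """Exhaustive case/control pair counting, ties counted half."""
    cases = score[labels == 1]
    controls = score[labels == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    return wins / (len(cases) * len(controls))


class TestComputeScore:
    def test_zero_weights_zero_scores(self, rng):
        X = rng.normal(size=(6, 4))
        np.testing.assert_array_equal(compute_score(X, np.zeros(4)).score, 0.0)

    def test_hand_computed_dot_products(self):
        X = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 1.0]])
        w = np.array([0.5, -1.0, 0.25])
        np.testing.assert_allclose(compute_score(X, w).score, [1.0, -0.75])

    def test_duplicated_snps_with_split_weight(self, rng):
        col = rng.normal(size=30)
        col = (col - col.mean()) / col.std()
        X = np.tile(col[:, None], (1, 5))
        scores = compute_score(X, np.full(5, 0.8 / 5)).score
        np.testing.assert_allclose(scores, col * 0.8, atol=1e-12)

    def test_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_score(np.ones((3, 2)), np.ones(3))


class TestR2:
    def test_perfect_predictor(self, rng):
        y = rng.normal(size=40)
        assert evaluate_r2(y, y) == pytest.approx(1.0)

    def test_independent_near_zero(self, rng):
        assert evaluate_r2(rng.normal(size=20000), rng.normal(size=20000)) < 0.001

    def test_fixed_vectors_textbook_formula(self):
        g = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0, 5.0])
        num = np.mean(g * y) - g.mean() * y.mean()
        expected = num**2 / (g.var() * y.var())
        assert evaluate_r2(g, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert evaluate_r2(np.ones(5), np.arange(5.0)) == 0.0

    def test_scale_invariance(self, rng):
        g = rng.normal(size=100)
        y = g + rng.normal(size=100)
        assert evaluate_r2(g, y) == pytest.approx(evaluate_r2(7.3 * g, y), abs=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        assert evaluate_auc(np.array([1, 2, 3, 10, 11]), np.array([0, 0, 0, 1, 1])) == 1.0

    def test_null_near_half(self, rng):
        score = rng.normal(size=20000)
        labels = rng.integers(0, 2, 20000)
        assert abs(evaluate_auc(score, labels) - 0.5) < 0.02

    def test_matches_all_pairs_with_tie(self):
        score = np.array([1.0, 2.0, 2.0, 4.0])
        labels = np.array([0, 0, 1, 1])
        assert evaluate_auc(score, labels) == pytest.approx(all_pairs_auc(score, labels))

    def test_matches_all_pairs_random(self, rng):
        score = rng.integers(0, 6, 40).astype(float)  # discrete: many ties
        labels = rng.integers(0, 2, 40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert evaluate_auc(score, labels) == pytest.approx(all_pairs_auc(score, labels))

    def test_label_flip_antisymmetry(self, rng):
        score = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        assert evaluate_auc(score, labels) == pytest.approx(1.0 - evaluate_auc(score, 1 - labels))

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            evaluate_auc(np.arange(4.0), np.ones(4))

    def test_scale_invariance(self, rng):
        score = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        assert evaluate_auc(score, labels) == evaluate_auc(3.0 * score, labels)


class TestLinearCalibration:
    def test_identity_fit(self, rng):
        y = rng.normal(size=30)
        cal = calibrate_linear(y, y)
        assert cal.slope == pytest.approx(1.0) and cal.intercept == pytest.approx(0.0, abs=1e-10)

    def test_inverse_scaling(self, rng):
        y = rng.normal(size=30)
        cal = calibrate_linear(2.0 * y, y)
        assert cal.slope == pytest.approx(0.5)

    def test_normal_equations_on_fixed_points(self):
        g = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = np.array([0.5, 1.1, 2.3, 2.8, 4.6, 4.9, 6.2, 7.4])
        design = np.column_stack([np.ones(8), g])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        cal = calibrate_linear(g, y)
        assert cal.intercept == pytest.approx(beta[0]) and cal.slope == pytest.approx(beta[1])

    def test_collinear_covariate_dropped(self, rng):
        g = rng.normal(size=40)
        y = g + rng.normal(size=40)
        cov = np.column_stack([rng.normal(size=40), 2.0 * g])  # second col collinear w/ score
        with pytest.warns(UserWarning, match="collinear"):
            cal = calibrate_linear(g, y, cov)
        assert cal.covariate_coefs[1] == 0.0

    def test_apply_reproduces_fit(self, rng):
        g = rng.normal(size=50)
        cov = rng.normal(size=(50, 2))
        y = 0.5 + 2.0 * g + cov @ [0.3, -0.2] + rng.normal(0, 0.01, 50)
        cal = calibrate_linear(g, y, cov)
        np.testing.assert_allclose(cal.apply(g, cov), y, atol=0.05)


class TestDecileCalibration:
    def test_perfect_calibration_zero_differences(self, rng):
        y = rng.normal(size=200)
        (table,) = calibration_by_decile(y, y)
        np.testing.assert_allclose(table["difference"], 0.0, atol=1e-12)
        assert table["n"].sum() == 200

    def test_constant_shift_moves_differences(self, rng):
        y = rng.normal(size=100)
        (ref,) = calibration_by_decile(y, y)
        (shifted,) = calibration_by_decile(y + 0.7, y)
        np.testing.assert_allclose(shifted["difference"], ref["difference"] - 0.7, atol=1e-12)

    def test_decile_conservation(self, rng):
        pred = rng.normal(size=137)
        obs = rng.normal(size=137)
        (table,) = calibration_by_decile(pred, obs)
        assert table["n"].sum() == 137
        weighted = (table["mean_observed"] * table["n"]).sum() / 137
        assert weighted == pytest.approx(obs.mean())

    def test_hl_statistic_two_bin_hand_sum(self):
        # two hand-specified bins: (O, E, n) = (3, 2.0, 10) and (7, 8.0, 10)
        stat, p, df = hosmer_lemeshow([3, 7], [2.0, 8.0], [10, 10], n_params_df=0)
        hand = (3 - 2.0) ** 2 / (2.0 * (1 - 0.2)) + (7 - 8.0) ** 2 / (8.0 * (1 - 0.8))
        assert stat == pytest.approx(hand)

    def test_binary_mode_returns_hl_on_8_df(self, rng):
        pred = rng.uniform(0.1, 0.9, 500)
        obs = (rng.random(500) < pred).astype(float)
        table, stat, pval, df = calibration_by_decile(pred, obs, binary=True)
        assert df == 8 and stat >= 0 and 0 <= pval <= 1

    def test_degenerate_bin_merged(self, rng):
        pred = np.r_[np.zeros(20), rng.uniform(0.2, 0.8, 80)]
        obs = (rng.random(100) < pred).astype(float)
        table, stat, pval, df = calibration_by_decile(pred, obs, binary=True)
        assert df < 8  # merged bins reduce G-2
        assert np.isfinite(stat)


class TestMeanAbsDifference:
    def test_zero_and_unit_shift(self, rng):
        y = rng.normal(size=25)
        assert mean_abs_difference(y, y) == 0.0
        assert mean_abs_difference(y + 1.0, y) == pytest.approx(1.0)

    def test_hand_computed_five_pairs(self):
        pred = np.array([0.0, 1.0, 2.0, -1.0, 0.5])
        obs = np.array([0.5, 1.0, 1.0, -2.0, 1.0])
        assert mean_abs_difference(pred, obs) == pytest.approx((0.5 + 0 + 1 + 1 + 0.5) / 5)


def test_r2_by_snp_fraction_monotone_n_and_full_match(rng):
    from grabld.score import r2_by_snp_fraction

    X = rng.normal(size=(300, 40))
    X = (X - X.mean(0)) / X.std(0)
    w = rng.normal(0, 0.05, 40)
    y = X @ w + rng.normal(0, 0.8, 300)
    table = r2_by_snp_fraction(X, w, y, order_by=np.abs(w), fractions=(0.1, 0.5, 1.0))
    assert list(table["n_snps"]) == [4, 20, 40]
    full = evaluate_r2(X @ w, y)
    assert table["r2"].iloc[-1] == pytest.approx(full)
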