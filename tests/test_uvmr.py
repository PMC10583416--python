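"""Univariable estimators against closed-form and brute-force oracles."""

import numpy as np
import pytest
from scipy.stats import norm

from medimr.exceptions import DomainError, InsufficientInstrumentsError
from medimr.uvmr import (UnivariableMR, cochran_q, egger, ivw, mode_estimate,
                         wald_ratio, weighted_median, _mode_point,
                         _ratio_weights, _weighted_median_point)

from conftest import hset, random_hset


def wls_origin_oracle(bx, by, sy):
    """Normal-equations solution of weighted regression through the origin."""
    w = 1 / np.asarray(sy, float) ** 2
    theta = np.sum(w * bx * by) / np.sum(w * np.asarray(bx) ** 2)
    se_fixed = np.sum(w * np.asarray(bx) ** 2) ** -0.5
    q = np.sum(w * (np.asarray(by) - theta * np.asarray(bx)) ** 2)
    return theta, se_fixed, q


def wls_intercept_oracle(bx, by, sy):
    """Normal-equations solution of weighted regression with intercept."""
    bx, by = np.asarray(bx, float), np.asarray(by, float)
    w = 1 / np.asarray(sy, float) ** 2
    design = np.column_stack([np.ones_like(bx), bx])
    a = design.T @ (w[:, None] * design)
    b = design.T @ (w * by)
    coef = np.linalg.solve(a, b)
    cov_unit = np.linalg.inv(a)
    q = np.sum(w * (by - design @ coef) ** 2)
    return coef, cov_unit, q


class TestWaldRatio:
    def test_basic_arithmetic(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_zero_numerator(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.02).theta == 0.0

    def test_joint_negation_invariance(self):
        a = wald_ratio(0.1, 0.01, 0.05, 0.02)
        b = wald_ratio(-0.1, 0.01, -0.05, 0.02)
        assert a.theta == b.theta and a.se == b.se

    def test_zero_denominator_error(self):
        with pytest.raises(DomainError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIVW:
    def test_single_variant_equals_wald(self):
        h = hset([0.1], [0.01], [0.05], [0.02])
        with pytest.warns(UserWarning):
            est = ivw(h)
        ref = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.theta == ref.theta and est.se == ref.se

    def test_collinear_pair(self):
        h = hset([0.1, 0.2], [0.01, 0.01], [0.05, 0.10], [0.1, 0.1])
        est = ivw(h)
        assert est.theta == pytest.approx(0.5)
        assert est.q == pytest.approx(0.0, abs=1e-25)
        fixed = ivw(h, effects_model="fixed")
        assert est.se == fixed.se  # dispersion floored at 1

    def test_two_point_hand_solution(self):
        h = hset([1, 1], [0.01, 0.01], [0, 1], [1, 1])
        est = ivw(h)
        assert est.theta == pytest.approx(0.5)
        assert est.q == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        h = random_hset(rng)
        theta, se_fixed, q = wls_origin_oracle(*[h.single(0)[i] for i in (0, 2, 3)])
        est = ivw(h, effects_model="fixed")
        assert est.theta == pytest.approx(theta, abs=1e-12)
        assert est.se == pytest.approx(se_fixed, abs=1e-12)
        assert est.q == pytest.approx(q, abs=1e-10)

    def test_random_se_never_below_fixed(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            h = random_hset(rng)
            assert ivw(h).se >= ivw(h, effects_model="fixed").se


class TestCochranQ:
    def test_perfect_fit(self):
        h = hset([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.10, 0.15], [0.02] * 3)
        q, p = cochran_q(h, 0.5)
        assert q == pytest.approx(0.0, abs=1e-28)
        assert p == pytest.approx(1.0)

    def test_se_scaling_quarters_q(self):
        h1 = hset([1, 1], [0.01] * 2, [0, 1], [1, 1])
        h2 = hset([1, 1], [0.01] * 2, [0, 1], [2, 2])
        assert cochran_q(h2, 0.5)[0] == pytest.approx(cochran_q(h1, 0.5)[0] / 4)


class TestEgger:
    def test_exact_recovery_on_constructed_data(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.3])
        by = 0.1 + 0.5 * bx
        h = hset(bx, [0.01] * 5, by, [0.02] * 5)
        est = egger(h)
        assert est.egger_intercept == pytest.approx(0.1, abs=1e-12)
        assert est.theta == pytest.approx(0.5, abs=1e-12)
        assert est.q == pytest.approx(0.0, abs=1e-20)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(3)
        h = random_hset(rng, j=6)
        bx, sx, by, sy = (a.copy() for a in h.single(0))
        bx[2] *= -1
        by[2] *= -1
        h_flip = hset(bx, sx, by, sy)
        a, b = egger(h), egger(h_flip)
        assert a.theta == pytest.approx(b.theta, abs=1e-14)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, abs=1e-14)

    def test_identical_ratios_give_zero_intercept(self):
        bx = np.array([0.05, 0.1, 0.2, 0.4])
        h = hset(bx, [0.01] * 4, 0.7 * bx, [0.02] * 4)
        est = egger(h)
        assert est.theta == pytest.approx(0.7, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            h = random_hset(rng)
            bx, _, by, sy = h.single(0)
            sign = np.where(bx < 0, -1, 1)
            coef, cov_unit, q = wls_intercept_oracle(bx * sign, by * sign, sy)
            disp = max(1.0, np.sqrt(q / (len(bx) - 2)))
            est = egger(h)
            assert est.egger_intercept == pytest.approx(coef[0], abs=1e-12)
            assert est.theta == pytest.approx(coef[1], abs=1e-12)
            assert est.se == pytest.approx(np.sqrt(cov_unit[1, 1]) * disp, abs=1e-12)

    def test_too_few_variants(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(hset([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.02] * 2))


def wm_bracket_oracle(ratios, weights):
    """Scan all adjacent cumulative-midpoint brackets for the 0.5 crossing."""
    order = np.argsort(ratios)
    th, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2
    if 0.5 <= s[0]:
        return th[0]
    for j in range(len(th) - 1):
        if s[j] <= 0.5 <= s[j + 1]:
            frac = (0.5 - s[j]) / (s[j + 1] - s[j])
            return th[j] + frac * (th[j + 1] - th[j])
    return th[-1]


class TestWeightedMedian:
    def test_equal_weights_is_median(self):
        h = hset([0.1] * 3, [0.001] * 3, [0.1, 0.2, 0.3], [0.02] * 3)
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.theta == pytest.approx(2.0)

    def test_dominant_weight_breakdown(self):
        # first variant carries ~97% of the weight (tiny outcome se)
        h = hset([0.1, 0.1, 0.1], [0.001] * 3, [0.1, 0.5, 0.9],
                 [0.01, 0.2, 0.2])
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.theta == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bracket_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = random_hset(rng, j=7)
        bx, _, by, sy = h.single(0)
        expected = wm_bracket_oracle(by / bx, _ratio_weights(bx, sy))
        assert _weighted_median_point(by / bx, _ratio_weights(bx, sy)) == \
            pytest.approx(expected, abs=1e-12)

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(4)
        h = random_hset(rng)
        a = weighted_median(h, n_boot=300, seed=42)
        b = weighted_median(h, n_boot=300, seed=42)
        assert a.se == b.se


def mode_grid_oracle(ratios, weights, phi, resolution=10_000):
    """Same kernel density evaluated on a 10x finer grid."""
    from scipy.stats import median_abs_deviation

    sd = np.std(ratios, ddof=1)
    mad = median_abs_deviation(ratios, scale="normal")
    b = phi * 0.9 * min(sd, mad) * len(ratios) ** (-0.2)
    grid = np.linspace(ratios.min() - 3 * b, ratios.max() + 3 * b, resolution)
    dens = (np.asarray(weights)[:, None]
            * norm.pdf((grid[None, :] - np.asarray(ratios)[:, None]) / b)).sum(0)
    return grid[np.argmax(dens)], (grid[-1] - grid[0])


class TestMode:
    def test_identical_ratios(self):
        h = hset([0.1, 0.2, 0.3], [0.001] * 3, [0.05, 0.10, 0.15], [0.02] * 3)
        est = mode_estimate(h, n_boot=100, seed=0)
        assert est.theta == pytest.approx(0.5)

    def test_bimodal_simple_mode_finds_larger_cluster(self):
        bx = np.full(9, 0.1)
        by = np.array([0.05] * 6 + [0.2] * 3) + \
            np.array([-0.002, -0.001, 0, 0.001, 0.002, 0.0005, -0.001, 0, 0.001])
        h = hset(bx, [0.001] * 9, by, [0.02] * 9)
        est = mode_estimate(h, weighted=False, n_boot=100, seed=0)
        assert est.theta == pytest.approx(0.5, abs=0.1)

    def test_weighted_mode_follows_the_weight(self):
        # 3-variant cluster at ratio 2.0 carries nearly all weight
        bx = np.full(9, 0.1)
        by = np.array([0.05] * 6 + [0.2] * 3) + \
            np.array([-0.002, -0.001, 0, 0.001, 0.002, 0.0005, -0.001, 0, 0.001])
        sy = np.array([0.5] * 6 + [0.005] * 3)
        h = hset(bx, [0.001] * 9, by, sy)
        est = mode_estimate(h, weighted=True, n_boot=100, seed=0)
        assert est.theta == pytest.approx(2.0, abs=0.1)

    @pytest.mark.parametrize("weighted", [False, True])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_fine_grid_oracle(self, weighted, seed):
        rng = np.random.default_rng(seed)
        h = random_hset(rng, j=9)
        bx, _, by, sy = h.single(0)
        ratios = by / bx
        w = _ratio_weights(bx, sy) if weighted else np.full(9, 1 / 9)
        coarse = _mode_point(ratios, w, 1.0)
        fine, span = mode_grid_oracle(ratios, w, 1.0)
        assert abs(coarse - fine) <= span / 999  # within one coarse-grid step


class TestInvarianceAndModel:
    @pytest.mark.parametrize("method", ["ivw", "egger", "weighted_median",
                                        "simple_mode", "weighted_mode"])
    def test_allele_orientation_invariance(self, method):
        """Jointly flipping one variant's betas must not move any estimator's
        point estimate (allele relabeling)."""
        rng = np.random.default_rng(8)
        h = random_hset(rng, j=8)
        bx, sx, by, sy = (a.copy() for a in h.single(0))
        bx[3] *= -1
        by[3] *= -1
        h_flip = hset(bx, sx, by, sy)
        kw = {} if method == "egger" else {"n_boot": 50, "seed": 0}
        if method == "ivw":
            kw = {}
        a = UnivariableMR(h).fit(method, **kw)
        b = UnivariableMR(h_flip).fit(method, **kw)
        assert a.theta == pytest.approx(b.theta, abs=1e-12)

    def test_fit_all_returns_requested_methods(self, homogeneous_hset):
        res = UnivariableMR(homogeneous_hset).fit_all(n_boot=100, seed=0)
        assert [e.method for e in res.estimates] == [
            "ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"]
        df = res.to_frame()
        assert len(df) == 5
        assert res["ivw"].theta == pytest.approx(0.5, abs=0.05)

    def test_ci_is_theta_plus_minus_1p96_se(self, homogeneous_hset):
        est = ivw(homogeneous_hset)
        assert est.ci_low == pytest.approx(est.theta - 1.96 * est.se)
        assert est.ci_high == pytest.approx(est.theta + 1.96 * est.se)
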