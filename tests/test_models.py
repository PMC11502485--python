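"""MR estimators against closed forms and independent WLS/median oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from stratmr.harmonize import HarmonizedSet
from stratmr.models import (
    egger_estimate,
    heterogeneity,
    ivw_estimate,
    penalized_weighted_median_estimate,
    penalized_weights,
    ratio_estimates,
    weighted_median_estimate,
)
from .conftest import make_hset, make_record


def wm_oracle(ratios, weights):
    """Brute-force weighted median: sorted prefix sums, manual interpolation."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    grid = []
    for r, w in pairs:
        grid.append(((cum + w / 2) / total, r))
        cum += w
    for (s0, r0), (s1, r1) in zip(grid, grid[1:]):
        if s0 <= 0.5 <= s1:
            return r0 + (r1 - r0) * (0.5 - s0) / (s1 - s0)
    return grid[0][1] if 0.5 < grid[0][0] else grid[-1][1]


class TestRatioEstimates:
    def test_direct_arithmetic(self):
        [r] = ratio_estimates(make_hset(bx=[0.2], by=[0.1], sy=[0.02]))
        assert r.ratio == pytest.approx(0.5)
        assert r.ratio_se == pytest.approx(0.1)
        assert r.weight == pytest.approx(100.0)

    def test_zero_outcome_effect_gives_zero_ratio(self):
        [r] = ratio_estimates(make_hset(bx=[0.2], by=[0.0], sy=[0.02]))
        assert r.ratio == 0.0

    def test_scale_invariance(self):
        a = ratio_estimates(make_hset(bx=[0.2], by=[0.1], sy=[0.02]))[0]
        b = ratio_estimates(make_hset(bx=[0.6], by=[0.3], sy=[0.02]))[0]
        assert a.ratio == pytest.approx(b.ratio)

    def test_zero_exposure_effect_excluded(self):
        hset = HarmonizedSet(records=[make_record(bx=0.0), make_record(vid="v2", bx=0.1)])
        assert [r.variant_id for r in ratio_estimates(hset)] == ["v2"]


class TestIVW:
    def test_single_instrument_reduces_to_wald_ratio(self):
        est = ivw_estimate(make_hset(bx=[0.2], by=[0.1], sy=[0.02]))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_exact_fit_gives_shared_ratio_and_zero_q(self):
        bx = np.array([0.1, 0.2, 0.3])
        est = ivw_estimate(make_hset(bx=bx, by=0.4 * bx, sy=[0.01, 0.02, 0.01]))
        assert est.beta == pytest.approx(0.4, rel=1e-12)
        assert est.Q == pytest.approx(0.0, abs=1e-20)
        fixed = ivw_estimate(make_hset(bx=bx, by=0.4 * bx, sy=[0.01, 0.02, 0.01]), random_effects=False)
        assert est.se == fixed.se  # no over-dispersion at exact fit

    def test_three_row_closed_form(self):
        est = ivw_estimate(
            make_hset(bx=[0.1, 0.2, 0.15], by=[0.02, 0.05, 0.03], sy=[0.01, 0.01, 0.02])
        )
        # weighted least squares through the origin: 131.25 / 556.25
        assert est.beta == pytest.approx(131.25 / 556.25, rel=1e-12)

    def test_no_instruments_is_structured_refusal(self):
        est = ivw_estimate(HarmonizedSet(records=[]))
        assert est.status == "no-instruments"
        assert np.isnan(est.beta)

    def test_matches_wls_oracle(self, rng):
        for _ in range(20):
            L = int(rng.integers(2, 51))
            bx = rng.normal(0.1, 0.05, L)
            by = rng.normal(0.02, 0.05, L)
            sy = rng.uniform(0.005, 0.05, L)
            est = ivw_estimate(make_hset(bx=bx, by=by, sy=sy), random_effects=False)
            fit = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
            assert est.beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_equivariant_under_instrument_order(self, rng):
        bx = rng.normal(0.1, 0.05, 10)
        by = rng.normal(0.02, 0.05, 10)
        sy = rng.uniform(0.005, 0.05, 10)
        perm = rng.permutation(10)
        a = ivw_estimate(make_hset(bx=bx, by=by, sy=sy))
        b = ivw_estimate(make_hset(bx=bx[perm], by=by[perm], sy=sy[perm]))
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)


class TestEgger:
    def test_exact_fit_recovers_intercept_and_slope(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        est = egger_estimate(make_hset(bx=bx, by=0.05 + 0.3 * bx, sy=[0.01] * 4))
        assert est.intercept == pytest.approx(0.05, rel=1e-10)
        assert est.beta == pytest.approx(0.3, rel=1e-10)
        assert est.Q == pytest.approx(0.0, abs=1e-18)

    def test_two_instruments_refused(self):
        est = egger_estimate(make_hset(bx=[0.1, 0.2], by=[0.01, 0.02], sy=[0.01] * 2))
        assert est.status == "insufficient-instruments"
        assert np.isnan(est.beta)

    def test_matches_wls_oracle_with_intercept(self, rng):
        for _ in range(20):
            L = int(rng.integers(3, 51))
            bx = np.abs(rng.normal(0.1, 0.05, L))
            by = rng.normal(0.02, 0.05, L)
            sy = rng.uniform(0.005, 0.05, L)
            est = egger_estimate(make_hset(bx=bx, by=by, sy=sy))
            fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
            assert est.intercept == pytest.approx(fit.params[0], rel=1e-9)
            assert est.beta == pytest.approx(fit.params[1], rel=1e-9)
            # statsmodels uses scale Q/(L-2); our se floors that scale at 1
            scale = max(1.0, np.sqrt(est.Q / (L - 2)))
            assert est.se == pytest.approx(fit.bse[1] / np.sqrt(fit.scale) * scale, rel=1e-9)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        est = weighted_median_estimate(
            make_hset(bx=[1.0, 1.0, 1.0], by=[0.1, 0.5, 0.9], sy=[0.1] * 3), n_boot=100
        )
        assert est.beta == pytest.approx(0.5)

    def test_single_instrument_returns_its_ratio(self):
        est = weighted_median_estimate(make_hset(bx=[0.2], by=[0.1], sy=[0.02]), n_boot=100)
        assert est.beta == pytest.approx(0.5)

    def test_matches_prefix_sum_oracle(self):
        bx = np.ones(4)
        by = np.array([0.1, 0.3, 0.5, 0.9])
        sy = np.array([0.1, 0.2, 0.05, 0.1])
        est = weighted_median_estimate(make_hset(bx=bx, by=by, sy=sy), n_boot=100)
        expected = wm_oracle(list(by), list(1 / sy**2))
        assert expected == pytest.approx(0.4882352941176471, rel=1e-12)  # frozen oracle value
        assert est.beta == pytest.approx(expected, rel=1e-12)

    def test_bootstrap_se_reproducible(self):
        hset = make_hset(bx=np.ones(5), by=[0.1, 0.2, 0.3, 0.4, 0.5], sy=[0.05] * 5)
        a = weighted_median_estimate(hset, n_boot=200, seed=42)
        b = weighted_median_estimate(hset, n_boot=200, seed=42)
        assert a.se == b.se


class TestPenalizedWeightedMedian:
    def test_homogeneous_ratios_equal_wm(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        hset = make_hset(bx=bx, by=0.3 * bx, sy=[0.01] * 4)
        wm = weighted_median_estimate(hset, n_boot=100, seed=0)
        pwm = penalized_weighted_median_estimate(hset, n_boot=100, seed=0)
        assert pwm.beta == pytest.approx(wm.beta, rel=1e-12)

    def test_penalty_factor_bounded(self, rng):
        bx = np.abs(rng.normal(0.2, 0.05, 12))
        by = rng.normal(0.05, 0.05, 12)
        hset = make_hset(bx=bx, by=by, sy=rng.uniform(0.005, 0.02, 12))
        for raw, penalized in penalized_weights(hset).values():
            assert 0 < penalized <= raw

    def test_gross_outlier_downweighted_and_estimate_robust(self):
        bx = np.ones(11)
        by = np.array([0.2] * 10 + [5.0])
        sy = np.full(11, 0.05)
        hset = make_hset(bx=bx, by=by, sy=sy)
        weights = penalized_weights(hset)
        raw, pen = weights["v11"]
        assert pen < raw
        wm = weighted_median_estimate(hset, n_boot=100, seed=0).beta
        pwm = penalized_weighted_median_estimate(hset, n_boot=100, seed=0).beta
        assert abs(pwm - 0.2) <= abs(wm - 0.2)


class TestHeterogeneity:
    def test_identical_ratios_no_heterogeneity(self):
        bx = np.array([0.1, 0.2, 0.3])
        Q, Q_pval, I2 = heterogeneity(make_hset(bx=bx, by=0.5 * bx, sy=[0.01] * 3), "IVW")
        assert Q == pytest.approx(0.0, abs=1e-18)
        assert I2 == 0.0
        assert Q_pval == pytest.approx(1.0)

    def test_i2_floored_at_zero_when_q_below_df(self):
        est = ivw_estimate(
            make_hset(bx=[0.1, 0.2, 0.3], by=[0.0501, 0.1, 0.15], sy=[0.05] * 3)
        )
        assert est.Q < 2
        assert est.I2 == 0.0

    def test_q_matches_direct_summation(self):
        bx = np.array([0.1, 0.2, 0.15])
        by = np.array([0.02, 0.05, 0.03])
        sy = np.array([0.01, 0.01, 0.02])
        est = ivw_estimate(make_hset(bx=bx, by=by, sy=sy))
        w = 1 / sy**2
        beta = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert est.Q == pytest.approx(float(np.sum(w * (by - beta * bx) ** 2)), rel=1e-12)
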