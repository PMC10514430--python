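"""Two-sample estimators: closed-form hand computations, Monte-Carlo and
weighted-least-squares oracles, robustness and routing behaviour."""

import numpy as np
import pandas as pd
import pytest

import targetmr as tm
from targetmr.harmonize import HARMONIZED_COLUMNS, HarmonizedTable
from targetmr.mr2s import (
    _mode_point, _weighted_median, cochran_q, ivw, leave_one_out, mode_estimator,
    scale_estimate, wald_ratio, weighted_median,
)


def table_from_arrays(bx, sx, by, sy, outcome_type="continuous"):
    k = len(bx)
    df = pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(k)], "proxy_snp": "",
        "EA": "A", "OA": "G",
        "beta_exposure": bx, "se_exposure": sx, "eaf_exposure": 0.3,
        "beta_outcome": by, "se_outcome": sy, "eaf_outcome": 0.3,
        "action": "kept"}, columns=HARMONIZED_COLUMNS)
    return HarmonizedTable("exposure", "outcome", df, outcome_type=outcome_type, oriented=True)


class TestWaldRatio:
    def test_zero_outcome_effect(self):
        est = wald_ratio(0.5, 0.01, 0.0, 0.05)
        assert est.beta == 0.0
        assert est.se == pytest.approx(0.05 / 0.5)

    def test_se_matches_monte_carlo_propagation(self):
        bx, sx, by, sy = 0.5, 0.01, 0.2, 0.05
        est = wald_ratio(bx, sx, by, sy)
        assert est.beta == pytest.approx(0.4)
        rng = np.random.default_rng(42)
        draws = (by + sy * rng.standard_normal(1_000_000)) / (bx + sx * rng.standard_normal(1_000_000))
        assert est.se == pytest.approx(draws.std(), rel=0.02)

    def test_scale_equivariance(self):
        a = wald_ratio(0.5, 0.01, 0.2, 0.05)
        b = wald_ratio(1.0, 0.02, 0.2, 0.05)
        assert b.beta == pytest.approx(a.beta / 2)
        assert b.se == pytest.approx(a.se / 2)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.2, 0.05)

    def test_simple_se_option(self):
        est = wald_ratio(0.5, 0.01, 0.2, 0.05, first_order=False)
        assert est.se == pytest.approx(0.05 / 0.5)


class TestIVW:
    def test_two_identical_ratios(self):
        tbl = table_from_arrays([1.0, 1.0], [0.0, 0.0], [-0.3, -0.3], [0.1, 0.1])
        fixed = ivw(tbl, "fixed")
        rand = ivw(tbl, "multiplicative_random")
        assert fixed.beta == pytest.approx(-0.3)
        assert fixed.q == pytest.approx(0.0, abs=1e-12)
        assert rand.se == pytest.approx(fixed.se)

    def test_closed_form_hand_computation(self):
        tbl = table_from_arrays([1.0, 1.0], [0.0, 0.0], [-0.2, -0.4], [0.1, 0.1])
        est = ivw(tbl, "fixed")
        assert est.beta == pytest.approx(-0.3)
        assert est.se == pytest.approx(0.1 / np.sqrt(2))  # 0.0707...
        assert est.q == pytest.approx(2.0)

    def test_single_variant_routes_to_wald(self):
        tbl = table_from_arrays([0.5], [0.01], [0.2], [0.05])
        est = ivw(tbl)
        assert est.method == "Wald ratio"
        assert est.beta == pytest.approx(0.4)

    def test_matches_wls_through_origin_when_exposure_noiseless(self):
        """No-measurement-error limit: IVW fixed equals the weighted
        least-squares slope of beta_out on beta_exp with weights 1/se_out²."""
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        k = 25
        bx = rng.uniform(0.05, 0.3, k)
        by = -0.3 * bx + rng.normal(0, 0.01, k)
        sy = rng.uniform(0.005, 0.02, k)
        tbl = table_from_arrays(bx, np.zeros(k), by, sy)
        est = ivw(tbl, "fixed")
        wls = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        assert est.beta == pytest.approx(float(wls.params[0]), abs=1e-10)

    def test_additive_random_effects_available(self):
        tbl = table_from_arrays([1.0, 1.0, 1.0], [0.0] * 3, [-0.1, -0.5, -0.9], [0.05] * 3)
        add = ivw(tbl, "additive_random")
        fixed = ivw(tbl, "fixed")
        assert add.se > fixed.se

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.1, 0.3, 10)
        by = -0.2 * bx + rng.normal(0, 0.01, 10)
        tbl = table_from_arrays(bx, np.full(10, 0.005), by, np.full(10, 0.01))
        perm = rng.permutation(10)
        shuffled = HarmonizedTable("e", "o", tbl.df.iloc[perm].reset_index(drop=True), oriented=True)
        assert ivw(tbl).beta == pytest.approx(ivw(shuffled).beta, abs=1e-14)


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        tbl = table_from_arrays([1.0, 1.0], [0.0, 0.0], [-0.3, -0.3], [0.1, 0.1])
        q, df, p = cochran_q(tbl)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_outlier_increases_q(self):
        base = table_from_arrays([1.0] * 3, [0.0] * 3, [-0.3, -0.31, -0.29], [0.1] * 3)
        spiked = table_from_arrays([1.0] * 4, [0.0] * 4, [-0.3, -0.31, -0.29, 0.8], [0.1] * 4)
        assert cochran_q(spiked)[0] > cochran_q(base)[0]


class TestWeightedMedian:
    def test_all_ratios_equal(self):
        tbl = table_from_arrays([1.0] * 4, [1e-6] * 4, [-0.25] * 4, [0.01] * 4)
        est = weighted_median(tbl, n_boot=200, seed=1)
        assert est.beta == pytest.approx(-0.25)
        assert est.se < 0.05

    def test_breakdown_robustness(self):
        r = np.array([1.0, 1.0, 1.0, 1.0, 100.0])
        assert _weighted_median(r, np.ones(5)) == pytest.approx(1.0)

    def test_interpolation_convention(self):
        # ratios 1,2,3 with weights 0.25, 0.5, 0.25: cumulative midpoints
        # 0.125, 0.5, 0.875 -> median exactly 2
        assert _weighted_median(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 1.0])) == pytest.approx(2.0)

    def test_requires_three_variants(self):
        tbl = table_from_arrays([1.0, 1.0], [0.0] * 2, [0.1, 0.1], [0.05] * 2)
        with pytest.raises(ValueError):
            weighted_median(tbl)

    def test_bootstrap_se_reproducible(self):
        tbl = tm.simulate_harmonized_table(k=20, true_effect=-0.3, seed=4)
        a = weighted_median(tbl, n_boot=200, seed=7)
        b = weighted_median(tbl, n_boot=200, seed=7)
        assert a.se == b.se


class TestModeEstimator:
    def test_tight_cluster(self):
        rng = np.random.default_rng(0)
        by = -0.25 + rng.normal(0, 0.005, 10)
        tbl = table_from_arrays(np.ones(10), np.zeros(10), by, np.full(10, 0.02))
        est = mode_estimator(tbl, weighted=True, n_boot=100, seed=2)
        assert est.beta == pytest.approx(-0.25, abs=0.02)

    def test_bimodal_majority_wins(self):
        by = np.array([-0.3] * 6 + [0.2] * 4) + np.random.default_rng(5).normal(0, 0.01, 10)
        tbl = table_from_arrays(np.ones(10), np.zeros(10), by, np.full(10, 0.02))
        est = mode_estimator(tbl, weighted=False, n_boot=100, seed=3)
        assert est.beta == pytest.approx(-0.3, abs=0.05)

    def test_weighting_pulls_towards_precise_cluster(self):
        # minority cluster has much smaller ses: weighted mode favours it,
        # simple mode stays with the majority
        by = np.array([-0.3] * 5 + [0.2] * 4)
        sy = np.array([0.05] * 5 + [0.005] * 4)
        tbl = table_from_arrays(np.ones(9), np.zeros(9), by, sy)
        simple = mode_estimator(tbl, weighted=False, n_boot=50, seed=1)
        weighted = mode_estimator(tbl, weighted=True, n_boot=50, seed=1)
        assert simple.beta == pytest.approx(-0.3, abs=0.05)
        assert weighted.beta == pytest.approx(0.2, abs=0.05)

    def test_identical_ratios_degenerate_bandwidth(self):
        tbl = table_from_arrays([1.0] * 3, [0.0] * 3, [-0.4] * 3, [0.05] * 3)
        est = mode_estimator(tbl, n_boot=50, seed=0)
        assert est.beta == pytest.approx(-0.4)


class TestLeaveOneOut:
    def test_row_count_and_influence(self):
        by = np.array([-0.3, -0.29, -0.31, -0.3, 0.6])
        tbl = table_from_arrays(np.ones(5), np.zeros(5), by, np.full(5, 0.05))
        loo, single = leave_one_out(tbl)
        assert len(loo) == 5 and len(single) == 5
        full = ivw(tbl, "fixed").beta
        moves = (loo["b"] - full).abs()
        assert loo.loc[moves.idxmax(), "omitted"] == "rs4"

    def test_homogeneous_loo_stays_close(self):
        tbl = tm.simulate_harmonized_table(k=20, true_effect=-0.22, seed=9)
        loo, _ = leave_one_out(tbl)
        full = ivw(tbl, "fixed")
        assert ((loo["b"] - full.beta).abs() <= full.se).all()


class TestScaleEstimate:
    def test_or_transform(self):
        est = tm.MREstimate("IVW", np.log(0.62), 0.1, np.log(0.62) - 0.196, np.log(0.62) + 0.196,
                            0.01, 10)
        scaled = scale_estimate(est, outcome_type="binary")
        assert scaled.odds_ratio == pytest.approx(0.62)
        assert scaled.percent_risk_change == pytest.approx(100 * (1 - 0.62))
        assert scaled.or_ci_low == pytest.approx(np.exp(est.ci_low))
        assert scaled.or_ci_high == pytest.approx(np.exp(est.ci_high))

    def test_null_effect(self):
        est = tm.MREstimate("IVW", 0.0, 0.1, -0.196, 0.196, 1.0, 10)
        scaled = scale_estimate(est, outcome_type="binary")
        assert scaled.odds_ratio == pytest.approx(1.0)
        assert scaled.percent_risk_change == pytest.approx(0.0)

    def test_continuous_untouched_numerically(self):
        est = tm.MREstimate("IVW", -0.22, 0.05, -0.318, -0.122, 1e-5, 34)
        scaled = scale_estimate(est)
        assert scaled.beta == est.beta
        assert "0.62" in scaled.unit


class TestConsistencySuite:
    def test_estimators_agree_under_valid_instruments(self):
        tbl = tm.simulate_harmonized_table(k=50, true_effect=-0.3, seed=12)
        iv_est = ivw(tbl)
        med = weighted_median(tbl, n_boot=300, seed=1)
        mode = mode_estimator(tbl, n_boot=300, seed=2)
        for a in (iv_est, med, mode):
            for b in (iv_est, med, mode):
                joint = np.hypot(a.se, b.se)
                assert abs(a.beta - b.beta) < 2 * joint + 1e-9
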