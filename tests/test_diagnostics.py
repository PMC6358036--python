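"""Heterogeneity, MR-Egger, weighted median/mode, funnel data, subset reruns."""

import numpy as np
import pytest

from conftest import make_instruments
from mrkit.diagnostics import (
    EggerRegression,
    WeightedMedianEstimator,
    WeightedModeEstimator,
    cochran_q,
    funnel_data,
    i2_gx,
    subset_rerun,
    weighted_median,
    weighted_mode,
)
from mrkit.estimators import IVWEstimator
from mrkit.exceptions import EstimationError, MrKitError
from mrkit.simulate import SimulationConfig, simulate_two_sample


class TestCochranQ:
    def test_homogeneous_estimates_give_zero(self):
        res = cochran_q([(0.4, 0.1), (0.4, 0.2), (0.4, 0.3)], 0.4)
        assert res.Q == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.df == 2

    def test_worked_example(self):
        res = cochran_q([(0.5, 0.2), (0.3, 0.1)], 0.34)
        assert res.Q == pytest.approx(0.8, rel=1e-12)
        assert res.df == 1
        assert res.p == pytest.approx(0.3711, abs=5e-5)

    def test_doubling_ses_quarters_q(self):
        pairs = [(0.5, 0.2), (0.3, 0.1), (0.45, 0.15)]
        doubled = [(t, 2 * s) for t, s in pairs]
        assert cochran_q(doubled, 0.34).Q == pytest.approx(cochran_q(pairs, 0.34).Q / 4)

    def test_requires_two_instruments(self):
        with pytest.raises(EstimationError):
            cochran_q([(0.5, 0.2)], 0.5)


class TestI2GX:
    def test_equal_gammas_give_zero(self):
        assert i2_gx([0.1, 0.1, 0.1], [0.01, 0.02, 0.01]) == 0.0

    def test_worked_example(self):
        assert i2_gx([0.1, 0.2], [0.01, 0.01]) == pytest.approx(0.98, rel=1e-12)

    def test_vanishing_measurement_error_limit(self):
        assert i2_gx([0.1, 0.2, 0.3], [1e-9, 1e-9, 1e-9]) == pytest.approx(1.0, abs=1e-12)


class TestEgger:
    def test_exact_line_recovered(self):
        gammas = np.array([0.05, 0.08, 0.1, 0.14, 0.2])
        inst = make_instruments(
            gammas, np.full(5, 0.01), 0.01 + 0.5 * gammas, np.full(5, 0.02)
        )
        eg = EggerRegression().fit(inst)
        assert eg.intercept_ == pytest.approx(0.01, abs=1e-12)
        assert eg.theta_ == pytest.approx(0.5, abs=1e-10)

    def test_matches_statsmodels_wls(self, instruments):
        import statsmodels.api as sm

        eg = EggerRegression().fit(instruments)
        X = sm.add_constant(np.abs(instruments.gamma_hat))
        wls = sm.WLS(
            np.sign(instruments.gamma_hat) * instruments.Gamma_hat,
            X,
            weights=1.0 / instruments.sigma_y**2,
        ).fit()
        assert eg.intercept_ == pytest.approx(wls.params[0], rel=1e-10)
        assert eg.theta_ == pytest.approx(wls.params[1], rel=1e-10)

    def test_slope_equals_ivw_when_intercept_constrained(self, instruments):
        """Dropping the intercept on the same 1/sigma_y^2 weights is simple IVW."""
        ivw = IVWEstimator(weighting="simple").fit(instruments)
        g, G, w = instruments.gamma_hat, instruments.Gamma_hat, 1.0 / instruments.sigma_y**2
        slope = np.sum(w * g * G) / np.sum(w * g * g)
        assert slope == pytest.approx(ivw.theta_, rel=1e-12)

    def test_negative_gammas_reoriented(self):
        gammas = np.array([0.05, -0.08, 0.1, -0.14, 0.2])
        inst = make_instruments(
            gammas, np.full(5, 0.01), 0.5 * gammas + np.sign(gammas) * 0.01, np.full(5, 0.02)
        )
        eg = EggerRegression().fit(inst)
        assert eg.extras_["n_reoriented"] == 2
        assert eg.intercept_ == pytest.approx(0.01, abs=1e-12)
        assert eg.theta_ == pytest.approx(0.5, abs=1e-10)

    def test_requires_three_instruments(self):
        inst = make_instruments([0.1, 0.2], [0.01, 0.01], [0.05, 0.1], [0.02, 0.02])
        with pytest.raises(EstimationError):
            EggerRegression().fit(inst)

    def test_null_intercept_under_balanced_pleiotropy(self):
        """With mean-zero pleiotropy and InSIDE the intercept centers on 0."""
        n_reps = 300
        intercepts = np.empty(n_reps)
        seeds = np.random.SeedSequence(271).generate_state(n_reps)
        for i, s in enumerate(seeds):
            cfg = SimulationConfig(
                theta=0.5, pleiotropy="balanced", pleiotropy_sd=0.01,
                gamma_sd=0.02, n_exp=5_000_000, seed=int(s) & 0x7FFFFFFF,
            )
            inst = simulate_two_sample(cfg).to_instrument_set()
            intercepts[i] = EggerRegression().fit(inst).intercept_
        mc_se = intercepts.std(ddof=1) / np.sqrt(n_reps)
        assert abs(intercepts.mean()) < 3 * mc_se


class TestWeightedMedian:
    def test_equal_weights_odd_k_is_middle_ratio(self):
        est = weighted_median([(0.2, 0.1), (0.6, 0.1), (0.4, 0.1)])
        assert est.theta == pytest.approx(0.4)

    def test_interpolation_worked_example(self):
        # weights proportional to (1, 1, 2) via se = (1, 1, 1/sqrt(2))
        est = weighted_median([(0.2, 1.0), (0.4, 1.0), (0.6, 1 / np.sqrt(2))])
        assert est.theta == pytest.approx(0.4667, abs=5e-5)

    def test_outlier_with_tiny_weight_is_ignored(self):
        base = [(0.48, 0.05), (0.5, 0.05), (0.52, 0.05), (0.49, 0.05), (0.51, 0.05)]
        spiked = base + [(25.0, 50.0)]
        a = weighted_median(base).theta
        b = weighted_median(spiked).theta
        assert abs(a - b) < 0.01

    def test_bootstrap_se_reproducible_and_stable(self, instruments):
        a = WeightedMedianEstimator(n_bootstrap=1000, random_state=5).fit(instruments)
        b = WeightedMedianEstimator(n_bootstrap=1000, random_state=5).fit(instruments)
        assert a.se_ == b.se_  # bit-for-bit given the seed
        big = WeightedMedianEstimator(n_bootstrap=2000, random_state=5).fit(instruments)
        assert abs(big.se_ - a.se_) / a.se_ < 0.05

    def test_requires_three_instruments(self):
        with pytest.raises(EstimationError):
            weighted_median([(0.2, 0.1), (0.4, 0.1)])


class TestWeightedMode:
    def test_degenerate_density_returns_common_value(self):
        est = weighted_mode([(0.5, 0.1), (0.5, 0.2), (0.5, 0.3)])
        assert est.theta == pytest.approx(0.5)

    def test_plurality_cluster_wins(self):
        rng = np.random.default_rng(1)
        cluster = [(0.5 + rng.normal(0, 0.01), 0.05) for _ in range(7)]
        outliers = [(1.5 + rng.normal(0, 0.01), 0.07) for _ in range(2)]
        est = weighted_mode(cluster + outliers)
        assert abs(est.theta - 0.5) < 0.05

    def test_mode_stays_in_data_range_when_bandwidth_halved(self, instruments):
        ratios = IVWEstimator().fit(instruments).extras_["ratios"]
        for phi in (1.0, 0.5, 0.25):
            est = WeightedModeEstimator(bandwidth_factor=phi, n_bootstrap=50).fit(instruments)
            assert ratios.min() <= est.theta_ <= ratios.max()

    def test_rejects_nonpositive_bandwidth(self, instruments):
        with pytest.raises(EstimationError):
            WeightedModeEstimator(bandwidth_factor=0.0).fit(instruments)


class TestFunnelData:
    def test_one_row_per_snp(self, instruments):
        ivw = IVWEstimator().fit(instruments)
        pairs = list(zip(ivw.extras_["ratios"], ivw.extras_["ratio_ses"]))
        tbl = funnel_data(pairs, snp_ids=instruments.snp_ids)
        assert len(tbl) == len(instruments)
        assert set(tbl.columns) == {"snp_id", "theta", "precision"}

    def test_symmetric_estimates_have_flat_precision_trend(self):
        """Under homogeneity the estimate is uncorrelated with precision."""
        rng = np.random.default_rng(2)
        reps = 200
        slopes = np.empty(reps)
        for i in range(reps):
            ses = rng.uniform(0.05, 0.3, 30)
            thetas = 0.5 + ses * rng.standard_normal(30)
            tbl = funnel_data(list(zip(thetas, ses)))
            slopes[i] = np.polyfit(tbl["precision"], tbl["theta"], 1)[0]
        assert abs(slopes.mean()) < 3 * slopes.std(ddof=1) / np.sqrt(reps)

    def test_single_snp(self):
        assert len(funnel_data([(0.4, 0.1)])) == 1


class TestSubsetRerun:
    def test_keep_all_matches_full_fit(self, instruments):
        tbl = subset_rerun(instruments, instruments.snp_ids, methods=("ivw",))
        full = IVWEstimator().fit(instruments)
        assert tbl.loc[0, "theta"] == pytest.approx(full.theta_)
        assert tbl.loc[0, "se"] == pytest.approx(full.se_)

    def test_subset_loses_information(self):
        study = simulate_two_sample(SimulationConfig(k=30, theta=0.3, seed=21))
        inst = study.to_instrument_set()
        full = IVWEstimator().fit(inst)
        sub = subset_rerun(inst, inst.snp_ids[:14], methods=("ivw",))
        assert sub.loc[0, "se"] > full.se_
        assert full.ci_low_ <= sub.loc[0, "theta"] <= full.ci_high_

    def test_too_small_subset_degrades_gracefully(self, instruments):
        tbl = subset_rerun(
            instruments, instruments.snp_ids[:1], methods=("wald", "egger", "weighted_median")
        )
        assert tbl.loc[tbl["method"] == "wald", "error"].iloc[0] == ""
        for method in ("egger", "weighted_median"):
            row = tbl.loc[tbl["method"] == method].iloc[0]
            assert "3 instruments" in row["error"] and np.isnan(row["theta"])

    def test_unknown_snp_errors(self, instruments):
        with pytest.raises(MrKitError, match="rs_nope"):
            subset_rerun(instruments, ["rs_nope"])
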