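"""Summary-level MR estimators: CI conversion, unit scaling, Wald ratio,
IVW, MR-Egger, weighted median and the allele-score IV estimator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vitdmr as v
from vitdmr import presets
from vitdmr.mr import _weighted_median


class TestCiToSe:
    def test_printed_european_estimate(self):
        # hand computation: (ln 0.87 - ln 0.79) / (2 * 1.959964) = 0.0246076
        se = v.ci_to_se(0.83, 0.79, 0.87)
        assert np.isclose(se, 0.0246076, atol=1e-6)

    def test_degenerate_ci_flagged(self):
        with pytest.warns(UserWarning):
            assert v.ci_to_se(1.0, 1.0, 1.0) == 0.0

    def test_roundtrip_identity(self):
        beta, se = -0.17, 0.033
        est = v.Estimate(beta=beta, se=se, unit="per-25-nmol/l", method="x")
        back = v.ci_to_se(est.odds_ratio, est.ci_low, est.ci_high)
        assert abs(back - se) < 1e-12

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            v.ci_to_se(0.9, -0.1, 1.0)
        with pytest.raises(ValueError):
            v.ci_to_se(0.9, 0.95, 1.0)


class TestScalePer25:
    def test_synthesis_score_arithmetic(self):
        # per-allele OR 0.97 with a 2.87 nmol/l score effect:
        # exp(25 ln 0.97 / 2.87) = 0.76695
        est = v.scale_per_25(np.log(0.97), 0.02, 2.87)
        assert np.isclose(est.odds_ratio, 0.76695, atol=5e-4)

    def test_unit_exposure_effect_leaves_estimate_unchanged(self):
        est = v.scale_per_25(-0.1, 0.05, 25.0)
        assert est.beta == -0.1 and est.se == 0.05

    def test_null_is_scale_invariant(self):
        for bx in (0.5, 2.87, 10.0):
            assert v.scale_per_25(0.0, 0.02, bx).odds_ratio == 1.0

    def test_refuses_unoriented_exposure(self):
        with pytest.raises(v.OrientationError):
            v.scale_per_25(-0.1, 0.05, -2.84)


class TestWaldRatio:
    def _instr(self, bx, by, sx=0.4, sy=0.02):
        return v.HarmonizedInstrument("rs", bx, sx, by, sy)

    def test_null_outcome_gives_null_estimate(self):
        res = v.wald_ratio(self._instr(0.95, 0.0))
        assert res.estimate.beta == 0.0

    def test_transport_snp_arithmetic(self):
        # per-allele OR 1.01 over beta_X = 3.59: exp(25 ln 1.01 / 3.59) = 1.0717
        res = v.wald_ratio(self._instr(3.59, np.log(1.01)))
        assert np.isclose(res.estimate.odds_ratio, 1.0717, atol=5e-4)

    def test_weak_instrument_refused(self):
        with pytest.raises(v.WeakInstrumentError):
            v.wald_ratio(self._instr(0.05, 0.01))

    def test_second_order_se_larger(self):
        first = v.wald_ratio(self._instr(2.84, -0.02))
        second = v.wald_ratio(self._instr(2.84, -0.02), second_order=True)
        assert second.estimate.se > first.estimate.se

    def test_common_scaling_of_both_sides_cancels(self):
        a = v.wald_ratio(self._instr(2.84, -0.02, 0.4, 0.02))
        c = 3.7
        b = v.wald_ratio(self._instr(2.84 * c, -0.02 * c, 0.4, 0.02 * c))
        assert np.isclose(a.estimate.beta, b.estimate.beta, rtol=1e-12)
        assert np.isclose(a.estimate.se, b.estimate.se, rtol=1e-12)


class TestIvw:
    def test_identical_pair(self):
        res = v.ivw([(-0.1, 0.05), (-0.1, 0.05)])
        assert np.isclose(res.estimate.beta, -0.1)
        assert np.isclose(res.estimate.se, 0.05 / np.sqrt(2))
        assert np.isclose(res.heterogeneity_q, 0.0)

    def test_requires_two_estimates(self):
        with pytest.raises(ValueError):
            v.ivw([(-0.1, 0.05)])

    def test_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            v.ivw([(-0.1, 0.05), (0.0, 0.0)])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_wls_oracle(self, seed):
        # intercept-free WLS of beta_i on 1 with weights 1/se^2 is the oracle
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 12))
        betas = rng.normal(0, 0.3, k)
        ses = rng.uniform(0.01, 0.5, k)
        res = v.ivw(zip(betas, ses))
        oracle = sm.WLS(betas, np.ones(k), weights=1.0 / ses**2).fit()
        assert np.isclose(res.estimate.beta, oracle.params[0], rtol=1e-10)


class TestEgger:
    def _line_instruments(self, slope, intercept=0.0, ses=(0.01, 0.02, 0.015, 0.03)):
        bxs = [2.84, 0.95, 3.59, 0.51]
        return [
            v.HarmonizedInstrument(f"rs{i}", bx, 0.4, intercept + slope * bx, se)
            for i, (bx, se) in enumerate(zip(bxs, ses))
        ]

    def test_exact_line_through_origin(self):
        slope_res, int_res = v.egger(self._line_instruments(-0.006))
        assert np.isclose(int_res.estimate.beta, 0.0, atol=1e-12)
        assert np.isclose(slope_res.estimate.beta, 25 * -0.006, atol=1e-10)

    def test_recovers_free_intercept(self):
        slope_res, int_res = v.egger(self._line_instruments(-0.006, 0.03))
        assert np.isclose(int_res.estimate.beta, 0.03, atol=1e-10)
        assert np.isclose(slope_res.estimate.beta, -0.15, atol=1e-10)

    def test_refuses_two_instruments(self):
        with pytest.raises(ValueError):
            v.egger(self._line_instruments(-0.006)[:2])

    def test_equal_weights_match_ols_oracle(self):
        rng = np.random.default_rng(11)
        bxs = [2.84, 0.95, 3.59, 0.51, 1.7]
        instrs = [
            v.HarmonizedInstrument(
                f"rs{i}", bx, 0.4, float(rng.normal(-0.005 * bx, 0.01)), 0.02
            )
            for i, bx in enumerate(bxs)
        ]
        slope_res, int_res = v.egger(instrs)
        by = [i.beta_outcome for i in instrs]
        ols_slope, ols_int = np.polyfit(bxs, by, 1)  # OLS oracle
        assert np.isclose(slope_res.estimate.beta, 25 * ols_slope, rtol=1e-8)
        assert np.isclose(int_res.estimate.beta, ols_int, rtol=1e-8)


class TestWeightedMedian:
    def test_equal_ratios(self):
        instrs = [
            v.HarmonizedInstrument(f"rs{i}", bx, 0.4, -0.004 * bx, 0.01)
            for i, bx in enumerate([2.84, 0.95, 3.59])
        ]
        res = v.weighted_median(instrs, n_boot=50, seed=0)
        assert np.isclose(res.estimate.beta, 25 * -0.004, atol=1e-10)

    def test_interpolation_matches_brute_force(self):
        # direct enumeration oracle for the interpolated weighted median
        values = np.array([1.0, 2.0, 5.0])
        weights = np.array([0.2, 0.3, 0.5])
        # cumulative positions: 0.1, 0.35, 0.75; interpolate 0.5 between
        # (0.35, 2.0) and (0.75, 5.0): 2 + 3 * (0.15/0.4) = 3.125
        assert np.isclose(_weighted_median(values, weights), 3.125)

    def test_median_half_weight_edges(self):
        v_ = np.array([1.0, 3.0])
        w = np.array([3.0, 1.0])  # positions 0.375, 0.875: interp -> 1.5
        assert np.isclose(_weighted_median(v_, w), 1.5)

    def test_requires_two_instruments(self):
        with pytest.raises(ValueError):
            v.weighted_median(
                [v.HarmonizedInstrument("rs", 2.8, 0.4, -0.01, 0.01)], seed=0
            )

    def test_bootstrap_se_reproducible(self, harmonized_set):
        a = v.weighted_median(harmonized_set, n_boot=200, seed=5)
        b = v.weighted_median(harmonized_set, n_boot=200, seed=5)
        assert a.estimate.se == b.estimate.se


class TestAgreementUnderNoPleiotropy:
    def test_ivw_egger_median_agree(self, harmonized_set):
        # equal-quality valid instruments: the three estimators agree
        wald = [v.wald_ratio(h).estimate for h in harmonized_set]
        ivw_res = v.ivw([(e.beta, e.se) for e in wald])
        slope_res, _ = v.egger(harmonized_set)
        med_res = v.weighted_median(harmonized_set, n_boot=500, seed=1)
        spread = 3 * max(
            ivw_res.estimate.se, slope_res.estimate.se, med_res.estimate.se
        )
        assert abs(ivw_res.estimate.beta - slope_res.estimate.beta) < spread
        assert abs(ivw_res.estimate.beta - med_res.estimate.beta) < spread


class TestScoreIv:
    def test_single_snp_score_equals_wald_of_individual_effects(
        self, genetic_cohort
    ):
        from vitdmr.results import ScoreModel

        out = v.per_snp_outcome_effects(genetic_cohort, ["rs12785878"])
        instrs = v.per_snp_exposure_effects(
            genetic_cohort,
            [s for s in presets.CKB_SNPS if s.snp_id == "rs12785878"],
        )
        bx = instrs[0].beta_exposure
        sm_ = ScoreModel(
            ("rs12785878",), {"rs12785878": bx}, bx, instrs[0].se_exposure, 50.0
        )
        res = v.score_iv(genetic_cohort, sm_)
        wald = v.wald_ratio(
            v.HarmonizedInstrument(
                "rs12785878",
                bx,
                instrs[0].se_exposure,
                float(out.iloc[0]["beta_outcome"]),
                float(out.iloc[0]["se_outcome"]),
            )
        )
        assert np.isclose(res.estimate.beta, wald.estimate.beta, rtol=1e-8)
        assert np.isclose(res.estimate.se, wald.estimate.se, rtol=1e-8)

    def test_missing_snp_column_rejected(self, genetic_cohort):
        from vitdmr.results import ScoreModel

        sm_ = ScoreModel(("rs_missing",), {"rs_missing": 2.0}, 2.0, 0.4, 50.0)
        with pytest.raises(KeyError):
            v.score_iv(genetic_cohort, sm_)
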