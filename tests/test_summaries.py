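"""Accuracy summaries: intervals, differences, ICC, consequences, regions."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit, logit

from cariesdta import (
    ArmRecord,
    SamplerSettings,
    StudyTable,
    consequences_per_1000,
    contour_contains,
    intrastudy_icc,
    pairwise_differences,
    roc_regions,
    summarize,
    threshold_stratified_fit,
)
from cariesdta.errors import ModelSpecError
from cariesdta.inference import PosteriorDraws
from cariesdta.summaries import round_half_away
from conftest import FAST


def _m3_draws(mu_se, mu_sp, tau_se, sigma_se, tau_sp=None, sigma_sp=None,
              rho_c=0.0, techs=("visual",)):
    """Hand-built M3 draw container; arrays are (chains, draws)."""
    C, N = mu_se.shape[:2]
    T = len(techs)
    tau_sp = tau_se if tau_sp is None else tau_sp
    sigma_sp = sigma_se if sigma_sp is None else sigma_sp
    return PosteriorDraws(
        model="M3", technologies=techs, study_ids=["s1"],
        params={
            "mu_se": np.broadcast_to(mu_se[..., None], (C, N, T)).copy(),
            "mu_sp": np.broadcast_to(mu_sp[..., None], (C, N, T)).copy(),
            "tau_se": np.full((C, N), tau_se), "tau_sp": np.full((C, N), tau_sp),
            "sigma_se": np.full((C, N), sigma_se), "sigma_sp": np.full((C, N), sigma_sp),
            "rho_c": np.full((C, N), rho_c),
        },
        fingerprint="x", settings=SamplerSettings(),
    )


class TestSummarize:
    def test_degenerate_draws_collapse_intervals(self):
        mu = np.full((2, 100), logit(0.7))
        draws = _m3_draws(mu, mu, tau_se=0.0, sigma_se=0.0)
        s = summarize(draws)[0]
        assert s.se_point == pytest.approx(0.70, abs=1e-12)
        assert s.se_cri == pytest.approx((0.70, 0.70))
        assert s.se_pri == pytest.approx((0.70, 0.70))

    def test_prediction_interval_contains_credible_interval(self, m3_fit):
        for s in summarize(m3_fit):
            assert s.se_pri[0] <= s.se_cri[0] <= s.se_point <= s.se_cri[1] <= s.se_pri[1]
            assert s.sp_pri[0] <= s.sp_cri[0] <= s.sp_point <= s.sp_cri[1] <= s.sp_pri[1]
            assert 0.0 <= s.se_pri[0] and s.se_pri[1] <= 1.0

    def test_prediction_interval_matches_monte_carlo_oracle(self):
        """mu ~ N(logit 0.8, 0.1^2) with total heterogeneity 0.5^2: the PrI
        must match a direct predictive simulation within 0.01."""
        rng = np.random.default_rng(11)
        mu = rng.normal(logit(0.8), 0.1, (2, 5000))
        draws = _m3_draws(mu, mu, tau_se=0.3, sigma_se=0.4, rho_c=0.0)
        s = summarize(draws, seed=4)[0]
        oracle_rng = np.random.default_rng(99)
        pred = expit(mu.ravel() + oracle_rng.normal(0, 0.5, mu.size))
        lo, hi = np.percentile(pred, [2.5, 97.5])
        assert s.se_pri[0] == pytest.approx(lo, abs=0.01)
        assert s.se_pri[1] == pytest.approx(hi, abs=0.01)


class TestPairwiseDifferences:
    def test_self_pair_degenerate(self, m3_fit):
        tech = m3_fit.technologies[0]
        d = pairwise_differences(m3_fit, [(tech, tech)])[0]
        assert d.dse_mean == 0.0 and d.dse_cri == (0.0, 0.0)

    def test_constant_draws_reproduce_point_difference(self):
        mu_a = np.full((2, 50), logit(0.71))
        draws = PosteriorDraws(
            model="M2-NMA", technologies=("fluorescence", "imaging"),
            study_ids=["s1"],
            params={
                "mu_se": np.stack([np.full((2, 50), logit(0.71)),
                                   np.full((2, 50), logit(0.48))], axis=-1),
                "mu_sp": np.stack([np.full((2, 50), logit(0.88)),
                                   np.full((2, 50), logit(0.92))], axis=-1),
                "s_se": np.full((2, 50), 0.5), "s_sp": np.full((2, 50), 0.5),
                "rho": np.zeros((2, 50)),
            },
            fingerprint="x", settings=SamplerSettings(),
        )
        d = pairwise_differences(draws, [("fluorescence", "imaging")])[0]
        assert d.dse_mean == pytest.approx(0.23, abs=1e-9)

    def test_antisymmetry(self, m3_fit):
        a, b = m3_fit.technologies[:2]
        fwd = pairwise_differences(m3_fit, [(a, b)])[0]
        rev = pairwise_differences(m3_fit, [(b, a)])[0]
        assert fwd.dse_mean == pytest.approx(-rev.dse_mean, abs=1e-12)
        assert fwd.dse_cri[0] == pytest.approx(-rev.dse_cri[1], abs=1e-9)
        assert fwd.dsp_cri[1] == pytest.approx(-rev.dsp_cri[0], abs=1e-9)

    def test_difference_of_points_consistency(self, m3_fit):
        summaries = {s.technology: s for s in summarize(m3_fit)}
        a, b = m3_fit.technologies[:2]
        d = pairwise_differences(m3_fit, [(a, b)])[0]
        assert abs(
            d.dse_mean - (summaries[a].se_point - summaries[b].se_point)
        ) < 0.02


class TestIcc:
    def test_equal_components_give_half(self):
        mu = np.zeros((2, 10))
        draws = _m3_draws(mu, mu, tau_se=0.7, sigma_se=0.7)
        icc = intrastudy_icc(draws)
        assert icc["icc_se"]["median"] == pytest.approx(0.5)

    def test_no_interaction_gives_one(self):
        mu = np.zeros((2, 10))
        draws = _m3_draws(mu, mu, tau_se=0.7, sigma_se=0.0)
        assert intrastudy_icc(draws)["icc_se"]["median"] == pytest.approx(1.0)

    def test_equals_direct_transformation_of_draws(self, m3_fit):
        icc = intrastudy_icc(m3_fit)
        tau = m3_fit.flat("tau_sp")
        sigma = m3_fit.flat("sigma_sp")
        direct = tau**2 / (tau**2 + sigma**2)
        assert np.allclose(np.sort(icc["icc_sp"]["draws"]), np.sort(direct))
        assert 0.0 <= icc["icc_sp"]["median"] <= 1.0

    def test_wrong_variant_rejected(self, rng):
        draws = PosteriorDraws(
            model="M2-NMA", technologies=("a",), study_ids=["s1"],
            params={"mu_se": rng.normal(size=(2, 5, 1)),
                    "mu_sp": rng.normal(size=(2, 5, 1)),
                    "s_se": np.ones((2, 5)), "s_sp": np.ones((2, 5)),
                    "rho": np.zeros((2, 5))},
            fingerprint="x", settings=SamplerSettings(),
        )
        with pytest.raises(ModelSpecError):
            intrastudy_icc(draws)


class TestConsequences:
    @pytest.mark.parametrize(
        "se,sp,tp,fn,tn,fp",
        [
            (0.83, 0.81, 232, 48, 583, 137),  # visual-classification column
            (0.50, 0.89, 140, 140, 641, 79),  # imaging column
        ],
    )
    def test_published_style_columns(self, se, sp, tp, fn, tn, fp):
        row = consequences_per_1000("t", se, sp, 0.28)
        assert (row.tp, row.fn, row.tn, row.fp) == (tp, fn, tn, fp)

    def test_perfect_test(self):
        row = consequences_per_1000("t", 1.0, 1.0, 0.5)
        assert (row.tp, row.fn, row.tn, row.fp) == (500, 0, 500, 0)

    def test_interval_columns_reverse_for_misses(self):
        row = consequences_per_1000(
            "t", 0.83, 0.81, 0.28, se_cri=(0.77, 0.87), sp_cri=(0.73, 0.87)
        )
        assert row.tp_ci == (216, 244)
        assert row.fn_ci == (36, 64)
        assert row.tn_ci == (526, 626)
        assert row.fp_ci == (94, 194)

    @given(
        se=st.floats(0, 1), sp=st.floats(0, 1),
        p=st.floats(0.001, 0.999), n=st.integers(10, 100000),
    )
    def test_cells_always_partition_cohort(self, se, sp, p, n):
        row = consequences_per_1000("t", se, sp, p, cohort=n)
        assert row.tp + row.fn + row.tn + row.fp == n
        assert row.tp + row.fn == round_half_away(n * p)
        assert min(row.tp, row.fn, row.tn, row.fp) >= 0

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(232.5) == 233
        assert round_half_away(-0.5) == -1
        assert round_half_away(47.6) == 48


class TestRocRegions:
    def test_degenerate_draws_collapse_to_point(self):
        mu = np.full((2, 300), logit(0.7))
        draws = _m3_draws(mu, mu, tau_se=0.0, sigma_se=0.0)
        region = roc_regions(draws)[0]
        assert np.allclose(region.credible_contour, region.summary_point)
        assert np.allclose(region.prediction_contour, region.credible_contour)

    def test_prediction_region_wider_than_credible(self, m3_fit, small_within_table):
        table, _ = small_within_table
        from scipy.spatial import ConvexHull

        for region in roc_regions(m3_fit, table=table):
            a_cred = ConvexHull(region.credible_contour[:-1]).volume
            a_pred = ConvexHull(region.prediction_contour[:-1]).volume
            assert a_pred >= a_cred
            assert region.study_points is not None

    def test_containment_of_fresh_predictive_draws(self, rng):
        """~95% of fresh draws from the same predictive law fall inside the
        emitted 95% prediction contour."""
        mu_se = rng.normal(1.2, 0.15, (2, 3000))
        mu_sp = rng.normal(1.5, 0.15, (2, 3000))
        draws = _m3_draws(mu_se, mu_sp, tau_se=0.4, sigma_se=0.4, rho_c=-0.3)
        region = roc_regions(draws, seed=1)[0]
        fresh_rng = np.random.default_rng(123)
        from cariesdta.summaries import _predictive_logits

        fresh = _predictive_logits(draws, "visual", fresh_rng)
        pts = np.stack([1 - expit(fresh[:, 1]), expit(fresh[:, 0])], axis=-1)
        frac = contour_contains(region.prediction_contour, pts).mean()
        assert abs(frac - 0.95) <= 0.015

    def test_few_draws_warns(self):
        mu = np.full((2, 100), 0.5)
        draws = _m3_draws(mu, mu, tau_se=0.2, sigma_se=0.2)
        with pytest.warns(UserWarning, match="unstable"):
            roc_regions(draws)


class TestThresholdStratified:
    def _fluorescence_table(self, thresholds, n_studies=4):
        rng = np.random.default_rng(0)
        arms = []
        for i, thr in enumerate(thresholds):
            for j in range(n_studies):
                nD = nS = 60
                tp = int(rng.binomial(nD, 0.75))
                tn = int(rng.binomial(nS, 0.85))
                arms.append(
                    ArmRecord(
                        f"s{i}_{j}", "fluorescence", tp=tp, fp=nS - tn,
                        fn=nD - tp, tn=tn, threshold=str(thr),
                    )
                )
        return StudyTable(arms)

    def test_single_bin_equals_plain_bivariate_fit(self):
        from cariesdta import fit, summarize

        table = self._fluorescence_table([10, 20, 30], n_studies=2)
        res = threshold_stratified_fit(table, [0, 100], settings=FAST)
        assert len(res) == 1 and res[0].n_studies == 6
        direct = summarize(fit("bivariate", table, settings=FAST), seed=FAST.seed)[0]
        assert res[0].summary.se_point == pytest.approx(direct.se_point)
        assert res[0].summary.sp_cri == pytest.approx(direct.sp_cri)

    def test_empty_bin_flagged_not_fitted(self):
        table = self._fluorescence_table([5, 35], n_studies=2)
        res = threshold_stratified_fit(table, [0, 10, 20, 40], settings=FAST)
        assert res[1].summary is None and res[1].low_information
        assert res[0].summary is not None

    def test_low_information_flag_and_exclusions(self):
        table = self._fluorescence_table([5], n_studies=2)
        extra = StudyTable(
            table.arms
            + [ArmRecord("sx", "fluorescence", tp=5, fp=2, fn=3, tn=6, threshold="n/a")]
        )
        with pytest.warns(UserWarning, match="without numeric thresholds"):
            res = threshold_stratified_fit(extra, [0, 10], settings=FAST)
        assert res[0].low_information  # 2 studies < 3

    def test_multi_technology_table_rejected(self, toy_table_t2):
        with pytest.raises(ModelSpecError):
            threshold_stratified_fit(toy_table_t2, [0, 1])

    def test_rising_accuracy_across_bins_recovered(self):
        """When true sensitivity rises with the positivity-threshold bin,
        the stratified fits recover the trend within their CrIs."""
        rng = np.random.default_rng(7)
        arms = []
        true_se = {5: 0.60, 15: 0.75, 25: 0.90}
        for thr, se in true_se.items():
            for j in range(5):
                nD = nS = 120
                tp = int(rng.binomial(nD, se))
                tn = int(rng.binomial(nS, 0.85))
                arms.append(
                    ArmRecord(f"b{thr}_{j}", "fluorescence", tp=tp, fp=nS - tn,
                              fn=nD - tp, tn=tn, threshold=str(thr))
                )
        res = threshold_stratified_fit(StudyTable(arms), [0, 10, 20, 30], settings=FAST)
        points = [r.summary.se_point for r in res]
        assert points == sorted(points)
        for r, se in zip(res, true_se.values()):
            assert r.summary.se_cri[0] <= se <= r.summary.se_cri[1]
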