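"""Sampler correctness, convergence gating, and cross-validation machinery."""
import numpy as np
import pytest
from scipy.special import logit

from cariesdta import (
    ArmRecord,
    SamplerSettings,
    SimulationConfig,
    StudyTable,
    check_convergence,
    compare_models_cv,
    fit,
    select_model,
    simulate_study_table,
)
from cariesdta.errors import ConfigError, EligibilityError, ModelSpecError
from cariesdta.inference import CvResult, PosteriorDraws, psis_loo
from cariesdta._marginal import study_pointwise_loglik
from cariesdta._posteriors import POSTERIORS, chol_from_cpc
from conftest import FAST, small_within_config


class TestPosteriorGradients:
    @pytest.mark.parametrize("model", ["M1", "M2", "M3"])
    def test_within_gradients_match_finite_differences(self, model, small_within_table):
        table, _ = small_within_table
        self._check(model, table)

    @pytest.mark.parametrize("model", ["M1-NMA", "M2-NMA"])
    def test_nma_gradients_match_finite_differences(self, model, toy_network):
        self._check(model, toy_network)

    @staticmethod
    def _check(model, table):
        rng = np.random.default_rng(3)
        post = POSTERIORS[model](table, table.technologies)
        x = post.initial_positions(2, rng) + 0.05 * rng.standard_normal((2, post.dim))
        _, grad = post.logp_grad(x)
        h = 1e-6
        for k in rng.choice(post.dim, size=min(30, post.dim), replace=False):
            xp, xm = x.copy(), x.copy()
            xp[:, k] += h
            xm[:, k] -= h
            fd = (post.logp_grad(xp)[0] - post.logp_grad(xm)[0]) / (2 * h)
            assert np.max(np.abs(fd - grad[:, k]) / (1 + np.abs(fd))) < 1e-4

    def test_prior_config_override_changes_density(self, toy_network):
        default = POSTERIORS["M2-NMA"](toy_network, toy_network.technologies)
        tight = POSTERIORS["M2-NMA"](
            toy_network, toy_network.technologies,
            {"mu": ("normal", 0.0, 0.5), "sd": ("half_normal", 0.2), "corr": ("lkj", 4.0)},
        )
        x = default.initial_positions(2, np.random.default_rng(1))
        lp_d, _ = default.logp_grad(x)
        lp_t, _ = tight.logp_grad(x)
        assert not np.allclose(lp_d, lp_t)

    def test_cpc_construction_gives_valid_correlation(self, rng):
        p = rng.uniform(-0.9, 0.9, (5, 15))
        L = chol_from_cpc(p, 6)
        R = L @ np.swapaxes(L, -1, -2)
        assert np.allclose(np.diagonal(R, axis1=-2, axis2=-1), 1.0)
        assert np.all(np.linalg.eigvalsh(R) > 0)


class TestFit:
    def test_same_seed_same_draws(self, toy_network):
        s = SamplerSettings(
            chains=2, warmup_iterations=150, sampling_iterations=150, seed=5,
            pointwise_loglik=False, auto_raise=False,
        )
        a = fit("M2-NMA", toy_network, settings=s)
        b = fit("M2-NMA", toy_network, settings=s)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_zero_heterogeneity_recovers_pooled_estimate(self):
        """30 studies x 200 sites with (near) no heterogeneity: the summary
        Se must sit within 0.03 of the pooled binomial MLE and of 0.8."""
        cfg = SimulationConfig(
            n_studies=30, technologies=("visual",),
            mu_se={"visual": logit(0.8)}, mu_sp={"visual": logit(0.85)},
            prevalence=0.5, site_count_range=(200, 200), seed=6,
            covariance=dict(
                tau_se=0.01, sigma_se=0.0, tau_sp=0.01, sigma_sp=0.0, rho_c=0.0
            ),
        )
        table, _ = simulate_study_table(cfg)
        draws = fit("bivariate", table, settings=FAST)
        from cariesdta import summarize

        s = summarize(draws)[0]
        pooled = sum(a.tp for a in table.arms) / sum(a.n_diseased for a in table.arms)
        assert abs(s.se_point - 0.80) < 0.03
        assert abs(s.se_point - pooled) < 0.02

    def test_identical_technologies_give_symmetric_difference(self):
        """Two technologies with byte-identical arms: the posterior mean of
        their sensitivity difference is zero up to Monte-Carlo error."""
        rng = np.random.default_rng(2)
        arms = []
        for i in range(15):
            nD, nS = 80, 80
            tp = int(rng.binomial(nD, 0.75))
            tn = int(rng.binomial(nS, 0.85))
            for tech in ("a", "b"):
                arms.append(
                    ArmRecord(f"s{i}", tech, tp=tp, fp=nS - tn, fn=nD - tp, tn=tn)
                )
        table = StudyTable(arms)
        draws = fit("M2-NMA", table, settings=FAST, technologies=("a", "b"))
        from cariesdta import pairwise_differences

        diff = pairwise_differences(draws, [("a", "b")])[0]
        assert abs(diff.dse_mean) < 0.02

    def test_indirect_comparison_proper_and_sharpens_with_data(self):
        """Chain network (A-B studies and B-C studies only): the A-C
        comparison is estimated through B, and its credible interval
        narrows as the number of studies grows."""
        from cariesdta import pairwise_differences

        def chain_fit(n_studies, seed):
            cfg = SimulationConfig(
                n_studies=n_studies,
                technologies=("fluorescence", "visual", "imaging"),
                mu_se={"fluorescence": 1.2, "visual": 1.0, "imaging": 0.2},
                mu_sp={"fluorescence": 1.5, "visual": 1.3, "imaging": 2.0},
                prevalence=0.6,
                site_count_range=(100, 200),
                seed=seed,
                design="incomplete",
                subset_probs={
                    ("fluorescence", "visual"): 0.5,
                    ("visual", "imaging"): 0.5,
                },
                covariance=dict(tau_se=0.4, sigma_se=0.0, tau_sp=0.4,
                                sigma_sp=0.0, rho_c=-0.3),
            )
            table, _ = simulate_study_table(cfg)
            return fit("M2-NMA", table, settings=FAST,
                       technologies=cfg.technologies)

        widths = []
        for n, seed in ((8, 1), (40, 2)):
            draws = chain_fit(n, seed)
            d = pairwise_differences(draws, [("fluorescence", "imaging")])[0]
            assert np.isfinite(d.dse_cri).all()
            widths.append(d.dse_cri[1] - d.dse_cri[0])
        assert widths[1] < widths[0]

    def test_nma_requires_two_technologies_per_study(self, toy_network):
        arms = toy_network.arms + [ArmRecord("solo", "visual", tp=5, fp=2, fn=3, tn=6)]
        with pytest.raises(EligibilityError):
            fit("M2-NMA", StudyTable(arms), settings=FAST)

    def test_unknown_model_key(self, toy_network):
        with pytest.raises(ModelSpecError):
            fit("M4", toy_network)


def _synthetic_draws(arr_map, study_ids=("s1",)):
    return PosteriorDraws(
        model="M2-NMA", technologies=("a",), study_ids=list(study_ids),
        params=arr_map, fingerprint="x", settings=SamplerSettings(),
    )


class TestCheckConvergence:
    def _draws(self, mu):
        C, N = mu.shape[:2]
        return _synthetic_draws(
            {
                "mu_se": mu.reshape(C, N, 1),
                "mu_sp": mu.reshape(C, N, 1),
                "s_se": np.abs(mu) + 0.5,
                "s_sp": np.abs(mu) + 0.5,
                "rho": np.tanh(mu),
            }
        )

    def test_iid_normal_chains_pass(self, rng):
        draws = self._draws(rng.standard_normal((4, 1000)))
        diag = check_convergence(draws)
        assert diag.passed
        assert 1.0 - 1e-9 <= diag.rhat_max < 1.01
        assert diag.ess_min > 100

    def test_constant_chains_fail(self):
        draws = self._draws(np.ones((4, 1000)))
        diag = check_convergence(draws)
        assert not diag.passed
        assert diag.ess["mu_se[a]"] == 0.0

    def test_disjoint_chains_fail(self, rng):
        mu = rng.standard_normal((2, 500))
        mu[1] += 10.0
        diag = check_convergence(self._draws(mu))
        assert not diag.passed
        assert diag.rhat_max > 1.05

    def test_thresholds_disabled_always_pass(self):
        draws = self._draws(np.ones((4, 100)))
        diag = check_convergence(draws, rhat_max=np.inf, ess_min=0.0)
        assert diag.passed

    def test_single_chain_rejected(self, rng):
        draws = self._draws(rng.standard_normal((1, 100)))
        with pytest.raises(ConfigError, match="chain"):
            check_convergence(draws)


class TestPointwiseLoglik:
    def test_partition_consistency(self, toy_network, rng):
        """The marginal log-likelihood of a table equals the sum over any
        partition of its studies (independence across studies)."""
        params = {
            "mu_se": rng.normal(0.5, 0.3, (8, 3)),
            "mu_sp": rng.normal(1.0, 0.3, (8, 3)),
            "s_se": np.full(8, 0.6), "s_sp": np.full(8, 0.5),
            "rho": np.full(8, -0.3),
        }
        techs = tuple(toy_network.technologies)
        whole = study_pointwise_loglik("M2-NMA", params, toy_network, techs)
        for j, sid in enumerate(toy_network.study_ids):
            alone = StudyTable(toy_network.for_study(sid))
            single = study_pointwise_loglik("M2-NMA", params, alone, techs)
            assert np.allclose(single[:, 0], whole[:, j], atol=1e-8)

    def test_total_equals_sum_of_pointwise(self, m3_fit):
        total = m3_fit.total_pointwise()
        assert np.allclose(total, m3_fit.pointwise.sum(axis=-1))
        assert total.shape == (2, 500)
        assert np.all(np.isfinite(m3_fit.pointwise))


class TestCompareModels:
    def _result_pair(self, pointwise_a, pointwise_b):
        a = CvResult("A", float(pointwise_a.sum()), 1.0, pointwise_a, "psis-loo", 0.1, True)
        b = CvResult("B", float(pointwise_b.sum()), 1.0, pointwise_b, "psis-loo", 0.1, True)
        return a, b

    def test_identical_draws_give_zero_difference(self, m3_fit, small_within_table):
        table, _ = small_within_table
        results = compare_models_cv({"M3": m3_fit, "M3-copy": m3_fit}, table,
                                    kfold_on_failure=False)
        assert results[0].d_elpd_best == 0.0
        assert results[1].d_elpd_best == 0.0

    def test_uniform_shift_gives_study_count(self, m3_fit, small_within_table):
        table, _ = small_within_table
        import copy

        worse = copy.deepcopy(m3_fit)
        worse.pointwise = m3_fit.pointwise - 1.0
        results = compare_models_cv({"M3": m3_fit, "worse": worse}, table,
                                    kfold_on_failure=False)
        assert results[0].model == "M3"
        n_studies = len(m3_fit.study_ids)
        assert results[1].d_elpd_best == pytest.approx(n_studies, abs=1e-6)
        assert results[1].d_se_best == pytest.approx(0.0, abs=1e-6)

    def test_fingerprint_mismatch_rejected(self, m3_fit, toy_network):
        with pytest.raises(ConfigError, match="same data"):
            compare_models_cv({"M3": m3_fit}, toy_network)

    def test_m2_vs_m3_on_m2_data_shows_no_clear_difference(self):
        """Data simulated under M2 (no cross-technology correlation): M3 may
        not beat M2 by more than twice the SE of the difference."""
        cfg = small_within_config(seed=29, n_studies=14)
        cov = np.zeros((6, 6))
        for t in range(3):
            cov[2 * t, 2 * t] = 0.8**2
            cov[2 * t + 1, 2 * t + 1] = 0.7**2
            cov[2 * t, 2 * t + 1] = cov[2 * t + 1, 2 * t] = -0.3 * 0.8 * 0.7
        cfg.covariance = cov
        table, _ = simulate_study_table(cfg)
        s = SamplerSettings(
            chains=2, warmup_iterations=400, sampling_iterations=400, seed=1,
            auto_raise=False,
        )
        fits = {m: fit(m, table, settings=s) for m in ("M2", "M3")}
        results = compare_models_cv(fits, table, kfold_on_failure=False)
        if results[0].model == "M3":
            worse = next(r for r in results if r.model == "M2")
            assert worse.d_elpd_best <= 2.0 * worse.d_se_best

    def test_selection_prefers_simplest_when_tied(self, rng):
        base = rng.normal(-10, 1, 20)
        a, b = self._result_pair(base, base + rng.normal(0, 0.05, 20))
        a.model, b.model = "M1", "M3"
        results = sorted([a, b], key=lambda r: r.elpd, reverse=True)
        best = results[0]
        for r in results:
            diff = best.pointwise - r.pointwise
            r.d_elpd_best = float(diff.sum())
            r.d_se_best = float(np.sqrt(len(diff) * np.var(diff)))
        assert select_model(results) == "M3"

    def test_psis_loo_runs_on_fit(self, m3_fit):
        res = psis_loo(m3_fit)
        assert res.method == "psis-loo"
        assert np.isfinite(res.elpd)
        assert res.pointwise.shape == (len(m3_fit.study_ids),)
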