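"""Compare within-person model variants by leave-one-study-out cross-validation.

Fits M2 (separate bivariate models) and M3 (shared heterogeneity) to the
same simulated network and applies the selection rule: when the expected log
predictive densities differ by less than twice the standard error of the
difference, prefer the simpler model.
"""
from cariesdta import (
    SamplerSettings,
    analysis1_config,
    compare_models_cv,
    fit,
    select_model,
    simulate_study_table,
)

cfg = analysis1_config(seed=8, n_studies=14)
table, _ = simulate_study_table(cfg)

settings = SamplerSettings(chains=2, warmup_iterations=800,
                           sampling_iterations=800, seed=9)
fits = {model: fit(model, table, settings=settings) for model in ("M2", "M3")}

results = compare_models_cv(fits, table, kfold_on_failure=False)
print("model  elpd_loo    se     d_elpd_best  d_se   method")
for r in results:
    print(f"{r.model:5s} {r.elpd:9.1f} {r.se:6.1f}   {r.d_elpd_best:9.2f} "
          f"{r.d_se_best:6.2f}  {r.method}")
chosen = select_model(results)
print(f"\nselected: {chosen} -- the simplest model among those with no "
      "evidence of a fit difference (|d_elpd| <= 2 SE)")
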