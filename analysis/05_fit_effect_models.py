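"""Fit the dose-effect mixed models and report the headline effect sizes.

Two fits of each model are reported:

* on a site-year dataset drawn directly from the generative mixed-model
  truth (dose slope -0.256 on bird numbers, +0.045 on Simpson's index) —
  this is the parameter-recovery view, and its percent-effect transforms
  are the headline numbers;
* on the ecological pipeline's own site-year table (counts aggregated from
  the synthetic census, doses weighted by observed abundances) — here the
  abundance-weighted dose carries species-composition noise, so the fitted
  dose slope is attenuated relative to the generative truth; the size of
  that attenuation is itself a finding worth reporting.

Models: Poisson GLMM for the total number of birds with random intercepts
for site and census-day-by-transect; Gaussian LMM for Simpson's index with
random intercepts for site, census day and transect.  Continuous inputs are
standardised by two standard deviations; coefficients are reported on both
scales.
"""

import json
from pathlib import Path

from birddose.community import build_site_year_table
from birddose.effects import (
    ModelSpec,
    fit_effect_model,
    linear_percent_lmm,
    percent_change_glmm,
    screen_collinearity,
)
from birddose.simulate import SyntheticStudy, simulate_glmm_dataset

ROOT = Path(__file__).resolve().parents[1]
CONTINUOUS = ["log10_TD", "time", "cloud", "temperature", "altitude",
              "grass", "farmland", "coniferous"]
GLMM_SPEC = ModelSpec(response="TNB")
LMM_SPEC = ModelSpec(response="simpson", family="gaussian-identity",
                     random_factors=("site", "day", "transect"))


def report_glmm(data, label):
    m = fit_effect_model(data, GLMM_SPEC)
    b, se = m.coef("raw")["log10_TD"], m.se("raw")["log10_TD"]
    loss, lo, hi = percent_change_glmm(b, se)
    print(f"[{label}] TNB ~ log10 dose: slope {b:.3f} (SE {se:.3f}) -> "
          f"{loss:.1f}% per unit log10 dose, 95% CI [{lo:.1f}, {hi:.1f}]")
    return m


def report_lmm(data, label):
    m = fit_effect_model(data, LMM_SPEC)
    b, se = m.coef("raw")["log10_TD"], m.se("raw")["log10_TD"]
    gain, lo, hi = linear_percent_lmm(b, se)
    print(f"[{label}] Simpson ~ log10 dose: slope {b:.4f} (SE {se:.4f}) -> "
          f"{gain:.1f} points per unit log10 dose, 95% CI [{lo:.1f}, {hi:.1f}]")
    return m


def main() -> None:
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    print("== generative-truth dataset (300 sites x 4 years) ==")
    truth_data = simulate_glmm_dataset(seed=1)
    kept, dropped = screen_collinearity(truth_data[CONTINUOUS])
    print("collinearity screen:",
          f"dropped {dropped}" if dropped else "all predictors retained (|r| < 0.87)")
    glmm = report_glmm(truth_data, "truth")
    print("  random-effect variances:",
          {k: round(v, 4) for k, v in glmm.variance_components.items()},
          "(generative: site 0.052, day_transect 0.023)")
    lmm = report_lmm(truth_data, "truth")
    print("  LMM variances:",
          {k: round(v, 4) for k, v in lmm.variance_components.items()},
          f"resid {lmm.fit_std.sigma_resid**2:.4f}",
          "(generative: 0.002 / 0.001 / 0.004, resid 0.026)")
    glmm.summary_table().to_csv(out / "tnb_glmm_coefficients.csv", index=False)
    lmm.summary_table().to_csv(out / "simpson_lmm_coefficients.csv", index=False)

    print("\n== ecological pipeline site-year table ==")
    study = SyntheticStudy.from_dir(ROOT / "scratch" / "synthetic_study")
    sy = build_site_year_table(study.census, doses=study.doses)
    pipe_data = sy.merge(study.covariates, on=["site", "year"])
    glmm_pipe = report_glmm(pipe_data, "pipeline")
    print("  note: the observed-abundance-weighted dose is a noisy proxy for the")
    print("  generative site dose, so this slope is attenuated by design.")

    fit_json = {
        "truth_glmm": {
            "coef_std": glmm.coef("std"), "se_std": glmm.se("std"),
            "coef_raw": glmm.coef("raw"), "se_raw": glmm.se("raw"),
            "variance_components": glmm.variance_components,
            "loglik": glmm.loglik, "aic": glmm.aic,
        },
        "truth_lmm": {
            "coef_std": lmm.coef("std"), "se_std": lmm.se("std"),
            "coef_raw": lmm.coef("raw"), "se_raw": lmm.se("raw"),
            "variance_components": lmm.variance_components,
            "sigma_resid_sq": lmm.fit_std.sigma_resid ** 2,
            "loglik": lmm.loglik, "aic": lmm.aic,
        },
        "pipeline_glmm": {
            "coef_raw": glmm_pipe.coef("raw"), "se_raw": glmm_pipe.se("raw"),
            "variance_components": glmm_pipe.variance_components,
        },
    }
    with open(out / "model_fit.json", "w") as fh:
        json.dump(fit_json, fh, indent=1)
    print(f"\ncoefficient tables and model_fit.json -> {out}")


if __name__ == "__main__":
    main()
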