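# birddose

Radiological dose reconstruction for wild birds, and dose–effect analysis of
bird census data.

After a large release of radionuclides, the radiation level measured with a
hand-held dosimeter at a census point is a biased indicator of the dose the
local wildlife actually absorbs: for a fixed ambient level, the dose rate of
an individual animal varies by orders of magnitude with its diet, transfer
parameters and time budget.  `birddose` implements the full chain from soil
deposition maps to organism-level dose–effect estimates for breeding-bird
census data of the kind collected along transects northwest of the Fukushima
Daiichi plant in 2011–2014:

1. **Dosimetry** — for each species *j*, radionuclide *r* and census site,
   the internal dose rate `IDR(j,r) = DCC_int(j,r) · CR(j,r) · A_soil(r)` and
   the external dose rate
   `EDR(j,r) = [DCC_on·T_on + DCC_off·(1 − T_on)] · A_soil(r)`,
   where `A_soil` is the decay-corrected soil activity (Bq kg⁻¹ dry weight,
   converted from Bq m⁻² with the 65 kg m⁻² surface-mass factor of a 5-cm,
   1300 kg m⁻³ soil layer), `CR` the soil-to-bird concentration ratio and
   `T_on` the fraction of time spent on soil.  The total dose rate `TDR` sums
   both pathways over radionuclides, and the cumulative total dose
   `TD = Σ_k TDR_k · D_k` (in Gy) accumulates it from the accident date over
   the census intervals (112, 478, 843, 1208 days for July censuses
   2011–2014).
2. **Spatial linkage** — each census site inherits the activity of the
   nearest soil sampling point (great-circle distance; per radionuclide,
   since the iodine map is sparser than the caesium one).
3. **Community metrics** — per site-year: total number of birds (TNB),
   Simpson's index of diversity `1 − Σ p_j²`, and the abundance-weighted
   total dose `TD_ik = Σ_j (A_ijk / TNB_ik) · TD_ijk`.
4. **Effect models** — a Poisson GLMM for TNB and a Gaussian (REML) LMM for
   Simpson's index against log₁₀ total dose, with census-condition and
   land-cover covariates standardised by two standard deviations, random
   intercepts for site and census-day×transect (GLMM) or site, day and
   transect (LMM), Wald z and Satterthwaite t tests.  The Laplace-
   approximated GLMM with crossed random intercepts is implemented
   in-package (and cross-checked against `lme4::glmer` in the test suite).
5. **ED50** — the total dose halving expected abundance, estimated by
   perturbing model-predicted dose–response curves with the model's own
   random-intercept and Poisson noise and refitting a constrained
   log-logistic `f(d) = c / (1 + exp(b(ln d − ln e)))` per replicate.

Because the underlying census database is not publicly deposited, the
package ships a synthetic-study generator (`birddose.simulate`) that
emulates the study design — 4 transects × 300 sites × 57 species × 4 years,
a 2×2 km deposition grid declining away from the source — with a recorded
generative truth (dose slope −0.256 per log₁₀ Gy, site variance 0.052,
day×transect variance 0.023; diversity-model variances 0.002/0.001/0.004,
residual 0.026), so every stage is testable end to end.

## Worked example

```python
from birddose import ModelSpec, estimate_ed50, fit_effect_model, percent_change_glmm
from birddose.simulate import simulate_glmm_dataset

data = simulate_glmm_dataset(seed=1)          # 300 sites x 4 years from the generative truth
model = fit_effect_model(data, ModelSpec(response="TNB"))
b, se = model.coef("raw")["log10_TD"], model.se("raw")["log10_TD"]
print(b, se)                                   # -0.283 0.031
print(percent_change_glmm(b, se))              # (-24.7, -29.1, -19.9)
print(estimate_ed50(model, B=1000, seed=42))
```

This prints a recovered unstandardised dose slope of −0.283 (SE 0.031) for a
generative value of −0.256 — i.e. an estimated 24.7 % loss of birds (95 % CI
[19.9, 29.1]) per tenfold increase in total dose on this replicate — and an
ED50 summary `point=0.179 Gy, ci=[0.010, 0.436]` (the dose at which expected
abundance halves relative to the low end of the calculated dose range).

The numbered scripts under `analysis/` run the same chain as a narrative:
`01` simulates a study into `scratch/`, `02` links census sites to soil
points, `03` reconstructs doses and classifies species maxima against the
ICRP effect bands, `04` builds site-year summaries, `05` fits both mixed
models (on the generative-truth dataset and on the pipeline's own table),
and `06` estimates the ED50.  Summary tables land in `results/`.

A small CLI mirrors the two entry points users run standalone:
`birddose simulate --seed 1 --out dir/` and
`birddose ed50 --study dir/ --B 1000 --seed 42 --out ed50.json`.

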