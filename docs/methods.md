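# Methods

## Recovery statistics

All recovery fractions are stored as unbounded fractions of the annual N
rate; percentages appear only in reports. Records with $RE^{LT} > 1$ or
$\Delta RE < 0$ are legal observations (uptake increments can exceed the
annual rate where soil-N legacies are large, and sampling noise can invert
the two recoveries); they are retained and tagged with warning flags rather
than filtered.

For subplot-method records the package exposes both the two-step route
($RE^{LT}$ and $RE^{1st}$ separately, then the difference) and the
algebraically identical one-step form
$\Delta RE = (U^{0N,ST} - U^{0N,LT})/N_{rate}$; their agreement to machine
precision is a standing property test. Trials whose design yields a ΔRE
directly but no separable recovery fractions enter as `direct_delta`
pass-through records carrying an externally computed value and weight.

A site-year offering both first-season methods contributes two records —
one per method — sharing $RE^{LT}$. The record weight is
`n_years_pooled × n_field_reps` of the underlying short-term observation;
weights are not renormalised (all weighted estimates are invariant to a
common rescaling of the weights, which is also tested).

## Mixed meta-model

The response is ΔRE; site and sampling year enter as *crossed* random
intercepts (not nested — multiple sites can share a calendar year), and the
replicate weight acts as an inverse-variance multiplier on the residual:
$\mathrm{Var}(\varepsilon_i) = \sigma^2/w_i$.

Estimation profiles out the fixed effects and the residual variance: with
variance ratios $\gamma_s = \sigma^2_{site}/\sigma^2$,
$\gamma_y = \sigma^2_{year}/\sigma^2$ and
$V = \gamma_s Z_sZ_s^\top + \gamma_y Z_yZ_y^\top + W^{-1}$, the GLS
estimate $\hat\beta = (X^\top V^{-1}X)^{-1}X^\top V^{-1}y$ and
$\hat\sigma^2$ are closed-form, and the profiled −2·log-(restricted)-
likelihood is minimised over $(\gamma_s,\gamma_y) \in [0,\infty)^2$ by a
coarse grid followed by bounded Powell search (derivative-free; function
tolerance 1e-10; ratios capped at 1e6). The REML criterion includes the
$\log|X^\top V^{-1}X|$ term. Degenerate limits are exact: pinning both
ratios at zero reproduces closed-form weighted least squares, and the
optimum is verified against brute-force grid evaluation of the same
criterion formula written independently.

Conventions, chosen once and logged by every pipeline run:

* **ML vs REML.** Model comparison (the dredge) uses ML throughout, since
  REML likelihoods are not comparable across different fixed-effect sets;
  final reported estimates use REML.
* **AICc parameter count.** $k$ counts all estimated parameters: fixed
  effects (including the intercept) plus the two random-intercept variances
  plus the residual variance.
* **Confidence intervals.** Wald-t with $df = n_{obs} - n_{sites}$. With
  nine sites carrying most of the heterogeneity this df is generous, so
  empirical coverage runs slightly below nominal (≈0.94 in the 200-seed
  replication) — acceptable for a summary interval, and reported rather
  than hidden. No Satterthwaite/Kenward–Roger correction is attempted.
* **Standardisation.** Continuous co-variables are z-scored (unweighted,
  sample SD); categorical ones are one-hot coded against the alphabetically
  first observed level; the binary residue flag stays 0/1. Scaling
  parameters are returned so coefficients can be mapped back exactly.
* **Ties in AICc** are broken by fewer parameters, then by the
  lexicographic term set, making the ranking deterministic and independent
  of input order. Non-converged or rank-deficient subsets are kept, flagged
  and ranked last.
* **Weighted mean ΔRE** is reported both as the intercept of the weighted
  intercept-only mixed model (the primary estimate) and as the plain
  weighted mean, since the two conventions differ when sites are unbalanced.
* **Method contrast** (¹⁵N − subplot) is estimated on all records and on
  the paired subset of site-years offering both methods. An optional
  outlier rule (drop the single record with the largest absolute
  studentised residual if it exceeds 3) exists for the paired contrast but
  is **off by default** and identifies the dropped record when used.
* **Normality screening** is numerical (skewness / excess kurtosis of the
  three recovery statistics) rather than graphical.

## Climate co-variables

The Global-Yield-Gap-Atlas-style triplet: growing degree days
(Σ max(T_d − base, 0); base temperature defaults to 0 °C, the common
small-grain convention — it is configuration, not ground truth), aridity
index (annual precipitation / annual PET; PET is an input, no
evapotranspiration model is included), and temperature seasonality (sample
SD, divisor 11, of the 12 monthly mean temperatures). Multi-year weather is
handled by computing indices per calendar year and averaging.

## Synthetic generator

`simulate_lte` is a statistical test-bed, not a mechanistic soil model.
Each annual application of `n_rate` splits into first-season uptake
(`r1`), a retained soil pool (`rho`) and implicit losses (`1 − r1 − rho`;
no leaching/denitrification split is modelled). Retained cohorts
remineralise by age: 10% of the *applied* amount in the second season
(capped by the cohort pool so conservation holds even for small `rho`), 3%
of the *remaining* pool in the third, and 1% of the remaining pool per
season thereafter — all three rates configurable. The crop captures
remineralised N with efficiency `e_min` (default `r1`; how efficiently
soil-released N is recovered is genuinely unknown, so it is a separate
dial). Native soil N supply declines exponentially from `s0` to a floor
`s_min` at rate `k_dep`. Site, year and plot noise are additive on uptake
(kg N/ha; observation noise scaled by √replicates).

Useful exact identities of the noise-free generator (all under test): both
first-season methods return `r1`; pipeline ΔRE at year *t* equals
`e_min · flux(t) / n_rate`, which rises monotonically to the conservation
limit `e_min · rho`; and a proportional ¹⁵N under-recovery `delta15_bias`
(standing in for added-nitrogen-interaction biases) raises the
¹⁵N-vs-subplot ΔRE contrast by exactly `delta15_bias · r1`.

Defaults (`n_rate` 150 kg N/ha, `r1` 0.45, `rho` 0.30, 16 seasons, noise
SDs 4–6 kg N/ha, 3 field replicates) describe a mid-sized temperate cereal
LTE.

### Study-like fixture

`make_study_like_dataset` emulates the *statistical* shape of a published
nine-LTE synthesis: 66 recovery records over nine heterogeneous sites
(winter wheat and maize; durations ≈5–140 years; clay 15–28%; N rates
34–269 kg N/ha; three sites offering both first-season methods; pooled
multi-year records carrying larger weights). Here the record-level true
ΔRE is designed directly — 0.244 plus zero-mean site (SD 0.07) and
calendar-year (SD 0.04) deviations, clipped symmetrically at ±2 SD so the
mean is preserved — rather than routed through the remineralisation
schedule: under the schedule's own conservation constraints
(`e_min ≤ 1`, `r1 + rho ≤ 1`) short-duration sites cannot mechanically
reach legacy effects near 0.24, which real short LTEs nevertheless show.
The fixture is therefore labelled synthetic emulation, first-season
recoveries are drawn per site from N(0.438, 0.06) clipped to [0.30, 0.60],
and plot uptake noise is 8 kg N/ha before replicate averaging. Uptakes are
rounded to 0.001 kg N/ha so the 6-significant-digit CSV round-trip is
exact. Crops are restricted to two levels because, with nine sites and
eight site-level regressors plus an intercept, a third crop level would
make the site-level design exactly rank-deficient.

What passing tests on this fixture show — and what they do not: estimator
correctness (bias, CI behaviour, selection combinatorics) under the
assumed variance structure, not the field realism of any particular LTE.
Real data add features the generator omits: priming and pool-substitution
dynamics beyond a fixed proportional bias, residue-return N flows, weather-
driven uptake correlations, and non-Gaussian measurement error.

## Problem sizes used by the shipped checks

The test-suite and the acceptance script run the full 512-model dredge once
on a 66-record dataset, a 200-seed replication of the mean-ΔRE estimate,
and a 100-replicate selection-consistency simulation on a reduced four-term
candidate set (16 models per replicate) — sizes chosen to give stable
Monte-Carlo summaries in about two minutes of CPU.

## Known limitations

* No yield-response-curve fitting; the meta-model explains ΔRE only.
* The CI df convention is deliberately simple (see above); p-values for
  co-variable effects are Wald-t and convention-dependent, so they are
  reported but not treated as reference values.
* `direct_delta` records cannot contribute to RE-level summaries.
* The generator lumps all non-recovered, non-retained N into a single loss
  term and treats residue retention purely as a label.
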