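# ltelegacy

Crops recover only part of the synthetic nitrogen fertiliser applied in a
season — but fertiliser N retained in the soil keeps feeding crops in later
years. `ltelegacy` quantifies this **legacy effect** from long-term
experiment (LTE) data: field trials that have maintained fixed fertiliser
treatments on the same plots for decades. It is aimed at agronomists and
biostatisticians working with paired long-term / short-term N-recovery
observations.

## The statistics

For a site-year with a long-term fertilised plot (uptake $U^{N,LT}$), a
long-term zero-N control ($U^{0N,LT}$) and an annual rate $N_{rate}$:

* **Long-term apparent recovery**
  $RE^{LT} = (U^{N,LT} - U^{0N,LT}) / N_{rate}$ — includes uptake of
  fertiliser N applied in earlier seasons.
* **First-season recovery**, by one of two methods:
  *subplot* (withholding N for one season on a subplot,
  $RE^{1st} = (U^{N,LT} - U^{0N,ST}) / N_{rate}$) or
  *¹⁵N* (labelled fertiliser, $RE^{1st} = U^{15N} / {}^{15}N_{rate}$).
* **Delta recovery** $\Delta RE = RE^{LT} - RE^{1st}$ — the legacy effect,
  as a fraction of the annual N rate.

Records are pooled with a **weighted linear mixed model** with crossed
random intercepts for site and year,

$$y_i = x_i^\top\beta + u_{site(i)} + u_{year(i)} + \varepsilon_i,\qquad
\mathrm{Var}(\varepsilon_i) = \sigma^2 / w_i,$$

where $w_i$ is the replicate weight (years pooled × field replicates).
Variance components are estimated by profiled ML/REML implemented in-house;
nine candidate co-variables (three climate indices, crop, duration, average
N rate, clay, method, residue retention) are screened by exhaustive AICc
model selection ("dredge", 512 candidate models, ΔAICc > 2 rule).

A synthetic LTE generator — built on a multi-year remineralisation schedule
(10% of applied N in the second season, 3% of the remaining pool in the
third, 1% per season thereafter) — provides ground truth for validating
every stage.

## Worked example

```sh
$ ltelegacy simulate --study-like --seed 1 --out obs.csv cov.csv
wrote 174 observations to obs.csv
$ ltelegacy recover --obs obs.csv --cov cov.csv --out recovery.csv
wrote 66 recovery records to recovery.csv
$ ltelegacy meta --input recovery.csv --out report.json
mean ΔRE = 24.1% (95% CI 18.8 .. 29.3%), n = 66
```

The simulated nine-site dataset yields 66 recovery records; the weighted
mixed-model intercept estimates the mean legacy effect at 24.1% of the
annual N rate (the generator's designed truth is 24.4%), meaning roughly a
quarter of an annual application re-surfaces as extra crop uptake via
N retained from earlier years. `report.json` additionally holds the
weighted mean first-season and long-term recoveries, the ¹⁵N-vs-subplot
method contrast, and collinearity/normality diagnostics. The same pipeline
runs in one step (`ltelegacy all --seed 1 --outdir demo_run`), and on real
observation files by passing `--obs/--cov`.

As a library:

```python
from ltelegacy import delta_re_withheld

# 29 kg N/ha extra uptake after one season of withheld N,
# on a plot with a 192 kg N/ha history:
delta_re_withheld(89.0, 60.0, 192.0)   # 0.151  → ΔRE = 15.1% of N applied
```

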