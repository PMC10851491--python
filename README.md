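# redlinex

Case-crossover analysis of whether living in a historically-redlined
neighborhood modifies the short-term effects of ambient PM2.5 and
extreme heat on mortality from internal causes.

In the 1930s the Home Owners Loan Corporation (HOLC) graded urban
neighborhoods A ("Best") through D ("Hazardous", drawn in red). This
package implements, as a tested and reusable pipeline, the full analysis
needed to ask whether those grades still modify environmental health
risks today:

* **HOLC grade apportionment** — Census block groups receive a grade by
  a population-threshold rule: block populations are binned into the
  grade of the HOLC polygon containing the block centroid, and a block
  group is labelled with the single bin holding strictly more than a
  threshold share (default 90%) of its population, else `Ambiguous`.
  `redlined` means grade D.
* **Exposure assignment** — daily 1-km gridded PM2.5 is averaged over
  grid centroids inside each block (nearest-centroid fallback), then
  population-weighted to block groups; minimum/maximum temperature and
  vapor pressure are areal-weighted over intersecting grid cells; the
  calendar follows the 365-day (Daymet-style) convention with no Dec 31
  in leap years, so 2–5-day moving averages touching that day are
  missing.
* **Extreme heat** — a day is extreme when its minimum temperature meets
  or exceeds a percentile cutoff (default 95th) computed per block group
  per year; runs of ≥2 consecutive extreme days are heat waves with
  days numbered from the run start; isolated extreme days are
  singletons.
* **Case-crossover strata** — each death is compared with itself on all
  other same-weekday days of its calendar month (3–4 bidirectional
  referents), after a sequential exclusion cascade (external causes,
  age < 18, coarse geocodes, out-of-state, study window, zero-population
  block groups, leap-year lag windows) tallied in a ledger.
* **Conditional logistic regression** — per stratum *s* with one case
  row *c*, the log-likelihood is `Σ_s [η_c − log Σ_r exp(η_r)]` with

  ```
  PM2.5 model:  η = β₁·PM/10 + ns(TMEAN, 4) + ns(VP, 4) + β_int·redlined·PM/10
  heat model:   η = β₁·extreme + ns(VP, 4) + β_int·redlined·extreme
  ```

  where `ns(·, 4)` is a natural cubic spline (interior knots at pooled
  quartiles, linear beyond the range). The redlined main effect is
  stratum-constant and cancels; the interaction `β_int` is the estimand.
  Newton–Raphson with step-halving maximises the likelihood; results
  are odds ratios with Wald 95% CIs, PM2.5 per 10 µg/m³.
* **Synthetic data** — a seeded generator produces the whole input stack
  (city, HOLC polygons, grids, mortality records) with death days drawn
  within referent strata with probability ∝ exp(η) at known true
  coefficients, so parameter recovery is an exact-specification test of
  the estimator.

## Worked example

`examples/demo.yaml` simulates a 64-block-group city over 2001–2002 with
8,000 deaths and fits four analyses:

```bash
redlinex run-all --config examples/demo.yaml --out scratch/demo
# 4/4 cells fitted
```

`scratch/demo/results.csv` then holds one row per analysis cell, e.g.

```
exposure  status  n_strata  or_interaction  ci_low  ci_high  pct_excess
pm25      ok      7956      0.780           0.568   1.071    -22.0
any_heat  ok      7956      1.065           0.633   1.790      6.5
```

`or_interaction` is the multiplicative change in the exposure–mortality
odds ratio associated with residence in a redlined block group
(per 10 µg/m³ for PM2.5), with its Wald 95% interval and the equivalent
percent excess daily risk. At this demonstration scale the intervals are
wide and comfortably cover the small generative truths (log OR ≈ 0.01);
the replicated recovery study in `tests/test_acceptance.py` shows the
estimator is unbiased and calibrated at 20,000 strata. The exclusion
ledger (`exclusion_ledger.csv`) mirrors the subject-restriction
flowchart: here 44 deaths fall before the January 5 study start (the
date that lets lag 4 reach January 1).

The same steps are available piecewise (`simulate`, `crosswalk`,
`exposures`, `heat`, `strata`, `fit`) and as library functions.

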