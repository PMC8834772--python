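# ocburden

Bayesian age–period–cohort (APC) projection of cancer-registry burden.

Population-based cancer registries publish event counts (incident cases or
deaths) and person-years at risk by 5-year age band and calendar year.
Public-health planners need those series carried forward a decade or more,
with honest uncertainty, and need the resulting change in case numbers
explained: how much is falling risk, how much is an aging population, how
much is population growth?  `ocburden` packages that workflow — built around
the projection of ovarian-cancer incidence and mortality in a
Catalonia-like registry setting (women aged ≥ 45, annual data from the
mid-1990s, projections to 2030) — for epidemiologists and biostatisticians
who want the whole chain reproducible from CSV in, CSV out.

## The model

Counts are Poisson with a log-linear age–period–cohort decomposition:

    y[a, p] ~ Poisson(n[a, p] · λ[a, p])
    log λ[a, p] = μ + α_a + β_p + γ_c,   c = p − a

* **α** (age): second-order random walk — a smooth age-incidence curve;
* **β** (period): first-order random walk *with drift* — the drift carries
  the calendar trend into the projection years;
* **γ** (birth cohort): first-order random walk without drift, on a 5-year
  cohort grid (band midpoint rule);
* half-normal hyperpriors on the innovation SDs, diffuse normals on μ and
  the drift.

Because cohort = period − age, one linear trend is not identifiable; the
package fixes the allocation with hard constraints (α, β, γ sum to zero and
γ is linearly detrended, so the net drift sits on the period axis) and
samples directly in the constrained subspace with a non-centred
parameterisation.  Inference is ensemble MCMC (emcee), mode-initialised,
seeded and reproducible draw-for-draw; rank-normalised R-hat / ESS come
from arviz and non-convergence is flagged, never swallowed.  Projections
simulate the period and cohort walks forward per posterior draw, so 95%
prediction intervals widen with the horizon.  Around the model sit:

* truncated age-standardised rates (ASR) to the European Standard
  Population (2013 bundled as default, 1976 as alternative), per 100,000
  women-years;
* annual average percent change (AAPC), endpoint-geometric or
  log-linear-regression;
* the Bashir–Estève decomposition of the net change in cases,
  NC = A + R|A + S|A (aging, risk given aging, size given aging), via
  counterfactual expected-case ladders;
* a synthetic-registry generator with known APC truth for validation.

## Worked example

```python
import ocburden as ob

config = ob.RunConfig(outdir="demo-run", seed=11)   # bundled scenario
report = ob.run_pipeline(config)
print(report.burden["incidence"].to_string(index=False))
print(report.decomposition["incidence"].to_string(index=False))
```

This synthesises a Catalonia-like registry (nine 5-year bands 45–49 … 85+,
observed 1994–2017), fits the APC model for incidence and mortality,
projects to 2030 and prints, among the other outputs:

```
  outcome  year  N <45  % <45  N 45-54  % 45-54  N 55-64  % 55-64  N 65-74  % 65-74  N 75+  % 75+  N total  net_change_pct  asr
incidence  2015     38   17.8       22     10.3       37     17.4       53     24.9     63   29.6      213             NaN 10.8
incidence  2030     36   22.0       13      7.9       24     14.6       38     23.2     53   32.3      164           -23.0  7.2

  cases_baseline  cases_final  net_change_pct  aging_pct  risk_pct  size_pct
           175.9        127.8           -27.3        5.5     -35.7       2.8
```

Reading it: modelled cases fall from 213 to 164 (−23.0%) between the two
reference years while the ASR drops from 10.8 to 7.2 per 100,000
women-years, and the decomposition attributes the decline to falling
age-specific risk (−35.7%) partially offset by population aging (+5.5%)
and growth (+2.8%) — the three components summing exactly to the net
change.  The run directory also contains the projected counts with 95%
prediction intervals, the ASR series with intervals, AAPC values, the
cohort/period relative-risk curves (the bundled scenario has a configured
risk rebound for cohorts born in the early 1980s, visible as the peak of
the cohort curve), posterior draws, diagnostics and a JSON manifest.  The
same pipeline runs from the shell:

```bash
ocburden run-all --seed 11 --outdir demo-run
ocburden simulate --outdir synthetic-tables
ocburden decompose --rates-baseline r1.csv --pop-baseline n1.csv \
                   --rates-final r2.csv --pop-final n2.csv --out dec.csv
```

Real data enter through the same CSV dialect (`age_band,year,value`, long
or wide) via a `RunConfig` with per-outcome `inputs` paths.

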