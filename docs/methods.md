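# Methods

## Model

Registry events are modelled as independent Poisson counts with
person-years as exposure:

    y[a, p] ~ Poisson(n[a, p] · λ[a, p]),
    log λ[a, p] = μ + α_a + β_p + γ_c(a, p).

The lattice uses annual periods and 5-year age bands with an open top band;
ages under 45 are excluded from the model because event rates there are
very low (they are reported separately, see below).  The birth cohort of a
cell is the calendar year minus the band midpoint rounded down (the open
top band is treated as 5 years wide for its midpoint), bucketed onto a
5-year grid.  This midpoint rule makes cells one band up and five years
later share a cohort, and the observed buckets form a contiguous sequence
(checked at design time).

Priors:

* **Age** α: second-order random walk — second differences
  N(0, σ_α²) — giving a smooth age curve with a free linear slope that the
  likelihood identifies.
* **Period** β: decomposed as drift · (p − p̄) plus deviations whose first
  differences are N(0, σ_β²); together this is a first-order random walk
  with drift.  The drift is what propagates the calendar trend into the
  projection.
* **Cohort** γ: first-order random walk, no drift, one step per 5-year
  bucket.
* Half-normal hyperpriors on (σ_α, σ_β, σ_γ); diffuse normals
  N(0, 10²) on μ and the free age slope, N(0, 1²) on the drift.

### Identifiability

cohort = period − age makes one linear trend exchangeable between the
three axes.  The package fixes the allocation by hard constraints rather
than by prior softness: α, β and γ each sum to zero, and γ is additionally
orthogonal to a linear trend in cohort (zero "cohort drift"), so the whole
net drift is carried by the period axis.  Any fixed allocation yields the
same fitted and projected rates; the constraint only decides how the trend
is labelled.  A least-squares projection of an arbitrary log-rate surface
onto this constrained basis (`decompose_surface`) defines the unique
"centred" coordinates used both to express simulation truths and to verify
that equivalent reparameterisations of a surface yield identical
constrained effects.

### Sampling

The posterior is explored with affine-invariant ensemble MCMC (emcee;
differential-evolution and snooker moves, 80/20), vectorised over walkers
and initialised in a small ball around the posterior mode (L-BFGS on the
log posterior).  The random-walk effects are parameterised
**non-centredly**: the free coordinates are standardised innovations that
are scaled by the innovation SDs and integrated inside the density.  The
centred form puts a funnel between each effect vector and its hyperprior
SD; ensemble moves get trapped in the σ → 0 neck, which in testing
collapsed the period/cohort effect intervals to near-zero width and
destroyed calibration.  The non-centred form removes the funnel entirely.

Defaults: walkers = 2·ndim + 2 (min 64), 4000 burn-in + 4000 retained
steps thinned by 10, 2000 retained posterior draws, all seeded through a
single integer (`APCSpec.seed`); identical seeds reproduce every draw
bitwise.  Convergence is summarised by rank-normalised split R-hat and ESS
(arviz) computed over walkers treated as chains.  The convergence flag
uses the strict threshold R-hat ≤ 1.01; ensemble walkers mix by a
high-dimensional random walk, so at default lengths the maximum R-hat
typically sits at 1.05–1.3 and the flag raises a warning.  This is
reported honestly rather than hidden: the quantities the package reports
(posterior medians, 95% intervals) are pooled over ~100 walkers and are
stable across seeds at these settings (the parameter-recovery and
calibration tests quantify exactly that), but users running one-off
analyses should lengthen the chains (`n_burn`/`n_steps`) until the flag
clears if they need publication-grade per-parameter diagnostics.

### Projection and prediction intervals

Future period effects continue the random walk with drift per posterior
draw (new innovation noise each year); future cohort buckets continue the
cohort walk.  Projected counts are Poisson draws around rate ×
person-years per draw, so the 95% prediction intervals contain parameter,
process and sampling uncertainty and widen with the horizon.  Future
person-years must be supplied (zero person-years give zero counts);
zero person-years in the *fitting* data are an error, not imputed.

## Rates, trends, decomposition

* Age-specific rate: 100000 · y / n.
* Truncated ASR: standard-population weights over the included (≥ 45)
  bands, renormalised to sum to 1, dotted with the age-specific rates.
  Renormalisation keeps the constant-rate identity exact (ASR of a flat
  surface equals the flat rate under any standard).  ESP 2013 is the
  bundled default, ESP 1976 the alternative; both ship as CSV package
  data summing to 100,000.  ASR prediction intervals are quantiles of the
  per-draw ASR of the posterior rate surface.
* AAPC: endpoint-geometric, 100·((r_to/r_from)^(1/(to−from)) − 1), as the
  default (it is the quantity the two printed reference-year ASRs
  determine); a log-linear regression variant is provided for annual
  series.  The two agree exactly on exactly exponential series.
* Net-change decomposition (Bashir–Estève): the counterfactual ladder
  applies population size first, then age structure, then risk —
  C1 → C1·T2/T1 → Σ r1·N2 → Σ r2·N2 — giving components S|A, A and R|A as
  percentages of baseline cases that sum to the net change exactly.  All
  components are relative to baseline cases; that is what makes the
  published triple additive.  Point partition only; no uncertainty is
  propagated through the decomposition.
* Burden tables round for display exactly as published tables do (N as
  integers, row percentages 1 d.p., net change 2 d.p., ASR 1 d.p.);
  full-precision companions are always written.  Published tables round
  percentages from unrounded model outputs, so percentages recomputed
  from printed integer counts can differ from the printed percentage by
  one unit in the last digit; the tests assert agreement to the printed
  precision.

## Under-45 reporting

The <45 band never enters the APC model, but burden tables report it.  It
is projected by a year-only log-linear Poisson trend (maximum likelihood,
two parameters) on the observed <45 series and merged into the table,
labelled like any other row.  A constant observed series projects that
constant; an exactly exponential series is extrapolated exactly.

## Synthetic-registry generator

The generator emulates the study conditions: nine 5-year bands
(45–49 … 85+), years 1994–2030 with 1994–2017 observed, an
ovarian-cancer-like age curve (15–35 per 100,000, peaking at 75–84),
log-linear period (−1%/year) and cohort (−1.5%/birth-year) declines, a
Gaussian log-RR rebound of +0.3 centred on birth year 1982 (width 2 years)
for the 1980s cohorts, and a ~1.5-million-women demography growing 0.3%/yr
with a gradual tilt toward older ages.  Base person-years (~0.6–2.5 × 10⁵
per band) put annual band counts in the tens, the realistic Poisson-noise
regime for a region of this size.  The cohort *drift* is linear in exact
birth year, so it decomposes exactly into period and age components and
the truth surface lies in the model family; only the bump is a genuine
bucketed cohort effect, which keeps the "true constrained effects"
well defined and makes the bump-location test exact.  The bump width was
set at 2 years so that the scenario simultaneously satisfies its two
defining properties: a cohort-curve maximum at the 1980–1984 bucket and a
strictly decreasing noiseless ASR through 2030 (a wider bump produces a
small ASR uptick in 2027 when the bump cohorts reach age 45, because all
bands change 5-year cohort bucket in the same calendar year under the
midpoint rule).

Counts are independent Poisson draws per cell, bitwise-reproducible per
seed.  What the generator does **not** emulate: registry reporting delay,
completeness drift, duplicate records, subtype composition shifts, and
any non-Poisson overdispersion.  Passing tests therefore show that the
method recovers structure from clean Poisson registries of realistic
size — not that it is robust to real-registry artefacts.

## Pipeline

One configured run per outcome (incidence, mortality fitted
independently): load or synthesise tables → fit → project → ASR/AAPC →
relative-risk curves → burden table on reporting bands (10-year pairs,
75+ open) → decomposition between the two reference years, plus a JSON
manifest (config, seed, version).  Every burden number is recomputable
from the emitted intermediate CSVs.  For reference years inside the
observed range the pipeline reports the model's fitted (posterior-median)
value, which smooths sampling noise in the observed year.  A stage
failure removes the partial outputs and names the stage.  Identical
config + seed gives a byte-identical bundle (the manifest records the
output path itself).

## Test and validation sizes

The suite validates the sampler on reduced problems chosen as the package's
standard validation sizes: parameter recovery and bump detection on the
full 9-band scenario at 2000 + 2000 × (thin 10) chains; interval
calibration on a 5-band, 12-observed-year variant with 5 fits × 40
replicate observation sets (200 replicates total, pooled over projected
cells); recovery-RMSE monotonicity across person-years scaled ×1, ×10,
×100.  The flat-surface oracle compares posterior median rates against the
analytic events/person-years estimate with period and cohort effects
clamped (`include_period=False`, `include_cohort=False`).

## Known limitations

* Ensemble MCMC is the package's inference engine; per-parameter R-hat at
  the strict 1.01 threshold requires longer chains than the defaults.
* The decomposition is a point partition; no intervals.
* Incidence and mortality are modelled independently; no shared-survival
  linkage between them.
* No overdispersion term: real registries with extra-Poisson variation
  will get too-narrow intervals.
* The ESP revision used by any given published ASR is a configuration
  choice (`esp2013` default); truncated weights are renormalised, which is
  one of several truncated-ASR conventions.
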