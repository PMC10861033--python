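# Methods

## The double pair comparison estimator

Fatality censuses are outcome-selected: a crash is recorded only if it
killed someone, so subject-group fatality counts cannot be divided by an
exposure denominator. The double pair comparison sidesteps exposure by
using a co-occupant of the same vehicle as an internal control. For a
subject cohort (say female drivers aged 23–27, belted, passenger cars)
and a fixed control cohort (say belted male front-right passengers aged
16–24), every qualifying vehicle contributes one subject–control pair.
The ratio `r1 = A/B` of subject deaths to control deaths over those
vehicles is a consistent estimate of the ratio of their per-crash death
probabilities: a death, by itself, guarantees the vehicle's inclusion in
the census, so selection removes no death events from either count. The
same ratio for male subjects, `r2 = C/D`, shares the control cohort, and
`R = r1/r2` cancels the control's risk entirely. `R > 1` means higher
female risk under matched conditions.

### Stratified counts and the variance of ln R

The classical error formula attaches an "intrinsic uncertainty" constant
to `R` (implemented in `evans_error`, with `sigma_mu` ∈ {0.05, 0.1});
because that constant drags every stratum's error toward a common floor
it distorts inverse-variance weights, and it is kept only as a legacy
comparator. Instead each aggregate count is split by whether the paired
occupant also died — `a` (both died, female subject), `b` (subject
only), `c` (control only), and `e, f, g` for male subjects — giving
`A = a+b`, `B = a+c`, `C = e+f`, `D = e+g` and the count-based variance

```
var(ln R) = [ (a(a+b+c) + bc)(f+g) + (e(e+f+g) + fg)(b+c) ]
            / [ (a+b)(a+c)(e+f)(e+g) ]
```

The published display of this expression has unbalanced brackets; the
completion implemented here is the unique one symmetric under swapping
the female `(a,b,c)` and male `(e,f,g)` triples, a symmetry the
estimator itself obeys (`R → 1/R` under the swap, variance invariant).
Both properties are asserted in the test suite, as is the hand-evaluated
point `a=0, b=c=1, e=0, f=g=1 → var = 4` and the exact `1/k` scaling
under count inflation.

### Pooling

Stratum log risk ratios are combined as

```
R_bar  = exp( Σ ln(R_i) w_i / Σ w_i ),    w_i = 1 / var_i
var_bar = 1 / Σ w_i
```

with the weights taken as the reciprocal of the variance exactly as the
published formulas read; the source text is ambiguous about whether its
pooled-dispersion symbol denotes a variance or a standard error, so the
variance reading is the default and `weight_mode="inverse_sq"` exposes
the alternative for sensitivity analysis. Because `var_bar` is again a
reciprocal weight sum, this pooling is associative: pooling the eight
control cohorts within each subject stratum and then pooling those
summaries (the two-level layout of the per-subject summary tables)
yields the identical number as pooling all strata flat. The
implementation exploits this (one flat pool) and a test asserts the
collapse.

Strata where any of `B`, `C`, `D` (or `A`, which would send `ln R` to
−∞) is zero are undefined and dropped from pooling with a count, rather
than continuity-corrected — small cells are handled by exclusion, not
adjustment. A stratum with deaths but no discordant pairs has variance
exactly zero (infinite weight); such degenerate strata are excluded
whenever at least one informative stratum exists, and pooled with equal
weights only when they are all there is (which makes a dataset whose
every stratum is forced to `R = 1` return the point interval [1, 1]).

### Bootstrap confidence intervals

CIs are 95% percentile intervals of the pooled estimate over resampled
datasets (no bias correction or acceleration, matching the middle-95%
description of the published procedure). The resampling unit is the
**vehicle** within the case-selected dataset: vehicles are the
independent sampling units and resampling them preserves the
within-vehicle dependence between subject and control outcomes.
Stratum-level resampling of `(R, var)` summaries is available as
`resample="strata"` for diagnostics. Replicates on which no stratum is
usable are redrawn, up to ten times the requested replicate count, and
reported in `n_redrawn`. The default is 5,000 replicates per pooled
estimate; tests and the acceptance script use 500–1,000 with fixed
seeds, which changes percentile noise, not coverage. For speed, each
stratum's pairs are reduced once to (vehicle code, outcome class) pairs,
so a replicate is a single weighted bincount under the resampled vehicle
multiplicities — replicate tabulation is exactly the full-data
tabulation evaluated under integer vehicle weights.

## Case selection, matching and binning

Vehicles qualify with ≥ 2 occupants, ≥ 1 occupant death, no rollover,
and the configured body type, year range, impact direction and
crash-size (one / two / three-plus vehicles) filters; all occupants of a
qualifying vehicle are kept together. Subject ages use closed five-year
windows centered on the nominal age (center ± 2 years, so the
25-year-old cohort is ages 23–27); sweeps step centers by five years
(disjoint windows) by default, since the published age curves do not
state an overlap convention. Control ages use the conventional coarse
bands 16–24, 25–34, 35–54, 55+.

Airbag handling follows the matched-deployment convention: under
`matched` both occupants' deployment status must be known and equal, and
unknown status excludes the pair. The `subject_deployed` /
`subject_not_deployed` modes additionally fix the shared state — the
per-subject summary tables split "airbag deployed" vs "not deployed"
*within* the matched condition, so both occupants deployed (or neither)
is the faithful reading. Occupants with unknown sex, age, belt use, or
seat are excluded from pairing (the published rule is explicit only for
airbags; extending it to the other matching attributes is this package's
choice, since every one of them is a stratification variable). A vehicle
with several eligible controls contributes one pair per control; pairing
is strictly within-vehicle.

## The synthetic generator

`synthetic.generate` emulates the structure the estimator relies on:
crashes holding 1–3 vehicles, vehicles holding 1–5 occupants seated
driver-first, a census inclusion rule (≥ 1 death per crash, enforced by
discarding and regenerating non-qualifying crashes), and a latent
per-crash severity `s ~ lognormal(median 1, σ = 0.5)` shared by all
occupants of the crash. Deaths are Bernoulli with
`p = min(1, base_lethality[seat] · s · m)`, where `m = 1` for males and
`m = true_R(age)` for females. Defaults — chosen once as plausible
census-like study conditions — are: occupancy distribution
(0.35, 0.45, 0.12, 0.06, 0.02) over 1–5 occupants; vehicle-count
distribution (0.35, 0.50, 0.15) over 1–3; 72% passenger cars; 8%
rollovers; 42% female occupants; ages 65% uniform 16–40 and 35% uniform
41–90 (concentrating mass in the young cohorts the analysis targets);
72% belt use; 62% frontal airbag deployment drawn once per vehicle front
row so matched deployment is the common case (per-seat deployment is a
config option); per-seat baseline lethality 0.12–0.17. Optional
`unknown_rates` mask fields to `unknown` after the outcome draw, so
missingness is non-informative by construction.

Because both sexes share `s` and the seat scale, the female/male ratio
of death probabilities equals `true_R` wherever the `min(·, 1)` clip
does not bind, making `true_R` the exact estimand of the double pair
pipeline in the small-probability regime; `known_truth` integrates the
clipped ratio over the severity distribution and warns when attenuation
exceeds 1%. Under the defaults the clip binds for well under 0.1% of
occupants.

What the generator does **not** emulate: crash physics and vehicle-mass
effects, correlated belt use within vehicles, age–seat correlation,
informative missingness, secular trends across calendar years, and
exposure differences between sexes. Passing recovery tests therefore
demonstrate the estimator's correctness under its own assumptions
(shared severity, multiplicative sex effect, non-informative
missingness), not robustness to their violation in real census data.

## Verification scale and results computed

The checks the suite runs (sizes chosen to make Monte-Carlo noise small
relative to the asserted tolerances):

- parameter recovery: one dataset of 50,000 qualifying crashes,
  injected `true_R = 1.2`, two-level pooling at age center 25 over
  8 subject strata × 8 control cohorts, 1,000 bootstrap replicates;
  asserted within ±0.08 of truth and within 3 bootstrap SEs (across
  independent seeds the point estimates average 1.20 with SD ≈ 0.05 at
  this scale);
- null calibration: the same at `true_R = 1.0`, asserted within ±0.05;
- CI coverage: 200 datasets of 5,000 qualifying crashes, 500 replicates
  each; observed coverage 0.985, asserted within [0.90, 0.99] (vehicle
  resampling with many sparse strata is mildly conservative);
- exact agreement of vectorized pairing/tabulation with exhaustive
  double-loop oracles on randomized vehicles, and of pooling with a
  direct summation oracle.

## Known limitations

- The row-level worked example is reproduced exactly, but its published
  pooled value (1.047 [0.832, 1.267]) cannot be recomputed: the
  stratified counts behind the variance weights are unpublished. The
  package reports this rather than approximating the weights.
- Census-scale headline estimates require the full occupant census,
  which is not redistributed here; the synthetic recovery checks stand
  in for them.
- Undefined strata are dropped, so sparse configurations (old-age
  centers, rear-seat subjects in recent years) can pool over few strata;
  `n_strata`/`n_dropped` expose this and very sparse subsets should be
  read with the same caution the published analysis applies (subsets
  with fewer than ~15 fatalities were excluded there).
- Percentile bootstrap intervals can in pathological cases exclude the
  point estimate; the estimate object carries the replicate quantiles so
  such cases are visible.
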