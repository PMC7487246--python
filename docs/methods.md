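# Methods

`topophen` analyses how topographic aspect — the pairing of cooler
north-facing and warmer south-facing slopes — stretches the season over
which a grassland offers flowering resources to pollinators. This note
documents the models and conventions the package implements, the
synthetic landscape its tests run on, and the choices made where the
design was genuinely open.

## Phenology from count surveys

The atomic observation is an inflorescence count for one species in one
1 m² plot on one survey date. For any aggregation level (plot community,
aspect, whole site, or a single species within an aspect) counts are
pooled by summation per date and converted to a cumulative proportion

    F(d) = (flowers counted through day d) / (total flowers over the season).

Start, mid and end of flowering are the days at which F first reaches
0.05, 0.50 and 0.95; duration is end − start. Two threshold conventions
are available:

* **step** (default): the first *observed survey date* with F ≥ q. This
  matches weekly field surveys, where a threshold "has been reached" at
  the survey that detects it. Dates are quantized to the survey grid.
* **interp**: linear interpolation of F between surveys. Same ordering,
  finer resolution.

A species recorded in flower on a single survey date gets a nominal
1-day duration when the single-date rule is on (default): the data
cannot resolve how long it actually flowered between visits.

Entities whose season total is zero are flagged "no flowering" and
excluded downstream rather than raising.

## The extension statistic

For a site × year with durations `dur_S`, `dur_N` on the two aspects and
a combined-aspect duration `Combined`,

    Longer    = max(dur_S, dur_N)
    Extension = (Combined − Longer) / Longer × 100.

This is conservative: only days beyond the *longer* single aspect count
as gained. Two conventions for `Combined` are computed:

* **pooled** (default): counts from both aspects' plots pooled into one
  cumulative curve, re-thresholded at 5–95%. Because each 5% tail of the
  pooled curve absorbs part of the earlier aspect's flowering, pooled
  extension is small whenever the two aspects overlap strongly, and can
  be negative under abundance imbalance; such cases are flagged, never
  clamped.
* **union**: the union of the two aspect intervals (mean plot start to
  mean plot end per aspect), with any between-aspect gap removed. For
  two equal-length, time-shifted curves this equals the shift.

Per-aspect duration defaults to the mean of the three plot-level
durations (`plot_mean`); pooling the plots first is available.

Species-level extension uses the union convention on the two aspect
intervals of a species present on both aspects, with
`gap = max(0, later start − earlier end)` removed from the union
measure. When the single-date rule makes a nominal duration exceed the
interval measure, the combined duration is floored at the longer nominal
duration so species-level extension is never negative.

**Turnover decomposition.** Absolute turnover at a site-year is the
count of species flowering on only one aspect. The community extension
is recomputed with the records restricted to species present on both
aspects; the difference (full − shared-only) is the turnover-attributed
extension. Turnover is also regressed on extension days by OLS.

**Complementarity sign test.** Across site-years, "success" means the
aspect that starts flowering earlier also ends earlier; exact ties on
start or end are excluded from n and reported. The p-value is the exact
two-sided binomial test at p₀ = 0.5 (minimum-likelihood two-sided
convention).

## Microclimate

Growing degree-days use daily-mean soil temperature clipped at a 5 °C
base, accumulated March–June. Hourly readings are averaged into daily
means first; gaps up to 7 days are linearly interpolated, longer gaps
must be filled with `gap_fill_temperature`, which substitutes the same
sensor's other-year mean for the missing day plus an air-temperature
adjustment (target-year minus donor-year air mean over the month
containing the gap). Paired S/N GDD totals get the exact binomial sign
test. Soil moisture (volumetric water content, %) is compared on the log
scale with aspect, site and measurement date as categorical fixed
effects; a date label encodes its year, so year is not entered as a
separate (aliased) term.

## Inference

All models are ordinary least squares with reference-level dummy coding,
the reference being the first level alphabetically; interactions are
products of coded columns. Rank-deficient designs raise an error naming
the aliased columns (pivoted QR). The Gaussian log-likelihood uses the
ML variance RSS/n, and

    AICc = −2 logL + 2k + 2k(k+1)/(n − k − 1)

with k the coefficient count including the intercept (the variance
parameter is not added to k). Nested models are compared with the
extra-sum-of-squares F test, F = ((RSS₀−RSS₁)/Δk)/(RSS₁/(n−k₁)). The
marginal R² of a focal term is var(X_focal β_focal)/var(y), an
all-fixed-effects analogue of the mixed-model marginal R²; it equals the
ordinary R² for a single-predictor model. Mixed-effects machinery is
deliberately out of scope: the aspect/site/year structure here is
fully crossed and small, and fixed effects answer the same questions;
the conditional R² reported alongside marginal R² in mixed-model
analyses therefore has no analogue in this package.

## The synthetic landscape

The generator produces the statistical structure the analysis assumes,
so every stage is testable without field data.

**Temperature.** Hourly soil temperature per site × aspect sensor =
seasonal linear warming (10 → 18 °C over the season at the north
baseline) + a 2 °C damped diurnal sinusoid (10 cm soil depth) + a
per-site offset (sd 0.5 °C) + a per-year offset + the south-aspect
offset (default 3.06 °C) + iid Gaussian noise (sd 0.5 °C). With noise
off, every paired S−N reading equals the offset exactly.

**Surveys.** Each of the 32 pool species has a peak flowering day; the
default layout is an even succession: peaks equally spaced across a
±√3·15 day span around DOY 115 (so their sd matches `var_species_peak`)
plus a 15% jitter — the classic staggered-succession picture of a
spring-flowering community. (An iid-normal layout is available, but
equal-abundance iid peaks make lumpy multimodal community curves whose
median responds erratically to composition differences.) The realized
peak of species *i* in plot *p* and year *t* is

    peak_i + site_shift + genotype(i, p) + plot_noise(i, p, t)
        − sensitivity × (T(p, t) − T̄)

with `T(p, t)` the plot's (= its aspect sensor's) mean March–May soil
temperature and T̄ the landscape mean, so south plots flower earlier by
sensitivity × offset ≈ 3.4 × 3.06 ≈ 10.4 days in expectation. Expected
counts follow a Gaussian-shaped curve (sd 7 days) evaluated at the
weekly survey dates and normalized to a season total of
`abundance_mean = 50`, so the expected total per species × plot is
conserved exactly; observed counts are Poisson draws. A species whose
curve mass falls entirely outside the season raises an error naming the
offenders rather than silently truncating. Zero-count records are kept —
downstream curves need the support.

**Turnover.** A fraction (default 0.3) of each site's species occur on
one aspect only, implemented as *guild-replacement pairs*: two species
adjacent in the pool's flowering succession are split between N and S,
with orientation alternating between a site's pairs. This emulates an
aspect specialist being replaced on the opposite slope by a different
species flowering in a near-identical window, so the two aspects keep a
comparable community phenology structure while species identities (and
hence turnover counts and the shared-species analysis) differ. The
specialist count is rounded to whole pairs, so per-site turnover is
even.

**Variance components** (days², calibration choices — the study system
does not pin them down): `var_species_peak = 225` (species peaks span
~7 weeks; community 5–95% durations come out near 50 days, matching the
field-scale values), `var_site = 25` read as one community-wide timing
offset per site (sd 5 days; sites within a couple of kilometres differ
in soils and exposure), `var_genotype = 4` (zeroed in fixed-genotype
mode), `var_plot_noise = 4`. Year temperature offsets default to
(0, +0.5, −1.0, +0.3) °C across the four seasons, making the third year
the coolest and latest-flowering.

**Moisture.** Log-scale VWC declines over the season (drydown); north
aspects are wetter by 0.157 on the log scale (≈ +1.7 %VWC at a ~10%
south-aspect baseline), with lognormal measurement noise.

**Fixed-genotype mode** emulates common-seed subplots: a single species,
no turnover, genotype variance forced to zero, so any aspect difference
in timing is plasticity.

**What the generator does not emulate.** Abundance is equal across
species (real communities are strongly uneven); specialists replace each
other in matched flowering windows, so turnover contributes little extra
extension here — the turnover-vs-extension regression is correspondingly
weak, whereas in real landscapes turnover can dominate; there is no
spatial terrain, insolation or soil-physics model, no pollinator
behaviour, and survey dates are a perfectly aligned weekly grid. Tests
passing on this landscape show the estimators recover known parameters
under the assumed structure, not that the structure captures any
particular field system.

## Parameter recovery and problem sizes

`topophen.recovery` regenerates a default landscape (5 sites × 4 years —
20 site-years, 120 plot-year mid dates, ~117k hourly temperature
readings) and re-estimates (a) the sensitivity slope from the
fixed-effects regression of plot-level midflowering on mean March–May
temperature with site and year factors, and (b) the mean paired S−N
daily-mean temperature contrast. Across seeds the slope recovers
−3.38 ± 0.14 days/°C against a generating value of −3.4, and the
contrast 3.06 ± 0.01 °C.

Regressions use the **interp** threshold convention: step dates are
quantized to the weekly grid (±3.5 days) and, because every site shares
the same survey calendar, that error does not average out across sites;
interpolation removes it without changing any ordering. Descriptive
tables keep the step convention.

## Numerical and degenerate-case conventions

* DOY is 1-based calendar day; durations are simple differences.
* The step threshold uses a 1e-12 tolerance when comparing cumulative
  proportions to the quantile, so exact fractions are not lost to
  floating-point rounding.
* A site-year with flowering on only one aspect gets combined = that
  aspect's duration and extension 0, flagged `single_aspect`.
* A site-year with no shared species yields a flagged missing
  shared-only result.
* Sign tests with every pair tied report the tie count and no p-value.
* Model comparisons restrict to sites observed in every year (balanced
  design); species-level tables keep all sites.

## Known limitations

* Pooled-count combined durations under strong aspect overlap give
  small (sometimes negative) extensions by construction; the
  interval-union value is reported alongside for comparison.
* The marginal R² is a fixed-effects analogue, not the mixed-model
  quantity, and will differ from values computed under random site or
  year effects.
* Gap-filling assumes donor years share the seasonal shape of the
  target year up to an additive air-temperature shift.
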