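# Methods

This note documents the models behind `arscore`, the defaults they ship
with, and what the synthetic components do and do not emulate.

## The ARS methodology

The annual risk score quantifies *perceived* climatic risk during one
production season of one crop.  At each scheduled observation point (OP)
the farm agent compares a set of observable state variables against
per-parameter **acceptance ranges**.  An observation inside its range
earns utility score 0 (no perceived risk); outside, 1.  Scores are summed
per OP (α_t = Σ_i α_i) and over the season (ARS = Σ_t α_t), with no
inter-temporal weighting — utility is revealed only ex post, so no OP is
privileged.  OP 0 scores the sowing date itself: 1 when the chosen
day-of-year historically led to an acceptable yield in fewer than half of
the years, 0 otherwise (a frequency of exactly 0.5 scores 0, per the
strict "less than" rule).  Under the default scheme — 10 parameters at
each of 7 OPs, plus OP 0 — the annual maximum is 71.

Boundary convention: values exactly on a range bound score 0.  The bounds
are whisker data points taken from seasons that met the yield threshold,
so the bound value itself was, by construction, acceptable.

Failed seasons (maturity never reached) score their unreached OPs at the
full parameter count.  A season that dies mid-way must not out-score a
completed risky season; the record flags which OPs were imputed.

### Acceptance-range initialization

The ranges embody simulated experience.  A what-if grid — every sowing
day-of-year in a plausible window crossed with every historical weather
year — yields one season per cell (default: 46 DOYs starting at 283 × 30
years = 1,380 seasons).  Seasons whose final yield fell below the
still-good yield (**sgy**, default 69.17 dt/ha) are discarded; for each
(OP, parameter) the surviving values are summarised by Tukey boxplot
whiskers: outliers lie below q1 − 1.5·IQR or above q3 + 1.5·IQR, and each
whisker is the innermost actual data point within its fence.  Quartiles
use linear interpolation between order statistics (the default of
mainstream statistics software); the convention is recorded in the pool's
provenance because whisker positions depend on it.  OP 0 is summarised
differently: the relative frequency, per sowing DOY, of seasons with
yield ≥ sgy, computed over *all* seasons including failures.

The sowing window deserves a note: the plausible window is described in
the source material both as days 283–324 and as 46 distinct days; the
package adopts 46 consecutive days from 283 (283..328) so the grid
cardinality is exactly 46 × 30, and leaves the window fully configurable.

### Observation schedule

OP 1 is 30 days after sowing; OPs 2, 4 and 5 coincide with the three
fertilizations (triggered at BBCH 25, 30 and 39); OPs 3 and 6 trail
fertilizations 1 and 3 by 14 days; OP 7 is harvest.  The ten parameters
are LAI, soil water at 30/60/90/120 cm, soil temperature at 5/10/50 cm,
biomass and BBCH.  At OPs 1–6 the biomass parameter is above-ground
biomass; at harvest it is generative (grain) biomass.  BBCH doubles as
the trigger variable and a scored parameter; a configuration switch
(`include_bbch=False`) excludes it from scoring for users who consider
that double duty circular.  Snapshots are end-of-day states on the OP's
date.

### Adaptation

After a new season is scored, three cases govern learning.  Yield ≥ sgy
with observations in range: the values join the distributions and the
whiskers are recomputed (normally a negligible move).  Yield ≥ sgy with
observations out of range: the values still join, as non-downside-risk
points; when such outliers accumulate they eventually shift the range.
Yield < sgy: the ranges are untouched — the loss is exactly what the
threshold predicts — but the OP-0 frequency of the season's sowing day is
updated either way.  The fourth combination (in-range observations,
yield < sgy) follows the yield gate and is excluded, consistent with the
initialization filter.  Expected ARS per crop is a weighted mean of past
totals; uniform weights are the default, with exponential-decay and
fixed-window schemes available because how learning should be weighted is
genuinely open.

The planning constraint compares a crop's current score, summed over the
fields growing it, with its expected score.  The literal inequality
(current ≥ expected is "satisfied") is internally inconsistent with ARS
being a *risk* score, where lower is better; the package ships both the
literal and the inverted reading behind a `mode` flag and endorses
neither.  Aggregation across fields is a plain sum, following the double
summation of the stated rule.

## Synthetic weather

Daily mean temperature is a sinusoid (default: mean 9.5 °C, amplitude
8.5 °C, peak at DOY 200) plus an AR(1) anomaly (sd 3 °C, lag-1
autocorrelation 0.7); tmin/tmax are fixed offsets (−4.5/+5.5 °C).
Precipitation occurrence is a two-state Markov chain (P(wet|dry) = 0.32,
P(wet|wet) = 0.55, so ≈152 wet days/yr) with gamma wet-day amounts (mean
5.15 mm, shape 0.85), giving ≈780 mm/yr — the midpoint of the 730–830 mm
target band.  Radiation is a clear-sky sinusoid (14 ± 11 MJ m⁻² d⁻¹)
attenuated by 55 % on wet days.  Years are fixed at 365 days.

What it does **not** emulate: spatial structure, temperature–radiation–
precipitation cross-correlations beyond wet-day attenuation, heat waves
and frost spells with realistic persistence, or any specific station
record.  The resemblance to the target region is statistical (annual
means), nothing more — so passing tests show the *method* behaves
correctly, not that its numbers transfer to any real site.

## Winter-wheat simulator

A daily radiation-use-efficiency model:

* **Phenology** — thermal time above a 0 °C base, mapped piecewise
  linearly onto BBCH through milestones (emergence 130 °C·d, tillering
  420, stem extension 700, flag leaf 900, anthesis 1350, maturity
  2050 °C·d).  Dormancy needs no extra state: cold days simply contribute
  no thermal time.
* **Growth** — dAGB = RUE · radiation · (1 − e^(−k·LAI)) · f_temp ·
  f_water · fert · sow, with RUE 15 kg ha⁻¹ per MJ m⁻² intercepted,
  k = 0.55, f_temp a linear ramp saturating at 17 °C.  LAI is tied to
  biomass (0.00105 LAI per kg/ha, cap 6.8) until anthesis and declines
  linearly to 25 % of its peak at maturity.  Each fertilization opens a
  28-day window with a ×1.22 growth bonus ("input levels kept constant"
  translates to identical bonuses every year).
* **Grain** — after anthesis, 50 % of new growth plus a 1 %/day
  remobilization of the vegetative surplus; yield = generative biomass at
  harvest / 100 (kg/ha → dt/ha), exactly.
* **Soil water** — four 30-cm buckets (field capacity 34 %, wilting point
  11 % by volume); rain infiltrates the top bucket, excess above field
  capacity cascades downward and finally drains out; evapotranspiration
  demand is radiation-driven (0.16 mm per MJ m⁻²), split between canopy
  transpiration and bare-soil evaporation by light interception; the
  stress factor is the rooted zone's relative available water scaled so
  growth is unstressed above 45 % availability.  The daily balance closes
  to 1e-9 mm by construction.
* **Soil temperature** — first-order relaxation toward daily air
  temperature with time constant 1 + depth/15 cm: shallow depths track
  the air, deep ones lag and damp, which is all the scoring needs.
* **Late sowing** — a multiplicative penalty of 0.0065 per day past DOY
  283 (floor 0.3).  Mechanistically the delay also shortens autumn
  development, but the explicit penalty is what makes the per-DOY success
  frequency fall realistically across the window.

**Calibration.** The defaults were fixed once, against the generator's
default climate, to meet three qualitative targets: grid yields spanning
roughly 49–99 dt/ha with a median near 73; a success frequency
P(yield ≥ 69.17) above 0.9 for the earliest sowing days, declining
through ~0.5 in the middle-late window to below 0.15 for the latest days;
and harvest generative biomass of 6,900–9,400 kg/ha.  These place the
synthetic seasons in the same magnitude range as the elicited yield
distribution the sgy threshold came from.  The calibration makes no claim
of agronomic fidelity — nitrogen dynamics, vernalization, photoperiod,
pests and cultivar differences are all absent — and the defaults should
be re-fitted before any real-site use.

## Risk statistics

Yield and ARS series are summarised by mean, standard deviation (n−1
denominator), skewness (population moment ratio m₃/m₂^{3/2}; reported as
NaN for constant series), coefficient of variation (SD/mean; NaN when the
mean is 0), and the relative frequency of seasons with yield ≥ sgy
(boundary inclusive, consistent with the pool filter).  The scenario
comparison flags scenarios whose rank by yield SD and rank by mean ARS
differ by a configurable gap — the diagnostic for seasons that deliver
acceptable yields while deviating wildly mid-season, which is precisely
the information variance-of-yield analysis misses.

## Survey module

Elicitations are (py, sgy, avy_farm) triples; records with py < sgy are
rejected (they would imply negative willingness to accept).  The
sensitivity classification uses two strict inequalities — sgy > avy_farm
and avy_farm > avy_region — giving four quadrants: high-sensitive
(both true), low-sensitive (farm above region, floor below average), and
two quadrants for farms at or below the regional average, labelled
`DEMANDING_UNDERPERFORMER` and `STANDARD` as package conventions.  Ties
fall to the less-sensitive side.  Records missing avy_farm contribute to
the descriptive rows where their fields exist, so per-variable n may
differ.

## Problem sizes and determinism

The default study conditions (46 × 30 grid, 20-year scenario) run in
about half a minute; the test suite exercises the same code on a 5 × 6
grid where full resolution adds nothing to the property under test.  All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical (parameters, seed) pairs reproduce
every artifact byte-for-byte, which the suite asserts end-to-end.

## Known limitations

* Acceptance ranges inherit every bias of the simulator that generated
  them; the method is only as good as the crop model behind it.
* The whisker convention makes ranges sensitive to the quantile method on
  small pools; pools record their convention for exactly this reason.
* Filtering by sgy *tends* to tighten ranges but is not guaranteed to do
  so per parameter (a subset's quartiles can widen a whisker); the suite
  checks the distributional claim, not a per-parameter one.
* One crop, one field, one management template; crop rotation, price
  dynamics and multi-field allocation are out of scope.
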