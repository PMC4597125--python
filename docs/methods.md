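# Methods

## The model

The package treats a species' *phenological niche* as a question of
seasonal placement: given a population's observed flowering window (a
cyclic run of consecutive calendar months), would any other window of
the same length have exposed it to fewer physiologically unsuitable
days? Suitability is univariate and threshold-based — four limits on
6-hourly surface weather (minimum temperature ≥ 5 °C, maximum
temperature ≤ 35 °C, relative humidity ≥ 50 %, no ≥ 15-day rainless
run), each taken from field ecophysiology of an atmospherically coupled
epiphyte. Limits are inclusive on the optimal side: an observation
exactly at 5 °C is optimal; strictly outside counts against.

Daily flags are derived from the four observations of one calendar day
(00/06/12/18 h):

* **Temperature/humidity**: the day is unsuitable when some *adjacent*
  pair of the four observations is strictly outside the limit. Pairs
  never span midnight; a cold 18 h observation followed by a cold 00 h
  observation the next day flags neither day. This is the literal
  one-day reading of the two-consecutive-observation rule and is the
  simplest choice that keeps day counts commensurable.
* **Relative humidity** is computed per 6-h step from dew point and
  mean air temperature via the Magnus-type fit
  e_s(T) = 6.112 exp(17.502 T/(240.97+T)); the rule is applied to all
  four daily steps, not a night-time subset, because the scored archive
  carries no explicit night mask at this cadence.
* **Rainless days**: a day is rainless when all four precipitation
  observations are ≤ a trace threshold (exactly 0 by default;
  configurable for drizzly reanalysis products). A day is unsuitable
  when it *ends* a run of `rainless_run_limit` rainless days.
  Attributing the flag to the terminal day of each qualifying run turns
  a per-period rule into a per-day rule, so all four variables yield
  one flag per day and their percentages are directly comparable. The
  first 14 days of a series can never be flagged.

**Percent time unsuitable** for a window is 100 × (flagged days in the
window's calendar months, pooled across all years) / (total days in
those months). Cross-year windows (Nov–Apr) pool by month membership
regardless of the year boundary; leap Februaries contribute 29 days.

**Windows and ranking.** Flowering windows come from specimen records
pooled on a 3° grid (climate stays at 1.5°; each scored 1.5° cell
inherits its parent's window, and only cells holding ≥ 1 record are
scored). Records are pooled across flowering and fruiting phenophases
(a filter exists). The window is the shortest cyclic arc of consecutive
months covering every recorded month — unimodal gap filling; ties
between equal arcs break to the earlier calendar start month. The mean
flowering month is a specimen-weighted *circular* mean (month m → angle
2π(m−½)/12), since southern-hemisphere windows wrap the year boundary;
an arithmetic mode is provided for strict comparability with analyses
that used a plain weighted average. Perfectly antipodal counts leave
the circular mean undefined and are reported as such rather than
coerced.

Each observed window is compared against all other cyclic windows of
its length (11 alternatives for lengths ≤ 11; a 12-month window has
none). Rank = 1 + number of candidates with strictly smaller percent
unsuitable, so ties share the better rank and rank 1 means "no season
would have been better". Per-variable rank distributions across cells
are compared pairwise with the two-sided two-sample Kolmogorov–Smirnov
test (asymptotic p-values; ranks are discrete, so ties are frequent and
flagged in the output — no tie correction is applied). The four ranks
collapse to the normalized Euclidean distance
sqrt(Σ(rᵢ−1)²)/sqrt(4·11²), taking the all-worst corner as the
normalizing constant. The per-variable "optimal share" summary counts
(cell, flowering-month) combinations whose within-month suitable-day
fraction is ≥ 0.70, with the denominator (cells × flowering months)
reported explicitly. The specimen-count effect on distance is a
Spearman correlation with a permutation p-value — exhaustive over all
n! pairings when n ≤ 7, otherwise 10 000 seeded Monte Carlo draws —
chosen for robustness at the small cell counts this analysis produces.

## The synthetic generator

The generator emulates the two inputs the method consumes, with a
planted ground truth for recovery testing.

*Climate*, per 1.5° cell and independent across cells (no spatial
correlation — a deliberate non-goal): sinusoidal annual cycles for
minimum/mean/maximum temperature (peak month settable per cell, which
is how seasons are planted), a sinusoidal diurnal cycle (minimum at
00 h), and AR(1) noise at the 6-h step shared by the three temperature
variables; ordering mn2t ≤ t2m ≤ mx2t is enforced by clamping. Dew
point is mean temperature minus a non-negative seasonal depression, so
RH ≤ 1 by construction. Precipitation is a per-day Bernoulli wet-day
draw with monthly probability and exponential wet-day amounts landed on
one random 6-h slot. The calendar is the real Gregorian calendar with
leap days. Defaults sketch a humid subtropical cell: annual mean 20 °C
(amplitude 8), minimum-temperature cycle 14 ± 9 °C (so winters dip
below the 5 °C limit), maximum 26 ± 8 °C, diurnal amplitude 3 °C, AR(1)
coefficient 0.7 with 1.5 °C innovations, dew-point depression 3 ± 1.5 °C
peaking in January, wet-day probability 0.35 year-round with 8 mm mean
amounts.

*Specimens*: per 3° cell, a Poisson number of records (default
intensity 4.5, matching the order of records-per-cell a continental
herbarium compilation yields), uniform locations within the cell,
months drawn inside the planted window with probability 0.9 (uniform
within/outside), half the records month-only dated, and a 70/30
flowering/fruiting mix. The truth is serialized alongside the table so
tests never re-derive it.

What the generator does **not** emulate: spatial correlation of
weather, non-sinusoidal seasonality (double wet seasons), observation
error in coordinates, collector bias toward roads or seasons. Passing
recovery tests therefore shows the pipeline's inference is correct
under its own assumptions, not that real reanalysis + herbarium data
satisfy those assumptions.

## Numerical choices and degenerate inputs

* Grid cells are half-open [edge, edge+size) on both axes; points on
  the extent's east/north boundary clamp into the last cell. Cells are
  indexed row-major from the northwest corner.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical config ⇒ byte-identical
  artifacts (the idempotence contract of the pipeline).
* Optimal-window ties break to the earliest calendar start month.
* A series shorter than the rainless run limit simply never flags.
* NetCDF I/O is NETCDF3_CLASSIC via xarray's scipy backend, with
  ERA-style kelvin/metre units converted to °C/mm on read. Missing
  variables or a broken 6-h cadence are hard errors — no gap filling.
* Grids are plain WGS84 lat/lon; outputs are CSV tables (no GeoTIFF).

## Problem sizes

The demonstration run under `analysis/` uses an 8 × 8-cell climate
grid over five years (7 300 six-hourly steps) and ~60 specimen
records; the recovery tests use a 4 × 4-cell grid over five years.
These sizes give stable rank statistics in seconds while exercising
every code path, including leap days and cross-year windows.

## Known limitations

* The two-consecutive rule's midnight boundary means a cold spell
  split exactly across midnight can go unflagged; at 6-h cadence this
  affects only pathological alternating series.
* Asymptotic KS p-values on heavily tied discrete ranks are
  conservative; the D statistics themselves are exact.
* The "optimal share" denominator depends on how flowering months are
  counted; the implementation exposes numerator and denominator so any
  convention can be audited.
* Per-cell independence in the generator understates the spatial
  coherence of real rank maps.
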