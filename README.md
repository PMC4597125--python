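# phenoclim

Does a plant flower when its climate is best for it? `phenoclim` answers
that question the way one would for a wide-ranging epiphyte such as
Spanish moss (*Tillandsia usneoides*): it scores gridded sub-daily
climate against the species' ecophysiological limits, derives each
population's flowering season from specimen records, and asks whether
any other season of the same length would have been more suitable.

The physiological envelope is four univariate thresholds on 6-hourly
weather at 2 m: minimum temperature ≥ 5 °C, maximum temperature ≤ 35 °C,
relative humidity ≥ 50 %, and no run of ≥ 15 consecutive rainless days.
Relative humidity comes from dew point T_d and air temperature T_a as

    RH = e_s(T_d) / e_s(T_a),    e_s(T) = 6.112 · exp(17.502 T / (240.97 + T))  [hPa]

A day is unsuitable for a temperature/humidity variable when two
*consecutive* of its four observations lie strictly outside the limit; a
day with all four precipitation observations at zero is rainless, and a
day ending a 15-day rainless run is unsuitable. For a cell with observed
flowering window *w* (a cyclic run of calendar months built from
specimen records, gaps filled under a unimodality assumption), the
percent of unsuitable days is computed for *w* and for the 11 other
windows of the same length; the observed window's **rank** is one plus
the number of alternatives with strictly less unsuitable time. The four
per-variable ranks r = (r₁…r₄) collapse to a normalized distance

    D = sqrt(Σ (rᵢ − 1)²) / sqrt(4 · (12 − 1)²)  ∈ [0, 1]

with D = 0 meaning the population flowers in the best available season
for every variable.

Because sub-daily reanalysis archives and herbarium databases cannot
ship with a package, `phenoclim` includes a synthetic generator that
emulates both (ERA-style NetCDF variables `mn2t, mx2t, t2m, d2m, tp` on
a 1.5° grid; Darwin-Core-compatible specimen CSV) with a *planted*
flowering season per cell, so the whole pipeline is testable for
parameter recovery.

## Worked example

The numbered drivers under `analysis/` run the study end to end on the
synthetic demonstration world (an 8 × 8 block of 1.5° cells, five years
of 6-hourly climate, ~60 specimen records over sixteen 3° phenology
cells):

```sh
python analysis/01_simulate_dataset.py
python analysis/02_flowering_profiles.py
python analysis/03_climate_suitability.py
python analysis/04_window_ranking.py
python analysis/05_report_figures.py
```

The ranking step prints, for this seed:

```
share of cells with observed window at rank 1:
max_temp        0.000
min_temp        0.611
rainless        0.639
rel_humidity    1.000

distance to optimum: median 0.500, 83% of cells at <= 0.5
sample-size effect: Spearman rho = 0.033, permutation p = 0.850 (n = 36 cells)
```

Flowering seasons were planted in the minimum-temperature cycle, so
observed windows rank first for `min_temp` in most cells even under
noisy, sparsely sampled records; they almost never rank first for
`max_temp` because the planted season coincides with the heat peak — the
kind of univariate trade-off the method is designed to expose. The
Spearman check confirms specimen count does not drive the distance.

The same pipeline is scriptable via the CLI (`phenoclim run -c
config.yaml`, with `simulate / profile / score / rank / report`
subcommands and threshold override flags).

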