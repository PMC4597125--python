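# Study conditions for the synthetic demonstration run.
#
# An 8 x 8 block of 1.5-degree climate cells (a 12 x 12 degree extent,
# sixteen 3-degree phenology cells), five years of 6-hourly climate,
# planted flowering seasons, and a specimen sampling regime of ~4.5
# records per phenology cell with 90 % of record months inside the true
# season and half of the records month-only dated.
seed: 42
grid:
  lon_min: -90.0
  lon_max: -78.0
  lat_min: 24.0
  lat_max: 36.0
  cell_size: 1.5
years:
  start: 2001
  n_years: 5
paths:
  outdir: results/demo
thresholds:
  tmin_limit_c: 5.0
  tmax_limit_c: 35.0
  rh_limit: 0.5
  rainless_run_limit: 15
  trace_mm: 0.0
options:
  mean_month_mode: circular
truth:
  window_length: 3
  intensity: 4.5
  concentration: 0.9
  imprecision: 0.5
  plant_in_climate: true
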