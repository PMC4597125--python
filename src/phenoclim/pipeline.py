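"""End-to-end orchestration: simulate -> profile -> score -> rank -> report.

Each stage reads its inputs from files and writes its outputs under the
configured output directory, so stages can be re-run independently from
the CLI. All randomness flows from the seeds in the config; identical
config + inputs reproduce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climate_io import ClimateSeries, read_netcdf, write_netcdf
from .grid import GridSpec, assign_cell, parent_3deg
from .phenology import build_profiles, profiles_to_frame, read_specimen_csv
from .ranking import (
    compare_rank_distributions,
    distance_to_optimum,
    optimal_share,
    optimal_window,
    rank_observed,
    sample_size_effect,
    score_candidates,
)
from .suitability import (
    VARIABLES,
    PhysiologyThresholds,
    compute_daily_flags,
    monthly_suitable_fraction,
)
from .synthetic import (
    ClimateGenParams,
    FloweringTruth,
    generate_climate,
    generate_specimens,
    params_for_truth,
    write_specimen_csv,
    write_truth_json,
)
from .windows import MonthWindow

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "run_simulate",
    "run_profile",
    "run_score",
    "run_rank",
    "run_report",
    "run_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (usually loaded from YAML)."""

    grid: GridSpec
    start_year: int = 2001
    n_years: int = 5
    outdir: Path = Path("phenoclim_out")
    climate_path: Path | None = None  # default: outdir / climate.nc
    specimen_path: Path | None = None  # default: outdir / specimens.csv
    truth_path: Path | None = None  # default: outdir / truth.json
    thresholds: PhysiologyThresholds = field(default_factory=PhysiologyThresholds)
    mean_month_mode: str = "circular"
    seed: int = 0
    window_length: int = 3
    specimen_intensity: float = 4.5
    month_concentration: float = 0.9
    date_imprecision: float = 0.5
    plant_truth_in_climate: bool = True
    climate_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        self.outdir = Path(self.outdir)
        self.climate_path = Path(self.climate_path or self.outdir / "climate.nc")
        self.specimen_path = Path(self.specimen_path or self.outdir / "specimens.csv")
        self.truth_path = Path(self.truth_path or self.outdir / "truth.json")

    @property
    def years(self) -> range:
        return range(self.start_year, self.start_year + self.n_years)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            grid = GridSpec(**raw["grid"])
        except KeyError as exc:
            raise ValueError("config lacks a 'grid' section") from exc
        years = raw.get("years", {})
        paths = raw.get("paths", {})
        opts = raw.get("options", {})
        truth = raw.get("truth", {})
        return cls(
            grid=grid,
            start_year=int(years.get("start", 2001)),
            n_years=int(years.get("n_years", 5)),
            outdir=Path(paths.get("outdir", "phenoclim_out")),
            climate_path=paths.get("climate"),
            specimen_path=paths.get("specimens"),
            truth_path=paths.get("truth"),
            thresholds=PhysiologyThresholds(**raw.get("thresholds", {})),
            mean_month_mode=opts.get("mean_month_mode", "circular"),
            seed=int(raw.get("seed", 0)),
            window_length=int(truth.get("window_length", 3)),
            specimen_intensity=float(truth.get("intensity", 4.5)),
            month_concentration=float(truth.get("concentration", 0.9)),
            date_imprecision=float(truth.get("imprecision", 0.5)),
            plant_truth_in_climate=bool(truth.get("plant_in_climate", True)),
            climate_params=dict(raw.get("climate", {})),
        )


@dataclass(frozen=True)
class ReportBundle:
    """Paths of the persisted pipeline artifacts."""

    profiles: Path
    suitability: Path
    ranks: Path
    rank_histograms: Path
    ks_matrix: Path
    optimal_months: Path
    distance_map: Path
    sample_size: Path
    optimal_share: Path
    manifest: Path


def _check_overwrite(paths, force: bool) -> None:
    existing = [str(p) for p in paths if Path(p).exists()]
    if existing and not force:
        raise FileExistsError(
            f"refusing to overwrite existing outputs (use --force): {existing}"
        )


_CYCLE_FIELDS = ("tmean", "tmin", "tmax", "dew_depression")


def _build_climate_params(cfg: PipelineConfig, truth: FloweringTruth):
    from .synthetic import SeasonalCycle

    raw = dict(cfg.climate_params)
    for name in _CYCLE_FIELDS:
        if isinstance(raw.get(name), dict):
            raw[name] = SeasonalCycle(**raw[name])
    if "wet_day_prob" in raw:
        raw["wet_day_prob"] = tuple(raw["wet_day_prob"])
    base = ClimateGenParams(seed=cfg.seed, **raw)
    if cfg.plant_truth_in_climate:
        return params_for_truth(cfg.grid, truth, base)
    return base


def run_simulate(cfg: PipelineConfig, force: bool = False) -> None:
    """Generate and persist climate NetCDF, specimen CSV and truth JSON."""
    _check_overwrite([cfg.climate_path, cfg.specimen_path, cfg.truth_path], force)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    truth = FloweringTruth.uniform(
        cfg.grid.coarsen(3.0),
        seed=cfg.seed,
        length=cfg.window_length,
        intensity=cfg.specimen_intensity,
        concentration=cfg.month_concentration,
        imprecision=cfg.date_imprecision,
    )
    params = _build_climate_params(cfg, truth)
    series = generate_climate(cfg.grid, cfg.start_year, cfg.n_years, params)
    specimens = generate_specimens(
        truth, cfg.grid, cfg.start_year, cfg.n_years, seed=cfg.seed + 1
    )
    write_netcdf(series, cfg.climate_path)
    write_specimen_csv(specimens, cfg.specimen_path)
    write_truth_json(truth, cfg.truth_path)
    log.info(
        "simulated %d cells x %d years, %d specimen records",
        cfg.grid.n_cells, cfg.n_years, len(specimens),
    )


def _load_profiles(cfg: PipelineConfig):
    specimens = read_specimen_csv(cfg.specimen_path)
    profiles = build_profiles(
        specimens, cfg.grid, mean_month_mode=cfg.mean_month_mode
    )
    return specimens, profiles


def _scored_cells(cfg: PipelineConfig, specimens, profiles) -> dict[int, MonthWindow]:
    """1.5 deg cells holding >= 1 record, each with its parent 3 deg window."""
    counts: dict[int, int] = {}
    for lon, lat in zip(specimens["longitude_dd"], specimens["latitude_dd"]):
        cid = assign_cell(lon, lat, cfg.grid)
        counts[cid] = counts.get(cid, 0) + 1
    return {
        cid: profiles[parent_3deg(cid, cfg.grid)].window
        for cid in sorted(counts)
    }, counts


def run_profile(cfg: PipelineConfig, force: bool = False) -> Path:
    """Write the per-3 deg-cell flowering profile table."""
    out = cfg.outdir / "profiles.csv"
    _check_overwrite([out], force)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    _, profiles = _load_profiles(cfg)
    profiles_to_frame(profiles).to_csv(out, index=False)
    return out


def _load_series_checked(cfg: PipelineConfig) -> ClimateSeries:
    series = read_netcdf(cfg.climate_path)
    span = set(series.years)
    if not set(cfg.years) <= span:
        raise ValueError(
            f"config years {cfg.start_year}..{cfg.start_year + cfg.n_years - 1} "
            f"outside climate span {min(span)}..{max(span)}"
        )
    return series


def run_score(cfg: PipelineConfig, force: bool = False) -> Path:
    """Per-cell, per-variable, per-candidate-window percent unsuitable."""
    out = cfg.outdir / "suitability.csv"
    _check_overwrite([out], force)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    specimens, profiles = _load_profiles(cfg)
    windows, _ = _scored_cells(cfg, specimens, profiles)
    series = _load_series_checked(cfg)
    daily = compute_daily_flags(series, cfg.thresholds)
    rows = []
    for cid, window in windows.items():
        row, col = cfg.grid.row_col(cid)
        lon_c, lat_c = cfg.grid.cell_center(cid)
        for variable in VARIABLES:
            cands, pcts = score_candidates(
                daily, row, col, variable, window, cfg.years
            )
            for i, (cand, pct) in enumerate(zip(cands, pcts)):
                rows.append(
                    {
                        "cell_id": cid,
                        "lon_center": lon_c,
                        "lat_center": lat_c,
                        "variable": variable,
                        "window_start_month": cand.start_month,
                        "window_length": cand.length,
                        "is_observed": i == 0,
                        "percent_unsuitable": pct,
                    }
                )
    pd.DataFrame(rows).to_csv(out, index=False, float_format="%.6f")
    return out


def run_rank(cfg: PipelineConfig, force: bool = False) -> list[Path]:
    """Ranks, KS matrix, optimal months, distances and the sample-size check."""
    outs = {
        name: cfg.outdir / f"{name}.csv"
        for name in (
            "ranks", "ks_matrix", "optimal_months", "distance_map", "optimal_share"
        )
    }
    sse_path = cfg.outdir / "sample_size_effect.json"
    _check_overwrite(list(outs.values()) + [sse_path], force)
    cfg.outdir.mkdir(parents=True, exist_ok=True)

    specimens, profiles = _load_profiles(cfg)
    windows, counts = _scored_cells(cfg, specimens, profiles)
    series = _load_series_checked(cfg)
    daily = compute_daily_flags(series, cfg.thresholds)

    rank_rows, opt_rows, dist_rows = [], [], []
    ranks_by_var: dict[str, list[int]] = {v: [] for v in VARIABLES}
    for cid, window in windows.items():
        row, col = cfg.grid.row_col(cid)
        lon_c, lat_c = cfg.grid.cell_center(cid)
        ranks = {}
        for variable in VARIABLES:
            cands, pcts = score_candidates(
                daily, row, col, variable, window, cfg.years
            )
            rank = rank_observed(pcts, 0)
            ranks[variable] = rank
            ranks_by_var[variable].append(rank)
            best = optimal_window(cands, pcts)
            rank_rows.append(
                {
                    "cell_id": cid,
                    "variable": variable,
                    "rank": rank,
                    "n_candidates": len(cands),
                    "observed_percent": pcts[0],
                }
            )
            opt_rows.append(
                {
                    "cell_id": cid,
                    "lon_center": lon_c,
                    "lat_center": lat_c,
                    "variable": variable,
                    "optimal_start_month": best.start_month,
                    "optimal_center_month": best.center_month,
                }
            )
        dist_rows.append(
            {
                "cell_id": cid,
                "lon_center": lon_c,
                "lat_center": lat_c,
                "distance": distance_to_optimum(
                    [ranks[v] for v in VARIABLES], max_rank=12
                ),
                "n_specimens": counts[cid],
            }
        )

    pd.DataFrame(rank_rows).to_csv(outs["ranks"], index=False, float_format="%.6f")
    pd.DataFrame(opt_rows).to_csv(outs["optimal_months"], index=False)
    dist_df = pd.DataFrame(dist_rows)
    dist_df.to_csv(outs["distance_map"], index=False, float_format="%.6f")

    ks = compare_rank_distributions({v: ranks_by_var[v] for v in VARIABLES})
    ks.table_layout().to_csv(outs["ks_matrix"], float_format="%.6f")

    monthly = {
        v: monthly_suitable_fraction(daily, v, cfg.years) for v in VARIABLES
    }
    share = optimal_share(monthly, windows, cfg.grid)
    pd.DataFrame(
        [
            {
                "variable": v,
                "n_optimal": share.n_optimal[v],
                "n_total": share.n_total,
                "fraction": share.fraction(v),
            }
            for v in VARIABLES
        ]
    ).to_csv(outs["optimal_share"], index=False, float_format="%.6f")

    sse = sample_size_effect(
        dist_df["distance"], dist_df["n_specimens"], seed=cfg.seed + 2
    )
    with open(sse_path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(sse), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return list(outs.values()) + [sse_path]


def run_report(cfg: PipelineConfig, config_path=None, force: bool = False) -> list[Path]:
    """Rank histograms and the run manifest."""
    hist_path = cfg.outdir / "rank_histograms.csv"
    manifest_path = cfg.outdir / "manifest.json"
    _check_overwrite([hist_path, manifest_path], force)
    ranks = pd.read_csv(cfg.outdir / "ranks.csv")
    hist = (
        ranks.groupby(["variable", "rank"]).size().rename("n_cells").reset_index()
    )
    hist.to_csv(hist_path, index=False)

    config_hash = None
    if config_path is not None:
        config_hash = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    manifest = {
        "phenoclim_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "config_sha256": config_hash,
        "grid": dataclasses.asdict(cfg.grid),
        "years": [cfg.start_year, cfg.start_year + cfg.n_years - 1],
        "thresholds": dataclasses.asdict(cfg.thresholds),
    }
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return [hist_path, manifest_path]


def run_pipeline(
    cfg: PipelineConfig, config_path=None, force: bool = False
) -> ReportBundle:
    """All stages in order; inputs are simulated when absent."""
    if not cfg.climate_path.exists() or not cfg.specimen_path.exists():
        run_simulate(cfg, force=force)
    run_profile(cfg, force=force)
    run_score(cfg, force=force)
    run_rank(cfg, force=force)
    run_report(cfg, config_path=config_path, force=force)
    return ReportBundle(
        profiles=cfg.outdir / "profiles.csv",
        suitability=cfg.outdir / "suitability.csv",
        ranks=cfg.outdir / "ranks.csv",
        rank_histograms=cfg.outdir / "rank_histograms.csv",
        ks_matrix=cfg.outdir / "ks_matrix.csv",
        optimal_months=cfg.outdir / "optimal_months.csv",
        distance_map=cfg.outdir / "distance_map.csv",
        sample_size=cfg.outdir / "sample_size_effect.json",
        optimal_share=cfg.outdir / "optimal_share.csv",
        manifest=cfg.outdir / "manifest.json",
    )
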