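"""Summary tables, run manifest and figures for the demonstration run.

Writes rank histograms and the manifest via the report stage, then
draws the per-variable rank histograms and the distance map / sample
size scatter to results/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from phenoclim.pipeline import PipelineConfig, run_report
from phenoclim.suitability import VARIABLES

HERE = Path(__file__).resolve().parent


def main() -> None:
    cfg = PipelineConfig.from_yaml(HERE / "config.yaml")
    run_report(cfg, config_path=HERE / "config.yaml", force=True)
    figdir = HERE.parent / "results" / "figures"
    figdir.mkdir(parents=True, exist_ok=True)

    hist = pd.read_csv(cfg.outdir / "rank_histograms.csv")
    fig, axes = plt.subplots(2, 2, figsize=(8, 6), sharex=True, sharey=True)
    for ax, variable in zip(axes.ravel(), VARIABLES):
        sub = hist[hist.variable == variable]
        ax.bar(sub["rank"], sub.n_cells, color="tab:blue")
        ax.set_title(variable)
        ax.set_xlim(0.5, 12.5)
    fig.supxlabel("rank of observed flowering window")
    fig.supylabel("number of cells")
    fig.tight_layout()
    fig.savefig(figdir / "rank_histograms.png", dpi=150)

    dist = pd.read_csv(cfg.outdir / "distance_map.csv")
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    sc = ax1.scatter(dist.lon_center, dist.lat_center, c=dist.distance,
                     cmap="viridis", vmin=0, vmax=1, s=120, marker="s")
    fig.colorbar(sc, ax=ax1, label="distance to optimum")
    ax1.set_xlabel("longitude")
    ax1.set_ylabel("latitude")
    ax2.scatter(dist.n_specimens, dist.distance, alpha=0.7)
    ax2.set_xlabel("specimens in cell")
    ax2.set_ylabel("distance to optimum")
    fig.tight_layout()
    fig.savefig(figdir / "distance_map.png", dpi=150)

    print(f"figures -> {figdir}")
    print(f"manifest -> {cfg.outdir / 'manifest.json'}")


if __name__ == "__main__":
    main()
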