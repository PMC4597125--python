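"""Simulate the synthetic study system: climate archive + specimen table.

Writes an ERA-style 6-hourly climate NetCDF, a herbarium-style
specimen CSV and the planted ground truth under results/demo/.
"""

from pathlib import Path

import pandas as pd

from phenoclim.pipeline import PipelineConfig, run_simulate

HERE = Path(__file__).resolve().parent
CONFIG = HERE / "config.yaml"


def main() -> None:
    cfg = PipelineConfig.from_yaml(CONFIG)
    run_simulate(cfg, force=True)
    specimens = pd.read_csv(cfg.specimen_path)
    print(f"climate: {cfg.grid.n_cells} cells x {cfg.n_years} years "
          f"-> {cfg.climate_path}")
    print(f"specimens: {len(specimens)} records "
          f"({(specimens.phenophase == 'flowering').sum()} flowering, "
          f"{(specimens.phenophase == 'fruiting').sum()} fruiting) "
          f"-> {cfg.specimen_path}")
    print(f"ground truth -> {cfg.truth_path}")


if __name__ == "__main__":
    main()
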