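"""Score every candidate window against the four physiological limits.

For each scored climate cell: percent of days outside the optimal
range, per variable, for the observed flowering window and its eleven
same-length alternatives.
"""

from pathlib import Path

import pandas as pd

from phenoclim.pipeline import PipelineConfig, run_score

HERE = Path(__file__).resolve().parent


def main() -> None:
    cfg = PipelineConfig.from_yaml(HERE / "config.yaml")
    out = run_score(cfg, force=True)
    suit = pd.read_csv(out)
    obs = suit[suit.is_observed]
    print(f"{suit.cell_id.nunique()} scored cells x 4 variables x "
          f"{suit.groupby(['cell_id', 'variable']).size().iloc[0]} "
          f"candidate windows -> {out}")
    print("mean percent unsuitable in the observed window:")
    print(obs.groupby("variable").percent_unsuitable.mean()
          .round(2).to_string())


if __name__ == "__main__":
    main()
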