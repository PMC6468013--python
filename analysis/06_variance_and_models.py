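#!/usr/bin/env python
"""Run the inference layer: variance contrasts and AICc model selection.

Produces the season/sex variance-comparison table (Levene + Fisher ratios)
for the five migration characteristics and the candidate-set mixed-model
selections for duration, distance roamed, speed and stopover use; prints
the sign pattern of the headline season and sex contrasts.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from herdtrack import pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    cfg = pipeline.load_config(None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts = pipeline.stage_report(cfg, OUT)
    print(f"report: {counts}")
    events = pd.read_csv(OUT / "events.csv")
    by = events.groupby("season")
    print("season contrast (spring vs autumn means):")
    for char in ("distance_roamed", "duration", "mean_speed", "stopover_used"):
        m = by[char].mean()
        arrow = ">" if m.get("spring", 0) > m.get("autumn", 0) else "<"
        print(f"  {char}: spring {arrow} autumn "
              f"({m.get('spring', float('nan')):.2f} vs {m.get('autumn', float('nan')):.2f})")
    bysex = events.groupby("sex")
    print("sex contrast (M vs F means):")
    for char in ("distance_roamed", "duration", "mean_speed", "n_stopovers"):
        m = bysex[char].mean()
        arrow = ">" if m.get("M", 0) > m.get("F", 0) else "<"
        print(f"  {char}: M {arrow} F "
              f"({m.get('M', float('nan')):.2f} vs {m.get('F', float('nan')):.2f})")
    models = json.loads((OUT / "model_selection.json").read_text())
    for resp, rep in models.items():
        print(
            f"selected model for {resp}: {rep['selected_terms'] or ['intercept only']} "
            f"(R2m {rep['r2_marginal']:.2f}, R2c {rep['r2_conditional']:.2f})"
        )


if __name__ == "__main__":
    main()
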