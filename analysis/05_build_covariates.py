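#!/usr/bin/env python
"""Build daily activity proportions and landscape/movement covariates.

Computes per-day activity proportions (n >= 5 rule), 95% kernel winter
ranges, distance of the winter barycenter to the coastline, the elevation
difference across each migration, and the region label.
"""

import warnings
from pathlib import Path

import pandas as pd

from herdtrack import pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    cfg = pipeline.load_config(None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts = pipeline.stage_covariates(cfg, OUT)
    print(f"covariates: {counts}")
    cov = pd.read_csv(OUT / "covariates.csv")
    if len(cov):
        print(
            f"coast distance: median {cov['dist_coast_km'].median():.1f} km; "
            f"elevation difference: median {cov['elev_diff_m'].median():.0f} m"
        )
    act = pd.read_csv(OUT / "daily_activity.csv")
    retained = act[act["retained"]]
    print(
        f"daily activity: {len(retained)} retained days, "
        f"mean proportion active {retained['prop_active'].mean():.2f}"
    )


if __name__ == "__main__":
    main()
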