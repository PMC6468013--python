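"""Ground-truth evaluation experiments for the analysis chain.

Each experiment simulates from the cohort generator, runs the corresponding
analysis stage, and scores the result against the generative truth:
seasonal-logistic parameter recovery, tactic-classification accuracy, and
stopover detection recall/precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from herdtrack import bbmm, nsd
from herdtrack import synthetic as syn
from herdtrack.synthetic import PopulationConfig, TrackTruth, _draw_truth

__all__ = [
    "recovery_experiment",
    "classification_experiment",
    "StopoverScore",
    "stopover_benchmark",
    "simulate_mixed_events",
]


def simulate_mixed_events(
    n: int = 400,
    beta_sex: float = 0.0,
    beta_x: float = 0.0,
    sd_animal: float = 0.4,
    sd_year: float = 0.2,
    sd_resid: float = 0.6,
    seed: int = 0,
    binary: bool = False,
) -> pd.DataFrame:
    """Event-level response with crossed animal/year random intercepts.

    Used to calibrate the model-selection layer: optional fixed effects of
    sex and a continuous covariate ``x`` on top of animal and year random
    intercepts, Gaussian by default or Bernoulli (logit link) with
    ``binary=True``.
    """
    rng = np.random.default_rng(seed)
    n_animals, years = 60, np.arange(2004, 2014)
    animal = rng.integers(0, n_animals, n)
    year = rng.choice(years, n)
    u = rng.normal(0, sd_animal, n_animals)
    v = rng.normal(0, sd_year, len(years))
    sex = rng.choice(["F", "M"], n)
    season = rng.choice(["spring", "autumn"], n)
    x = rng.normal(0, 1, n)
    eta = beta_sex * (sex == "M") + beta_x * x + u[animal] + v[year - years[0]]
    df = pd.DataFrame(
        {
            "animal_id": [f"a{i}" for i in animal],
            "year": year,
            "sex": sex,
            "season": season,
            "x": x,
        }
    )
    if binary:
        p = 1.0 / (1.0 + np.exp(-(eta - eta.mean())))
        df["y"] = (rng.random(n) < p).astype(int)
    else:
        df["y"] = eta + rng.normal(0, sd_resid, n)
    return df


def _year_track(truth: TrackTruth, seed: int) -> syn.Track:
    start = pd.Timestamp(year=truth.year, month=1, day=1, tz="UTC")
    end = pd.Timestamp(year=truth.year, month=12, day=31, hour=22, tz="UTC")
    return syn.simulate_track(truth, None, start, end, seed=seed)


def recovery_experiment(
    n: int = 200,
    noise_sd_km: float = 0.5,
    seed: int = 0,
    config: PopulationConfig | None = None,
) -> pd.DataFrame:
    """Recovery of (delta, theta, phi) for simulated spring movements.

    Simulates ``n`` migrant animal-years with within-range spread
    ``noise_sd_km``, fits the spring seasonal logistic on the displacement
    series restricted to the first half-year, and returns truth vs estimate
    per animal.
    """
    cfg = config or PopulationConfig(n=n, migrant_fraction=1.0, ou_sd_km=noise_sd_km)
    rows = []
    for i in range(n):
        sub = np.random.SeedSequence(seed, spawn_key=(i,))
        rng = np.random.default_rng(sub)
        truth = _draw_truth(cfg, i, rng)
        track = _year_track(truth, seed=int(rng.integers(2**31)))
        series = nsd.compute_displacement(track)
        split = 0.5 * (truth.spring_theta + truth.autumn_theta)
        fit = nsd.fit_seasonal_logistic(series.restrict(-np.inf, split), "spring")
        rows.append(
            {
                "animal_id": truth.animal_id,
                "delta_true": truth.range_distance,
                "theta_true": truth.spring_theta,
                "phi_true": truth.spring_phi,
                "delta_est": fit.delta,
                "theta_est": fit.theta,
                "phi_est": fit.phi,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def relative_bias(df: pd.DataFrame, name: str) -> float:
    """Mean relative bias of one recovered parameter, as a fraction."""
    rel = (df[f"{name}_est"] - df[f"{name}_true"]) / df[f"{name}_true"]
    return float(rel.mean())


def classification_experiment(
    n: int = 100, seed: int = 0, config: PopulationConfig | None = None
) -> pd.DataFrame:
    """Binary migrant/resident classification over a mixed cohort."""
    cfg = config or PopulationConfig(n=n)
    rows = []
    for i in range(n):
        sub = np.random.SeedSequence(seed, spawn_key=(i,))
        rng = np.random.default_rng(sub)
        truth = _draw_truth(cfg, i, rng)
        track = _year_track(truth, seed=int(rng.integers(2**31)))
        series = nsd.compute_displacement(track)
        fits = nsd.fit_movement_models(series)
        cls = nsd.classify_tactic(
            fits, t_span=(float(series.times.min()), float(series.times.max()))
        )
        rows.append(
            {
                "animal_id": truth.animal_id,
                "tactic_true": truth.tactic,
                "tactic_est": nsd.binary_tactic(cls.tactic),
                "model": cls.tactic,
                "review_flag": cls.review_flag,
            }
        )
    df = pd.DataFrame(rows)
    df["correct"] = df["tactic_true"] == df["tactic_est"]
    return df


@dataclass(frozen=True)
class StopoverScore:
    n_true: int
    n_detected: int
    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> float:
        return self.tp / max(self.tp + self.fn, 1)

    @property
    def precision(self) -> float:
        return self.tp / max(self.tp + self.fp, 1)


def stopover_benchmark(
    n_tracks: int = 50,
    seed: int = 42,
    match_radius_km: float = 1.5,
    cell_m: float = 150.0,
    config: PopulationConfig | None = None,
    range_tail_fraction: float = 0.13,
    range_buffer_km: float = 0.4,
) -> StopoverScore:
    """Stopover detection scored against generated dwells.

    Simulates ``n_tracks`` migrant animal-years, runs the BBMM UD and
    stopover identification on both seasonal migration windows (known from
    truth, so the score isolates the detector), and matches detected
    clusters to true dwell locations within ``match_radius_km``.
    """
    cfg = config or PopulationConfig(n=n_tracks, migrant_fraction=1.0)
    tp = fp = fn = n_true = n_det = 0
    for i in range(n_tracks):
        sub = np.random.SeedSequence(seed, spawn_key=(i,))
        rng = np.random.default_rng(sub)
        truth = _draw_truth(cfg, i, rng)
        track = _year_track(truth, seed=int(rng.integers(2**31)))
        t = track.julian_days()
        for season, theta, phi in (
            ("spring", truth.spring_theta, truth.spring_phi),
            ("autumn", truth.autumn_theta, truth.autumn_phi),
        ):
            true_locs = [s.location for s in truth.stopovers if s.season == season]
            n_true += len(true_locs)
            mask = (t >= theta - 2 * phi - 0.5) & (t <= theta + 2 * phi + 0.5)
            if mask.sum() < 6:
                fn += len(true_locs)
                continue
            seg = syn.replace_track_fixes(track, track.fixes.loc[mask])
            try:
                var = bbmm.estimate_bb_variance(seg)
                grid = bbmm.make_grid_for_segment(seg, var, cell_m=cell_m)
                ud = bbmm.compute_bbmm_ud(seg, var, grid)
            except ValueError:
                fn += len(true_locs)
                continue
            d = truth.range_distance
            r = range_tail_fraction * d + range_buffer_km
            excl = [
                (*truth.winter_center, r),
                (*truth.summer_center, r),
            ]
            stops = bbmm.identify_stopovers(ud, seg, exclude_ranges=excl)
            found = [c.centroid for c in stops.clusters]
            n_det += len(found)
            for loc in true_locs:
                cand = sorted(
                    (f for f in found
                     if np.hypot(f[0] - loc[0], f[1] - loc[1]) < match_radius_km),
                    key=lambda f: np.hypot(f[0] - loc[0], f[1] - loc[1]),
                )
                if cand:
                    tp += 1
                    found.remove(cand[0])
                else:
                    fn += 1
            fp += len(found)
    return StopoverScore(n_true=n_true, n_detected=n_det, tp=tp, fp=fp, fn=fn)
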