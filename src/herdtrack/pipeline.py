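"""One-command pipeline: simulate -> clean -> migrate -> stopovers ->
phenology -> covariates -> report.

Every stage communicates through documented delimited-text files in the run
directory, so stages can be rerun or replaced independently:

* ``fixes.csv`` — animal_id, sex, brand, timestamp (ISO-8601 UTC), x_km,
  y_km, activity_count
* ``truth.csv`` — per-animal generative ground truth
* ``landscape_elevation.csv`` / ``landscape_region.csv`` + ``landscape.json``
  (extent, cell sizes)
* ``ndvi.csv`` — long format: pixel_id, date (Julian day), ndvi
* ``clean.csv`` — cleaned fix table (same columns as fixes.csv)
* ``events.csv`` — one row per migration event
* ``stopovers.csv`` — animal_id, season, cluster id, x, y, entry, residence_h
* ``phenology_fits.csv`` / ``phenology_metrics.csv`` / ``synchrony.json``
* ``daily_activity.csv`` / ``covariates.csv``
* ``variance_report.csv`` / ``model_selection.json`` / ``timing_overlay.png``
* ``manifest.json`` — config hash, master seed, per-stage row counts
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from herdtrack import bbmm, covariates as cov, inference, nsd, phenology, preprocessing
from herdtrack import synthetic as syn

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

#: Every analysis threshold surfaced as a named key, defaulting to the value
#: the analysis is defined with (24-h capture trim, 2-h fixes, 3-km migrant
#: threshold, 25% UD quantile, n>=5 daily-activity rule, r=0.3 collinearity
#: screen, 2-AICc parsimony window).
DEFAULT_CONFIG: dict = {
    "simulate": {
        "n_animals": 40,
        "female_fraction": 0.65,
        "migrant_fraction": 0.551,
        "fix_interval_h": 2.0,
        "extent_km": 50.0,
        "cell_size_m": 100.0,
        "ndvi_cell_size_m": 250.0,
        "ndvi_noise_sd": 0.02,
        "n_ndvi_pixels": 400,
    },
    "clean": {
        "trim_hours": 24.0,
        "max_speed_kmh": 15.0,
        "spike_speed_kmh": 10.0,
        "spike_angle_deg": 170.0,
    },
    "migrate": {"min_delta_km": 3.0},
    "stopovers": {
        "quantile": 0.25,
        "min_residence_h": 12.0,
        "sigma_loc_km": 0.02,
        "cell_m": 150.0,
        "quad_per_interval": 10,
        "range_radius_quantile": 0.95,
    },
    "covariates": {
        "activity_min_values": 5,
        "kernel_level": 0.95,
    },
    "report": {"r_max": 0.3},
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config, validated against the default schema."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    _merge(cfg, user, prefix="")
    return cfg


def _merge(base: dict, user: dict, prefix: str) -> None:
    for key, val in user.items():
        if key not in base:
            raise KeyError(f"unknown config key: {prefix}{key}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise KeyError(f"config key {prefix}{key} must be a mapping")
            _merge(base[key], val, prefix=f"{prefix}{key}.")
        else:
            base[key] = val


def _require(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        raise FileNotFoundError(f"stage {stage!r}: missing input file {p}")
    return p


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: dict, out: Path, seed: int) -> dict:
    c = cfg["simulate"]
    ext = float(c["extent_km"])
    landscape = syn.simulate_landscape(
        seed=seed,
        extent=(0.0, ext, 0.0, ext),
        cell_size=float(c["cell_size_m"]),
        ndvi_cell_size=float(c["ndvi_cell_size_m"]),
    )
    pop_cfg = syn.PopulationConfig(
        n=int(c["n_animals"]),
        female_fraction=float(c["female_fraction"]),
        migrant_fraction=float(c["migrant_fraction"]),
    )
    tracks, activity, truth, _ = syn.simulate_population(
        pop_cfg, seed=seed, landscape=landscape
    )
    fixes = syn.tracks_to_table(tracks, activity)
    fixes.to_csv(out / "fixes.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)

    np.savetxt(out / "landscape_elevation.csv", landscape.elevation, delimiter=",", fmt="%.2f")
    np.savetxt(out / "landscape_region.csv", landscape.region, delimiter=",", fmt="%d")
    landscape.ndvi_params.to_csv(out / "landscape_ndvi_params.csv", index=False)
    with open(out / "landscape.json", "w") as fh:
        json.dump(
            {
                "extent_km": list(landscape.extent),
                "cell_size_m": landscape.cell_size,
                "ndvi_cell_size_m": landscape.ndvi_cell_size,
            },
            fh,
            indent=2,
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10_001,)))
    n_pix = min(int(c["n_ndvi_pixels"]), len(landscape.ndvi_params))
    pick = rng.choice(len(landscape.ndvi_params), size=n_pix, replace=False)
    sub = syn.LandscapeGrid(
        extent=landscape.extent,
        cell_size=landscape.cell_size,
        elevation=landscape.elevation,
        region=landscape.region,
        ndvi_cell_size=landscape.ndvi_cell_size,
        ndvi_params=landscape.ndvi_params.iloc[np.sort(pick)].reset_index(drop=True),
    )
    series = syn.simulate_ndvi_series(
        sub, seed=int(rng.integers(2**31)), noise_sd=float(c["ndvi_noise_sd"])
    )
    long = pd.concat(
        [
            pd.DataFrame({"pixel_id": s.pixel_id, "date": s.dates, "ndvi": s.values})
            for s in series
        ],
        ignore_index=True,
    )
    long.to_csv(out / "ndvi.csv", index=False)
    return {"fixes.csv": len(fixes), "truth.csv": len(truth), "ndvi.csv": len(long)}


def stage_clean(cfg: dict, out: Path) -> dict:
    c = cfg["clean"]
    fixes = pd.read_csv(_require(out, "fixes.csv", "clean"), parse_dates=["timestamp"])
    tracks = syn.table_to_tracks(fixes)
    cleaned = []
    removed_total = 0
    for tr in tracks:
        tr2 = preprocessing.trim_capture_window(tr, hours=float(c["trim_hours"]))
        if len(tr2) == 0:
            continue
        tr3, removed = preprocessing.screen_outliers(
            tr2,
            max_speed_kmh=float(c["max_speed_kmh"]),
            spike_angle_deg=float(c["spike_angle_deg"]),
            spike_speed_kmh=float(c["spike_speed_kmh"]),
        )
        removed_total += removed
        cleaned.append(tr3)
    # carry activity counts through the fix filter
    keep = pd.concat([t.fixes.assign(animal_id=t.animal_id) for t in cleaned])
    merged = fixes.merge(
        keep[["animal_id", "timestamp"]], on=["animal_id", "timestamp"], how="inner"
    )
    merged.to_csv(out / "clean.csv", index=False)
    return {"clean.csv": len(merged), "removed_fixes": removed_total}


def stage_migrate(cfg: dict, out: Path) -> dict:
    c = cfg["migrate"]
    fixes = pd.read_csv(_require(out, "clean.csv", "migrate"), parse_dates=["timestamp"])
    tracks = syn.table_to_tracks(fixes)
    truth = pd.read_csv(out / "truth.csv") if (out / "truth.csv").exists() else None
    years = (
        dict(zip(truth["animal_id"], truth["year"])) if truth is not None else {}
    )
    events, classifications, diag = [], {}, {}
    for tr in tracks:
        res = nsd.analyze_track(tr, min_delta_km=float(c["min_delta_km"]))
        cls = res["classification"]
        classifications[tr.animal_id] = cls
        diag[tr.animal_id] = {
            "tactic": cls.tactic,
            "review_flag": cls.review_flag,
            "notes": cls.notes,
            "aicc": {f.model: f.aicc for f in cls.fits},
        }
        for season in ("spring", "autumn"):
            fit = res[f"{season}_fit"]
            if fit is None or not fit.converged:
                continue
            try:
                ev = nsd.extract_migration_event(
                    fit, tr, year=years.get(tr.animal_id)
                )
            except ValueError:
                continue
            events.append(ev)
    table = nsd.events_to_table(events)
    table.to_csv(out / "events.csv", index=False)
    with open(out / "fit_diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=2, default=float)
    tactics = pd.DataFrame(
        [
            {"animal_id": a, "tactic": d["tactic"], "review_flag": d["review_flag"]}
            for a, d in diag.items()
        ]
    )
    tactics.to_csv(out / "tactics.csv", index=False)
    return {"events.csv": len(table), "tactics.csv": len(tactics)}


def _range_circles(
    track, event, quantile: float, pad_days: float = 15.0
) -> list[tuple[float, float, float]]:
    """Seasonal-range exclusion circles from fixes adjacent to the movement.

    Only fixes within ``pad_days`` of the window are used — later in the year
    the animal migrates again, and those fixes belong to the other range.
    The radius also covers the slow tail of the logistic (the ~12% of the
    displacement outside the +/- 2 phi window is range-side by convention).
    """
    t = track.julian_days()
    xy = track.xy()
    tail = 0.13 * float(getattr(event, "range_distance", 0.0) or 0.0) + 0.4
    circles = []
    for mask in (
        (t < event.departure) & (t >= event.departure - pad_days),
        (t > event.arrival) & (t <= event.arrival + pad_days),
    ):
        pts = xy[mask]
        if len(pts) < 5:
            continue
        center = pts.mean(axis=0)
        r = float(np.quantile(np.hypot(*(pts - center).T), quantile))
        circles.append((float(center[0]), float(center[1]), max(r, tail)))
    return circles


def stage_stopovers(cfg: dict, out: Path) -> dict:
    c = cfg["stopovers"]
    fixes = pd.read_csv(_require(out, "clean.csv", "stopovers"), parse_dates=["timestamp"])
    events = pd.read_csv(_require(out, "events.csv", "stopovers"))
    tracks = {t.animal_id: t for t in syn.table_to_tracks(fixes)}
    rows = []
    counts = {}
    for idx, ev in events.iterrows():
        tr = tracks.get(ev["animal_id"])
        if tr is None:
            continue
        t = tr.julian_days()
        pad = 0.5  # day of context either side of the window
        mask = (t >= ev["departure"] - pad) & (t <= ev["arrival"] + pad)
        if mask.sum() < 5:
            counts[idx] = 0
            continue
        seg = syn.replace_track_fixes(tr, tr.fixes.loc[mask])
        try:
            var = bbmm.estimate_bb_variance(seg, sigma_loc=float(c["sigma_loc_km"]))
            grid = bbmm.make_grid_for_segment(seg, var, cell_m=float(c["cell_m"]))
            ud = bbmm.compute_bbmm_ud(
                seg, var, grid, quad_per_interval=int(c["quad_per_interval"])
            )
        except ValueError:
            counts[idx] = 0
            continue
        ev_obj = nsd.MigrationEvent(
            animal_id=ev["animal_id"], year=int(ev["year"]), season=ev["season"],
            sex=ev["sex"], departure=ev["departure"], arrival=ev["arrival"],
            duration=ev["duration"], distance_roamed=ev["distance_roamed"],
            mean_speed=ev["mean_speed"], n_stopovers=0,
            range_distance=float(ev.get("range_distance", 0.0)),
        )
        circles = _range_circles(tr, ev_obj, float(c["range_radius_quantile"]))
        stops = bbmm.identify_stopovers(
            ud,
            seg,
            quantile=float(c["quantile"]),
            min_residence_h=float(c["min_residence_h"]),
            exclude_ranges=circles,
        )
        counts[idx] = stops.n_stopovers
        for k, cl in enumerate(stops.clusters):
            rows.append(
                {
                    "animal_id": ev["animal_id"],
                    "season": ev["season"],
                    "cluster_id": k,
                    "x_km": cl.centroid[0],
                    "y_km": cl.centroid[1],
                    "entry_day": cl.entry_day,
                    "residence_h": cl.residence_h,
                }
            )
    events["n_stopovers"] = [counts.get(i, 0) for i in events.index]
    events["stopover_used"] = events["n_stopovers"] > 0
    events.to_csv(out / "events.csv", index=False)
    pd.DataFrame(
        rows,
        columns=[
            "animal_id", "season", "cluster_id", "x_km", "y_km", "entry_day",
            "residence_h",
        ],
    ).to_csv(out / "stopovers.csv", index=False)
    return {"stopovers.csv": len(rows)}


def stage_phenology(cfg: dict, out: Path) -> dict:
    ndvi = pd.read_csv(_require(out, "ndvi.csv", "phenology"))
    fits, metrics = [], []
    for pid, grp in ndvi.groupby("pixel_id"):
        series = syn.NDVISeries(
            pixel_id=int(pid),
            dates=grp["date"].to_numpy(float),
            values=grp["ndvi"].to_numpy(float),
        )
        try:
            fit = phenology.fit_double_logistic(series)
        except RuntimeError:
            continue
        if not fit.converged:
            continue
        fits.append(fit)
        metrics.append(phenology.phenology_metrics(fit))
    pd.DataFrame([vars(f) for f in fits]).to_csv(out / "phenology_fits.csv", index=False)
    mtab = phenology.metrics_table(metrics)
    mtab.to_csv(out / "phenology_metrics.csv", index=False)
    report = phenology.synchrony_summary(mtab)
    with open(out / "synchrony.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    if (out / "events.csv").exists():
        events = pd.read_csv(out / "events.csv")
        phenology.migration_phenology_overlay(
            mtab, events, out_path=str(out / "timing_overlay.png")
        )
    return {"phenology_metrics.csv": len(mtab)}


def stage_covariates(cfg: dict, out: Path) -> dict:
    c = cfg["covariates"]
    fixes = pd.read_csv(_require(out, "clean.csv", "covariates"), parse_dates=["timestamp"])
    events = pd.read_csv(_require(out, "events.csv", "covariates"))
    with open(_require(out, "landscape.json", "covariates")) as fh:
        meta = json.load(fh)
    landscape = syn.LandscapeGrid(
        extent=tuple(meta["extent_km"]),
        cell_size=meta["cell_size_m"],
        elevation=np.loadtxt(out / "landscape_elevation.csv", delimiter=","),
        region=np.loadtxt(out / "landscape_region.csv", delimiter=",", dtype=int),
        ndvi_cell_size=meta["ndvi_cell_size_m"],
        ndvi_params=pd.read_csv(out / "landscape_ndvi_params.csv"),
    )
    tracks = {t.animal_id: t for t in syn.table_to_tracks(fixes)}

    # daily activity
    act_rows = []
    if "activity_count" in fixes.columns:
        for aid, grp in fixes.groupby("animal_id"):
            series = syn.ActivitySeries(
                animal_id=str(aid),
                timestamps=grp["timestamp"].reset_index(drop=True),
                counts=grp["activity_count"].to_numpy(int),
            )
            for da in cov.daily_activity_proportion(
                series, min_values=int(c["activity_min_values"])
            ):
                act_rows.append(vars(da))
    pd.DataFrame(act_rows).to_csv(out / "daily_activity.csv", index=False)

    rows = []
    for _, ev in events.iterrows():
        tr = tracks.get(ev["animal_id"])
        if tr is None:
            continue
        t = tr.julian_days()
        winter_mask = t < ev["departure"] if ev["season"] == "spring" else t > ev["arrival"]
        pts = tr.xy()[winter_mask]
        if len(pts) < 30:
            continue
        try:
            hr = cov.kernel_home_range(
                pts, animal_id=ev["animal_id"], season="winter",
                level=float(c["kernel_level"]),
            )
            ev_obj = nsd.MigrationEvent(
                animal_id=ev["animal_id"], year=int(ev["year"]), season=ev["season"],
                sex=ev["sex"], departure=ev["departure"], arrival=ev["arrival"],
                duration=ev["duration"], distance_roamed=ev["distance_roamed"],
                mean_speed=ev["mean_speed"], n_stopovers=int(ev["n_stopovers"]),
                range_distance=float(ev.get("range_distance", np.nan)),
            )
            rec = cov.build_covariates(tr, hr, landscape, ev_obj)
        except ValueError:
            continue
        rows.append(vars(rec))
    pd.DataFrame(rows).to_csv(out / "covariates.csv", index=False)
    return {"covariates.csv": len(rows), "daily_activity.csv": len(act_rows)}


def stage_report(cfg: dict, out: Path) -> dict:
    c = cfg["report"]
    events = pd.read_csv(_require(out, "events.csv", "report"))
    var_report = inference.variance_comparison_report(events)
    var_report.to_csv(out / "variance_report.csv", index=False)

    # per-characteristic model selection; merged with covariates when available
    merged = events.copy()
    cov_path = out / "covariates.csv"
    if cov_path.exists():
        cdf = pd.read_csv(cov_path)
        if len(cdf):
            merged = merged.merge(
                cdf, on=["animal_id", "year", "season"], how="left"
            )
    merged = merged.dropna(subset=["duration", "distance_roamed", "mean_speed"])
    tf = {"duration": "log", "distance_roamed": "log", "mean_speed": "log"}
    for extra in ("range_distance", "dist_coast_km", "elev_diff_m"):
        if extra in merged.columns and merged[extra].notna().all() and merged[extra].std() > 0:
            tf[extra] = "zscore"
    merged = inference.transform_variables(merged, tf)

    reports = {}
    main_terms = ["sex", "season"]
    if "range_distance" in tf:
        main_terms.append("range_distance")
    for resp in ("duration", "distance_roamed", "mean_speed"):
        if merged["sex"].nunique() < 2 or merged["season"].nunique() < 2:
            continue
        try:
            rep = inference.fit_characteristic_models(
                merged, resp, main_terms, interactions=[("sex", "season")],
                r_max=float(c["r_max"]),
            )
        except RuntimeError:
            continue
        reports[resp] = {
            "selected_terms": list(rep["selection"].selected.terms),
            "aicc": rep["selection"].selected.aicc,
            "coefficients": rep["coefficients"]["estimate"].to_dict(),
            "r2_marginal": rep["r2"].r2_marginal,
            "r2_conditional": rep["r2"].r2_conditional,
            "n_failed": rep["n_failed"],
        }
    if "stopover_used" in merged.columns and merged["stopover_used"].nunique() > 1:
        merged["stopover_used"] = merged["stopover_used"].astype(int)
        try:
            rep = inference.fit_characteristic_models(
                merged, "stopover_used", main_terms,
                interactions=[("sex", "season")],
                engine=inference.BinomialGLMEngine(), r_max=float(c["r_max"]),
            )
            reports["stopover_used"] = {
                "selected_terms": list(rep["selection"].selected.terms),
                "aicc": rep["selection"].selected.aicc,
                "coefficients": rep["coefficients"]["estimate"].to_dict(),
                "r2_marginal": rep["r2"].r2_marginal,
                "r2_conditional": rep["r2"].r2_conditional,
                "n_failed": rep["n_failed"],
            }
        except RuntimeError:
            pass
    with open(out / "model_selection.json", "w") as fh:
        json.dump(reports, fh, indent=2, default=float)
    return {"variance_report.csv": len(var_report), "models": len(reports)}


STAGES = [
    ("simulate", stage_simulate),
    ("clean", stage_clean),
    ("migrate", stage_migrate),
    ("stopovers", stage_stopovers),
    ("phenology", stage_phenology),
    ("covariates", stage_covariates),
    ("report", stage_report),
]


def run_pipeline(
    config: str | Path | dict | None,
    out_dir: str | Path,
    seed: int = 1,
) -> Path:
    """Run the full pipeline into ``out_dir``; returns the run directory.

    ``config`` is a YAML path, an already-validated dict, or None for the
    defaults.  A ``manifest.json`` with the config hash, master seed and
    per-stage row counts is written last.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": int(seed),
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "config": cfg,
        "stages": {},
    }
    for name, fn in STAGES:
        counts = fn(cfg, out, seed) if name == "simulate" else fn(cfg, out)
        manifest["stages"][name] = counts
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return out
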