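"""Synthetic landscapes, GPS tracks, activity counts and NDVI series.

Every downstream stage of the pipeline is exercised against cohorts produced
here, for which the migratory ground truth (tactic, seasonal-range centers,
logistic timing parameters, stopovers, behavioural states) is known exactly.

Conventions
-----------
* Coordinates are planar, in projected kilometres; the synthetic coastline is
  the ``x = 0`` meridian and elevation rises inland.
* Time is UTC; model time is fractional Julian day (day-of-year, day 1 =
  January 1st).
* Migratory displacement between the winter and summer range follows the
  logistic form ``delta / (1 + exp((theta - t) / phi))`` per season, the same
  curve the analysis layer fits, so generative truth and analysis model agree
  by construction.
* Within-range wander is a discrete mean-reverting (Ornstein-Uhlenbeck) walk
  with stationary standard deviation ``ou_sd`` per coordinate.
* Randomness: one master seed; per-animal generators are derived with
  ``numpy.random.SeedSequence(master, spawn_key=(index,))`` so cohorts are
  reproducible and order-independent.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LandscapeGrid",
    "Stopover",
    "TrackTruth",
    "Track",
    "ActivitySeries",
    "NDVISeries",
    "PopulationConfig",
    "simulate_landscape",
    "simulate_track",
    "behavioral_states",
    "simulate_activity_counts",
    "simulate_ndvi_series",
    "simulate_population",
]

HOURS_PER_DAY = 24.0

# Curvature-extremum constant of the logistic: onset-to-peak duration of a
# seasonal transition with rate m is LN_2_SQRT3 / m.
LN_2_SQRT3 = math.log(2.0 + math.sqrt(3.0))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandscapeGrid:
    """A rectangular synthetic landscape.

    ``elevation`` and ``region`` are sampled on ``cell_size`` (m) cells;
    the per-pixel NDVI double-logistic parameter fields are sampled on
    coarser ``ndvi_cell_size`` (m) pixels.  The coastline is the x = 0 line.
    """

    extent: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax (km)
    cell_size: float  # metres
    elevation: np.ndarray  # (ny, nx) metres
    region: np.ndarray  # (ny, nx) int labels, 4 levels
    ndvi_cell_size: float  # metres
    ndvi_params: pd.DataFrame  # per NDVI pixel: base, amplitude, S, mS, A, mA

    def __post_init__(self) -> None:
        if self.cell_size <= 0 or self.ndvi_cell_size <= 0:
            raise ValueError("cell sizes must be positive")
        if not np.all(np.isfinite(self.elevation)):
            raise ValueError("elevation must be finite")
        if len(np.unique(self.region)) != 4:
            raise ValueError("region layer must have exactly 4 labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    def elevation_at(self, x: float, y: float) -> float:
        """Elevation (m) of the cell containing projected point (x, y) km."""
        xmin, xmax, ymin, ymax = self.extent
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise ValueError(f"point ({x}, {y}) outside landscape extent")
        step = self.cell_size / 1000.0
        ny, nx = self.elevation.shape
        j = min(int((x - xmin) / step), nx - 1)
        i = min(int((y - ymin) / step), ny - 1)
        return float(self.elevation[i, j])

    def region_at(self, x: float, y: float) -> int:
        xmin, xmax, ymin, ymax = self.extent
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise ValueError(f"point ({x}, {y}) outside landscape extent")
        step = self.cell_size / 1000.0
        ny, nx = self.region.shape
        j = min(int((x - xmin) / step), nx - 1)
        i = min(int((y - ymin) / step), ny - 1)
        return int(self.region[i, j])


@dataclass(frozen=True)
class Stopover:
    """A generated en-route dwell: where, when, and for how long."""

    location: tuple[float, float]  # km
    arrival_day: float  # fractional Julian day
    residence_h: float  # hours
    season: str  # 'spring' | 'autumn'


@dataclass(frozen=True)
class TrackTruth:
    """Generative ground truth for one animal-year."""

    animal_id: str
    sex: str  # 'F' | 'M'
    tactic: str  # 'migrant' | 'resident'
    winter_center: tuple[float, float]
    summer_center: tuple[float, float]
    spring_theta: float  # Julian day of spring mid-migration
    autumn_theta: float
    spring_phi: float  # days; >= 0 (0 is the instantaneous-switch limit)
    autumn_phi: float
    stopovers: tuple[Stopover, ...] = ()
    ou_sd: float = 0.5  # km
    activity_baseline: dict = field(
        default_factory=lambda: {"stationary": 0.35, "traveling": 0.85}
    )
    year: int = 2010

    def __post_init__(self) -> None:
        if self.spring_phi < 0 or self.autumn_phi < 0:
            raise ValueError("phi must be non-negative")
        if self.spring_theta >= self.autumn_theta:
            raise ValueError("spring mid-date must precede autumn mid-date")
        dist = self.range_distance
        if self.tactic == "migrant" and dist <= 0:
            raise ValueError("migrant truth requires distinct seasonal centers")
        if self.tactic == "resident" and dist != 0:
            raise ValueError("resident truth requires identical centers")
        for s in self.stopovers:
            theta = self.spring_theta if s.season == "spring" else self.autumn_theta
            phi = self.spring_phi if s.season == "spring" else self.autumn_phi
            lo, hi = theta - 2.0 * phi, theta + 2.0 * phi
            if not (lo <= s.arrival_day and s.arrival_day + s.residence_h / 24.0 <= hi):
                raise ValueError(
                    f"stopover at day {s.arrival_day} outside the "
                    f"{s.season} migration window [{lo:.1f}, {hi:.1f}]"
                )

    @property
    def range_distance(self) -> float:
        """delta: Euclidean distance between seasonal range centers (km)."""
        wx, wy = self.winter_center
        sx, sy = self.summer_center
        return math.hypot(sx - wx, sy - wy)


@dataclass(frozen=True)
class Track:
    """One animal's GPS trajectory."""

    animal_id: str
    sex: str
    brand: str
    fixes: pd.DataFrame  # columns: timestamp (UTC), x_km, y_km
    fix_interval_h: float = 2.0

    def __post_init__(self) -> None:
        ts = self.fixes["timestamp"]
        if len(ts) and not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if len(ts) > 1 and ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.fixes[["x_km", "y_km"]].to_numpy())):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.fixes)

    def julian_days(self) -> np.ndarray:
        """Fractional day-of-year of each fix (day 1 = Jan 1)."""
        ts = pd.to_datetime(self.fixes["timestamp"])
        year0 = ts.iloc[0].year
        ref = pd.Timestamp(year=year0, month=1, day=1, tz=ts.iloc[0].tz)
        return ((ts - ref) / pd.Timedelta(days=1)).to_numpy() + 1.0

    def xy(self) -> np.ndarray:
        return self.fixes[["x_km", "y_km"]].to_numpy()


@dataclass(frozen=True)
class ActivitySeries:
    """Per-fix neck-movement activity counts for one animal."""

    animal_id: str
    timestamps: pd.Series
    counts: np.ndarray  # non-negative ints, one per retained fix
    active_threshold: int = 20

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("activity counts must be non-negative")
        if len(self.counts) != len(self.timestamps):
            raise ValueError("one count per fix required")


@dataclass(frozen=True)
class NDVISeries:
    """One pixel's annual NDVI series on a 16-day composite grid."""

    pixel_id: int
    dates: np.ndarray  # Julian days, strictly increasing, 16-day spacing
    values: np.ndarray  # in [-1, 1]

    def __post_init__(self) -> None:
        d = np.diff(self.dates)
        if len(d) and not np.all(d == 16):
            raise ValueError("composite dates must advance in 16-day steps")
        if np.any(np.abs(self.values) > 1.0):
            raise ValueError("NDVI values must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


def simulate_landscape(
    seed: int,
    extent: tuple[float, float, float, float] = (0.0, 50.0, 0.0, 50.0),
    cell_size: float = 100.0,
    ndvi_cell_size: float = 250.0,
    spring_peak_sd: float = 23.64,
    autumn_peak_sd: float = 9.63,
    greenup_duration_mean: float = 11.45,
    drydown_duration_mean: float = 6.57,
) -> LandscapeGrid:
    """Generate a synthetic coastal landscape with NDVI parameter fields.

    Elevation rises smoothly with distance from the coast (x = 0) plus
    spatially correlated noise; four contiguous region blocks stand in for
    administrative counties.  Each NDVI pixel carries the parameters of an
    annual double-logistic greenness curve; the spring inflection (green-up
    peak) field is substantially more variable than the autumn one, matching
    the broad-scale asymmetry between green-up and dry-down synchrony.

    Defaults for the phenology fields (peak-date SDs 23.64 / 9.63 days,
    onset-to-peak durations 11.45 / 6.57 days) are the study-scale values
    the analysis layer is meant to recover.
    """
    if cell_size <= 0 or ndvi_cell_size <= 0:
        raise ValueError("cell sizes must be positive")
    xmin, xmax, ymin, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("extent must be non-degenerate")

    rng = np.random.default_rng(seed)
    step = cell_size / 1000.0
    nx = int(round((xmax - xmin) / step))
    ny = int(round((ymax - ymin) / step))
    xs = xmin + (np.arange(nx) + 0.5) * step

    # ramp from sea level inland + correlated bumps
    ramp = 12.0 * (xs - xmin)  # 12 m per km from the coast
    noise = rng.normal(0.0, 1.0, size=(ny, nx))
    noise = ndimage.gaussian_filter(noise, sigma=8.0, mode="nearest")
    sd = noise.std()
    noise = noise / sd * 60.0 if sd > 0 else noise
    elevation = np.maximum(ramp[None, :] + noise, 0.0)

    region = np.zeros((ny, nx), dtype=int)
    region[ny // 2 :, : nx // 2] = 1
    region[: ny // 2, nx // 2 :] = 2
    region[ny // 2 :, nx // 2 :] = 3

    nstep = ndvi_cell_size / 1000.0
    nnx = int(round((xmax - xmin) / nstep))
    nny = int(round((ymax - ymin) / nstep))
    npix = nnx * nny

    def _smooth_field(mean: float, sd_target: float, sigma: float = 4.0) -> np.ndarray:
        f = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, size=(nny, nnx)), sigma=sigma, mode="nearest"
        )
        s = f.std()
        if s > 0 and sd_target > 0:
            f = f / s * sd_target
        return (mean + f).ravel()

    spring_peak = _smooth_field(140.0, spring_peak_sd)
    autumn_peak = _smooth_field(280.0, autumn_peak_sd)
    # keep S < A everywhere even in the tails
    autumn_peak = np.maximum(autumn_peak, spring_peak + 30.0)
    greenup_dur = np.clip(_smooth_field(greenup_duration_mean, 3.0), 2.0, None)
    drydown_dur = np.clip(_smooth_field(drydown_duration_mean, 2.0), 2.0, None)

    ndvi_params = pd.DataFrame(
        {
            "pixel_id": np.arange(npix),
            "base": np.clip(_smooth_field(0.2, 0.03), 0.0, 0.4),
            "amplitude": np.clip(_smooth_field(0.5, 0.05), 0.2, 0.75),
            "S": spring_peak,
            "mS": LN_2_SQRT3 / greenup_dur,
            "A": autumn_peak,
            "mA": LN_2_SQRT3 / drydown_dur,
        }
    )
    return LandscapeGrid(
        extent=extent,
        cell_size=cell_size,
        elevation=elevation,
        region=region,
        ndvi_cell_size=ndvi_cell_size,
        ndvi_params=ndvi_params,
    )


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------


def _logistic_progress(t: np.ndarray, theta: float, phi: float) -> np.ndarray:
    """Fraction of the seasonal transition completed at day t (0..1)."""
    if phi == 0.0:
        return (t >= theta).astype(float)
    z = np.clip((theta - t) / phi, -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(z))


def _center_path(truth: TrackTruth, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expected activity-center position (n, 2) and dwell mask at day t."""
    w = np.asarray(truth.winter_center, dtype=float)
    s = np.asarray(truth.summer_center, dtype=float)
    if truth.tactic == "resident":
        return np.broadcast_to(w, (len(t), 2)).copy(), np.zeros(len(t), dtype=bool)
    prog = _logistic_progress(t, truth.spring_theta, truth.spring_phi)
    prog = prog - _logistic_progress(t, truth.autumn_theta, truth.autumn_phi)
    centers = w[None, :] + prog[:, None] * (s - w)[None, :]
    dwelling = np.zeros(len(t), dtype=bool)
    for stop in truth.stopovers:
        t0 = stop.arrival_day
        t1 = t0 + stop.residence_h / HOURS_PER_DAY
        inside = (t >= t0) & (t < t1)
        centers[inside] = np.asarray(stop.location, dtype=float)
        dwelling |= inside
    return centers, dwelling


def simulate_track(
    truth: TrackTruth,
    landscape: LandscapeGrid | None,
    start: pd.Timestamp,
    end: pd.Timestamp,
    seed: int,
    fix_interval_h: float = 2.0,
    ou_tau_days: float = 0.15,
    dwell_sd_km: float = 0.10,
    brand: str = "brandA",
) -> Track:
    """Simulate one animal-year of 2-hourly GPS fixes.

    The fix position is an Ornstein-Uhlenbeck excursion around a moving
    activity center: the winter range center, the logistic migration path,
    an en-route stopover, or the summer range center, depending on the date.
    While dwelling at a stopover the animal is locally stationary, so the
    excursion scale tightens to ``dwell_sd_km`` (never above ``ou_sd``).
    Passing ``landscape`` is optional and only used to bound coordinates.
    """
    if start >= end:
        raise ValueError("start must precede end")
    rng = np.random.default_rng(seed)
    times = pd.date_range(start, end, freq=pd.Timedelta(hours=fix_interval_h), tz="UTC")
    ref = pd.Timestamp(year=times[0].year, month=1, day=1, tz="UTC")
    t_days = ((times - ref) / pd.Timedelta(days=1)).to_numpy() + 1.0

    centers, dwelling = _center_path(truth, t_days)
    dt = fix_interval_h / HOURS_PER_DAY
    # dwells relax fast (hours) so the animal settles onto the stopover;
    # ranging relaxes on ou_tau_days
    a = np.where(dwelling, math.exp(-dt / 0.08), math.exp(-dt / ou_tau_days))
    sd = np.where(dwelling, min(dwell_sd_km, truth.ou_sd), truth.ou_sd)
    innov_sd = sd * np.sqrt(np.maximum(1.0 - a * a, 0.0))

    xy = np.empty((len(times), 2))
    xy[0] = centers[0] + rng.normal(0.0, sd[0], size=2)
    eps = rng.normal(0.0, 1.0, size=(len(times) - 1, 2))
    for k in range(1, len(times)):
        pull = centers[k] + a[k] * (xy[k - 1] - centers[k - 1])
        xy[k] = pull + innov_sd[k] * eps[k - 1]

    if landscape is not None:
        xmin, xmax, ymin, ymax = landscape.extent
        xy[:, 0] = np.clip(xy[:, 0], xmin, xmax)
        xy[:, 1] = np.clip(xy[:, 1], ymin, ymax)

    fixes = pd.DataFrame({"timestamp": times, "x_km": xy[:, 0], "y_km": xy[:, 1]})
    return Track(
        animal_id=truth.animal_id,
        sex=truth.sex,
        brand=brand,
        fixes=fixes,
        fix_interval_h=fix_interval_h,
    )


def behavioral_states(track: Track, truth: TrackTruth) -> np.ndarray:
    """Label each fix 'traveling' or 'stationary' from the generative truth.

    Traveling = inside a migration window [theta - 2 phi, theta + 2 phi] and
    not dwelling at a stopover; everything else (ranges, dwells) is
    stationary.
    """
    t = track.julian_days()
    state = np.full(len(t), "stationary", dtype=object)
    if truth.tactic == "migrant":
        for theta, phi in (
            (truth.spring_theta, truth.spring_phi),
            (truth.autumn_theta, truth.autumn_phi),
        ):
            inside = (t >= theta - 2.0 * phi) & (t <= theta + 2.0 * phi)
            state[inside] = "traveling"
        for stop in truth.stopovers:
            t0 = stop.arrival_day
            t1 = t0 + stop.residence_h / HOURS_PER_DAY
            state[(t >= t0) & (t < t1)] = "stationary"
    return state


# ---------------------------------------------------------------------------
# Activity counts
# ---------------------------------------------------------------------------


def simulate_activity_counts(
    track: Track,
    truth: TrackTruth,
    seed: int,
    active_threshold: int = 20,
    lam_active: float = 60.0,
    lam_inactive: float = 5.0,
) -> ActivitySeries:
    """Draw per-fix dual-axis activity-count analogs.

    Each fix is active with the state-dependent probability in
    ``truth.activity_baseline``; active counts are ``threshold + 1 +
    Poisson(lam_active)`` and inactive counts are ``min(Poisson(lam_inactive),
    threshold)``, so the active/inactive split is exact by construction while
    the counts remain realistically overdispersed around two modes.
    """
    if len(track) == 0:
        raise ValueError("track must be nonempty")
    rng = np.random.default_rng(seed)
    states = behavioral_states(track, truth)
    p = np.where(
        states == "traveling",
        truth.activity_baseline["traveling"],
        truth.activity_baseline["stationary"],
    )
    active = rng.random(len(p)) < p
    counts = np.where(
        active,
        active_threshold + 1 + rng.poisson(lam_active, size=len(p)),
        np.minimum(rng.poisson(lam_inactive, size=len(p)), active_threshold),
    )
    return ActivitySeries(
        animal_id=track.animal_id,
        timestamps=track.fixes["timestamp"],
        counts=counts.astype(int),
        active_threshold=active_threshold,
    )


# ---------------------------------------------------------------------------
# NDVI series
# ---------------------------------------------------------------------------


def double_logistic(
    t: np.ndarray,
    base: float,
    amplitude: float,
    S: float,
    mS: float,
    A: float,
    mA: float,
) -> np.ndarray:
    """Annual double-logistic greenness curve (same form the fitter uses)."""
    t = np.asarray(t, dtype=float)
    up = 1.0 / (1.0 + np.exp(np.clip(-mS * (t - S), -500, 500)))
    down = 1.0 / (1.0 + np.exp(np.clip(mA * (t - A), -500, 500)))
    return base + amplitude * (up + down - 1.0)


def simulate_ndvi_series(
    landscape: LandscapeGrid,
    seed: int,
    noise_sd: float = 0.02,
    first_doy: int = 9,
) -> list[NDVISeries]:
    """16-day-composite annual NDVI series for every landscape pixel."""
    rng = np.random.default_rng(seed)
    dates = np.arange(first_doy, 366, 16, dtype=float)
    out = []
    for row in landscape.ndvi_params.itertuples(index=False):
        clean = double_logistic(dates, row.base, row.amplitude, row.S, row.mS, row.A, row.mA)
        vals = np.clip(clean + rng.normal(0.0, noise_sd, size=len(dates)), -1.0, 1.0)
        out.append(NDVISeries(pixel_id=int(row.pixel_id), dates=dates, values=vals))
    return out


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationConfig:
    """Cohort-level generator settings.

    Defaults emulate the study conditions: roughly two-thirds females, a
    55.1% migrant fraction, spring departures synchronised around late April
    (mid-date ~ Julian day 124) and autumn departures more spread around
    mid-September, migration scale parameters giving spring duration means
    of ~8 d (F) / ~15 d (M) and shorter autumn migrations, and more frequent
    stopover use by males and in spring.
    """

    n: int = 40
    female_fraction: float = 0.65
    migrant_fraction: float = 0.551
    year_range: tuple[int, int] = (2004, 2015)
    range_distance_mean_km: float = 15.0
    range_distance_sd_km: float = 6.0
    min_range_distance_km: float = 5.0
    ou_sd_km: float = 0.5
    spring_theta_mean: dict = field(default_factory=lambda: {"F": 124.0, "M": 123.0})
    spring_theta_sd: dict = field(default_factory=lambda: {"F": 15.0, "M": 18.0})
    autumn_theta_mean: dict = field(default_factory=lambda: {"F": 260.0, "M": 262.0})
    autumn_theta_sd: dict = field(default_factory=lambda: {"F": 30.0, "M": 24.0})
    spring_phi_mean: dict = field(default_factory=lambda: {"F": 2.0, "M": 3.8})
    autumn_phi_mean: dict = field(default_factory=lambda: {"F": 1.5, "M": 2.3})
    phi_cv: float = 0.45
    stopover_rate: dict = field(
        default_factory=lambda: {
            ("F", "spring"): 0.41,
            ("M", "spring"): 0.77,
            ("F", "autumn"): 0.18,
            ("M", "autumn"): 0.35,
        }
    )
    stopover_residence_mean_h: float = 30.0
    stopover_residence_min_h: float = 14.0
    activity_baseline: dict = field(
        default_factory=lambda: {"stationary": 0.35, "traveling": 0.85}
    )
    brands: tuple[str, ...] = ("televilt", "vectronic")

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("population size must be positive")
        if not 0.0 <= self.migrant_fraction <= 1.0:
            raise ValueError("migrant fraction must be in [0, 1]")


def _draw_truth(cfg: PopulationConfig, idx: int, rng: np.random.Generator) -> TrackTruth:
    sex = "F" if rng.random() < cfg.female_fraction else "M"
    migrant = rng.random() < cfg.migrant_fraction
    winter = (rng.uniform(5.0, 20.0), rng.uniform(5.0, 45.0))

    theta_s = rng.normal(cfg.spring_theta_mean[sex], cfg.spring_theta_sd[sex])
    theta_a = rng.normal(cfg.autumn_theta_mean[sex], cfg.autumn_theta_sd[sex])
    theta_s = float(np.clip(theta_s, 60.0, 185.0))
    theta_a = float(np.clip(theta_a, max(theta_s + 60.0, 210.0), 345.0))

    def _phi(mean: float) -> float:
        sdlog = math.sqrt(math.log(1.0 + cfg.phi_cv**2))
        mulog = math.log(mean) - 0.5 * sdlog**2
        return float(np.clip(rng.lognormal(mulog, sdlog), 0.4, 12.0))

    phi_s, phi_a = _phi(cfg.spring_phi_mean[sex]), _phi(cfg.autumn_phi_mean[sex])
    # keep windows inside the year and apart
    phi_s = min(phi_s, (theta_a - theta_s) / 5.0)
    phi_a = min(phi_a, (theta_a - theta_s) / 5.0, (360.0 - theta_a) / 2.1)

    if migrant:
        dist = float(
            np.clip(
                rng.normal(cfg.range_distance_mean_km, cfg.range_distance_sd_km),
                cfg.min_range_distance_km,
                None,
            )
        )
        bearing = rng.uniform(0.0, 2.0 * math.pi)
        summer = (
            winter[0] + dist * math.cos(bearing),
            winter[1] + dist * math.sin(bearing),
        )
        tactic = "migrant"
    else:
        summer = winter
        tactic = "resident"
        dist = 0.0

    stopovers: list[Stopover] = []
    if migrant:
        for season, theta, phi in (
            ("spring", theta_s, phi_s),
            ("autumn", theta_a, phi_a),
        ):
            n_stop = rng.poisson(cfg.stopover_rate[(sex, season)])
            window = 4.0 * phi
            taken: list[tuple[float, float]] = []  # disjoint dwell windows
            for _ in range(n_stop):
                res_h = cfg.stopover_residence_min_h + rng.exponential(
                    cfg.stopover_residence_mean_h - cfg.stopover_residence_min_h
                )
                res_d = res_h / HOURS_PER_DAY
                if window <= res_d + 0.5:
                    continue  # dwell does not fit inside this movement
                arrival = None
                for _attempt in range(20):
                    cand = theta - 2.0 * phi + 0.25 + rng.uniform(
                        0.0, window - res_d - 0.5
                    )
                    if all(
                        cand + res_d + 0.25 < lo or cand > hi + 0.25
                        for lo, hi in taken
                    ):
                        arrival = cand
                        break
                if arrival is None:
                    continue  # no room left for a disjoint dwell
                taken.append((arrival, arrival + res_d))
                frac = rng.uniform(0.25, 0.75)
                w, s = np.asarray(winter), np.asarray(summer)
                loc = w + frac * (s - w)
                # offset perpendicular to the route so dwells sit off-corridor
                perp = np.array([-(s - w)[1], (s - w)[0]])
                nrm = np.linalg.norm(perp)
                if nrm > 0:
                    loc = loc + perp / nrm * rng.uniform(-1.0, 1.0)
                stopovers.append(
                    Stopover(
                        location=(float(loc[0]), float(loc[1])),
                        arrival_day=float(arrival),
                        residence_h=float(res_h),
                        season=season,
                    )
                )

    year = int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1))
    return TrackTruth(
        animal_id=f"deer{idx:03d}",
        sex=sex,
        tactic=tactic,
        winter_center=winter,
        summer_center=summer,
        spring_theta=theta_s,
        autumn_theta=theta_a,
        spring_phi=phi_s,
        autumn_phi=phi_a,
        stopovers=tuple(stopovers),
        ou_sd=cfg.ou_sd_km,
        activity_baseline=dict(cfg.activity_baseline),
        year=year,
    )


def truth_table(truths: Sequence[TrackTruth]) -> pd.DataFrame:
    """Flatten truths into the per-animal ground-truth table."""
    rows = []
    for tr in truths:
        rows.append(
            {
                "animal_id": tr.animal_id,
                "sex": tr.sex,
                "tactic": tr.tactic,
                "year": tr.year,
                "winter_x": tr.winter_center[0],
                "winter_y": tr.winter_center[1],
                "summer_x": tr.summer_center[0],
                "summer_y": tr.summer_center[1],
                "range_distance_km": tr.range_distance,
                "spring_theta": tr.spring_theta,
                "spring_phi": tr.spring_phi,
                "autumn_theta": tr.autumn_theta,
                "autumn_phi": tr.autumn_phi,
                "n_stopovers_spring": sum(s.season == "spring" for s in tr.stopovers),
                "n_stopovers_autumn": sum(s.season == "autumn" for s in tr.stopovers),
                "ou_sd": tr.ou_sd,
            }
        )
    return pd.DataFrame(rows)


def simulate_population(
    config: PopulationConfig,
    seed: int,
    landscape: LandscapeGrid | None = None,
    with_activity: bool = True,
) -> tuple[list[Track], list[ActivitySeries], pd.DataFrame, list[TrackTruth]]:
    """Simulate a cohort of animal-years.

    Returns tracks, per-fix activity series, the flattened truth table and
    the full truth objects.  Per-animal randomness comes from
    ``SeedSequence(seed, spawn_key=(i,))`` so any animal can be regenerated
    in isolation.
    """
    tracks: list[Track] = []
    activity: list[ActivitySeries] = []
    truths: list[TrackTruth] = []
    for i in range(config.n):
        sub = np.random.SeedSequence(seed, spawn_key=(i,))
        rng = np.random.default_rng(sub)
        truth = _draw_truth(config, i, rng)
        truths.append(truth)
        track_seed, act_seed = sub.spawn(2)
        start = pd.Timestamp(year=truth.year, month=1, day=1, tz="UTC")
        end = pd.Timestamp(year=truth.year, month=12, day=31, hour=22, tz="UTC")
        brand = config.brands[i % len(config.brands)]
        track = simulate_track(
            truth,
            landscape,
            start,
            end,
            seed=np.random.default_rng(track_seed).integers(2**31),
            brand=brand,
        )
        tracks.append(track)
        if with_activity:
            activity.append(
                simulate_activity_counts(
                    track, truth, seed=np.random.default_rng(act_seed).integers(2**31)
                )
            )
    return tracks, activity, truth_table(truths), truths


def tracks_to_table(
    tracks: Sequence[Track], activity: Sequence[ActivitySeries] | None = None
) -> pd.DataFrame:
    """Flatten tracks (and optional activity counts) to one fix table."""
    frames = []
    act_by_id = {a.animal_id: a for a in activity} if activity else {}
    for tr in tracks:
        df = tr.fixes.copy()
        df.insert(0, "animal_id", tr.animal_id)
        df.insert(1, "sex", tr.sex)
        df.insert(2, "brand", tr.brand)
        if tr.animal_id in act_by_id:
            df["activity_count"] = act_by_id[tr.animal_id].counts
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def table_to_tracks(table: pd.DataFrame, fix_interval_h: float = 2.0) -> list[Track]:
    """Rebuild Track objects from a flat fix table."""
    out = []
    for animal_id, grp in table.groupby("animal_id", sort=True):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        out.append(
            Track(
                animal_id=str(animal_id),
                sex=str(grp["sex"].iloc[0]) if "sex" in grp else "F",
                brand=str(grp["brand"].iloc[0]) if "brand" in grp else "unknown",
                fixes=grp[["timestamp", "x_km", "y_km"]].assign(
                    timestamp=pd.to_datetime(grp["timestamp"], utc=True)
                ),
                fix_interval_h=fix_interval_h,
            )
        )
    return out


def replace_track_fixes(track: Track, fixes: pd.DataFrame) -> Track:
    """Return a copy of ``track`` with a new fix table."""
    return dataclasses.replace(track, fixes=fixes.reset_index(drop=True))
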