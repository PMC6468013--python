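"""Net-squared-displacement tactic classification and migration characteristics.

The annual shape of an animal's displacement from its winter origin separates
space-use tactics: flat for residents, a single sigmoid for dispersers, a
double sigmoid (out and back) for migrants.  Five candidate movement models
are fitted to the net-displacement series by nonlinear least squares and
ranked by AICc; each seasonal migratory movement is then refitted with its
own three-parameter logistic

    nd(t) = delta / (1 + exp((theta - t) / phi))

whose parameters carry the biology: ``delta`` the distance between seasonal
ranges (km), ``theta`` the mid-date of migration (inflection point, Julian
day), and ``phi`` the temporal scale (days).  The migration window used for
every derived characteristic is [theta - 2 phi, theta + 2 phi]: departure =
theta - 2 phi, arrival = theta + 2 phi, duration = 4 phi, and the distance
roamed / mean travel speed are accumulated over the fixes inside that window.
(The logistic reaches 75% of its asymptote at theta + phi ln 3; the 2-phi
convention is retained for all outputs because the derived characteristics
are defined in its terms.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from herdtrack.inference import aicc
from herdtrack.synthetic import Track

__all__ = [
    "DisplacementSeries",
    "MovementModelFit",
    "SeasonalLogisticFit",
    "MigrationEvent",
    "TacticClassification",
    "compute_displacement",
    "fit_movement_models",
    "classify_tactic",
    "season_split_day",
    "seasonal_series",
    "fit_seasonal_logistic",
    "extract_migration_event",
    "analyze_track",
]

MODEL_NPARAMS = {
    "resident": 1,
    "nomad": 1,
    "disperser": 3,
    "migrant": 5,
    "mixed_migrant": 6,
}


@dataclass(frozen=True)
class DisplacementSeries:
    """Net displacement of each fix from a trajectory origin."""

    animal_id: str
    origin: tuple[float, float]
    times: np.ndarray  # fractional Julian day
    nd: np.ndarray  # km
    nsd: np.ndarray  # km^2

    def __post_init__(self) -> None:
        if np.any(self.nd < 0):
            raise ValueError("net displacement must be non-negative")
        if not np.allclose(self.nsd, self.nd**2):
            raise ValueError("nsd must equal nd squared")

    def __len__(self) -> int:
        return len(self.times)

    def restrict(self, tmin: float, tmax: float) -> "DisplacementSeries":
        m = (self.times >= tmin) & (self.times <= tmax)
        return DisplacementSeries(
            self.animal_id, self.origin, self.times[m], self.nd[m], self.nsd[m]
        )


@dataclass(frozen=True)
class MovementModelFit:
    """One candidate movement model fitted to a displacement series."""

    model: str
    params: dict
    rss: float
    n_obs: int
    aicc: float
    converged: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.model == "resident":
            return np.full_like(t, p["c"])
        if self.model == "nomad":
            return p["beta"] * np.sqrt(np.maximum(t - t.min(), 0.0))
        if self.model == "disperser":
            return _logistic(t, p["delta"], p["theta"], p["phi"])
        if self.model == "migrant":
            return _double_logistic(
                t, p["delta"], p["theta_s"], p["phi_s"], p["theta_a"], p["phi_a"]
            )
        if self.model == "mixed_migrant":
            return _double_logistic(
                t, p["delta"], p["theta_s"], p["phi_s"], p["theta_a"], p["phi_a"],
                p["delta2"],
            )
        raise ValueError(f"unknown model {self.model!r}")

    def fitted_amplitude(self, t_span: tuple[float, float]) -> float:
        """Range of the fitted displacement curve over the data window.

        For a well-behaved migrant this equals the asymptote; for the
        degenerate near-cancelling double sigmoids the optimizer can reach,
        it measures the displacement the curve actually realizes.
        """
        grid = np.linspace(t_span[0], t_span[1], 400)
        y = self.predict(grid)
        return float(y.max() - y.min())


@dataclass(frozen=True)
class SeasonalLogisticFit:
    """Three-parameter logistic fit of one seasonal migratory movement."""

    season: str  # 'spring' | 'autumn'
    delta: float  # asymptote: distance between seasonal ranges, km
    theta: float  # mid-date of migration, Julian day
    phi: float  # temporal scale, days
    rss: float
    n_obs: int
    converged: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        return _logistic(np.asarray(t, dtype=float), self.delta, self.theta, self.phi)


@dataclass(frozen=True)
class MigrationEvent:
    """The five characteristics of one seasonal migratory movement."""

    animal_id: str
    year: int
    season: str
    sex: str
    departure: float  # Julian day, theta - 2 phi
    arrival: float  # theta + 2 phi
    duration: float  # days, == 4 phi
    distance_roamed: float  # km, sum of step lengths in the window
    mean_speed: float  # km/h, mean of per-step speeds
    n_stopovers: int
    range_distance: float = np.nan  # fitted delta, km

    @property
    def stopover_used(self) -> bool:
        return self.n_stopovers > 0


@dataclass(frozen=True)
class TacticClassification:
    tactic: str
    review_flag: bool
    best_fit: MovementModelFit
    fits: tuple[MovementModelFit, ...] = field(repr=False, default=())
    notes: str = ""


# ---------------------------------------------------------------------------
# Displacement
# ---------------------------------------------------------------------------


def compute_displacement(
    track: Track, origin: tuple[float, float] | None = None
) -> DisplacementSeries:
    """Net (and net-squared) displacement of every fix from ``origin``.

    The origin defaults to the first retained fix (the winter position for a
    track that starts in winter).
    """
    if len(track) == 0:
        raise ValueError("track must be nonempty")
    xy = track.xy()
    if origin is None:
        origin = (float(xy[0, 0]), float(xy[0, 1]))
    nd = np.hypot(xy[:, 0] - origin[0], xy[:, 1] - origin[1])
    return DisplacementSeries(
        animal_id=track.animal_id,
        origin=origin,
        times=track.julian_days(),
        nd=nd,
        nsd=nd**2,
    )


# ---------------------------------------------------------------------------
# Candidate movement models
# ---------------------------------------------------------------------------


def _logistic(t: np.ndarray, delta: float, theta: float, phi: float) -> np.ndarray:
    z = np.clip((theta - t) / max(phi, 1e-9), -500.0, 500.0)
    return delta / (1.0 + np.exp(z))


def _double_logistic(t, delta, theta_s, phi_s, theta_a, phi_a, delta2=None):
    if delta2 is None:
        delta2 = delta
    return _logistic(t, delta, theta_s, phi_s) - _logistic(t, delta2, theta_a, phi_a)


def _gaussian_aicc(rss: float, n: int, k_model: int) -> float:
    """AICc of a least-squares fit; k counts model parameters plus sigma."""
    sigma2 = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return aicc(loglik, k_model + 1, n)


def _steepest_changes(times: np.ndarray, nd: np.ndarray) -> tuple[float, float]:
    """Initial (theta_spring, theta_autumn) from the displacement derivative."""
    if len(times) < 3:
        return float(times[len(times) // 2]), float(times[-1])
    # smooth nd on a coarse daily grid before differencing
    order = np.argsort(times)
    t, y = times[order], nd[order]
    grid = np.arange(t[0], t[-1], 1.0)
    if len(grid) < 5:
        grid = np.linspace(t[0], t[-1], 5)
    yg = np.interp(grid, t, y)
    kernel = np.ones(5) / 5.0
    ys = np.convolve(yg, kernel, mode="same")
    dy = np.gradient(ys, grid)
    up = float(grid[np.argmax(dy)])
    down = float(grid[np.argmin(dy)])
    return up, down


def fit_movement_models(
    series: DisplacementSeries,
    phi_starts: tuple[float, ...] = (1.0, 5.0, 15.0),
) -> list[MovementModelFit]:
    """Fit the five candidate movement models to a full-year nd(t) series.

    Requires at least 50 observations spanning at least 200 days.  Candidates
    that fail to converge are returned flagged (``converged=False``) with
    infinite AICc rather than dropped.
    """
    t, y = series.times, series.nd
    n = len(t)
    if n < 50 or (t.max() - t.min()) < 200.0:
        raise ValueError("need >= 50 observations spanning >= 200 days")

    fits: list[MovementModelFit] = []

    # resident: nd = c, closed form
    c = float(np.mean(y))
    rss = float(np.sum((y - c) ** 2))
    fits.append(
        MovementModelFit("resident", {"c": c}, rss, n, _gaussian_aicc(rss, n, 1), True)
    )

    # nomad: nd = beta * sqrt(t - t0), closed form LS
    s = np.sqrt(np.maximum(t - t.min(), 0.0))
    denom = float(np.sum(s * s))
    beta = float(np.sum(y * s) / denom) if denom > 0 else 0.0
    rss = float(np.sum((y - beta * s) ** 2))
    fits.append(
        MovementModelFit(
            "nomad", {"beta": beta}, rss, n, _gaussian_aicc(rss, n, 1), True
        )
    )

    theta_up, theta_down = _steepest_changes(t, y)
    delta0 = float(np.quantile(y, 0.75))
    delta0 = max(delta0, 1e-3)
    span = (float(t.min()), float(t.max()))
    # mid-dates must lie near the observed window and the temporal scale must
    # stay on a migration timescale, else the sigmoids degenerate into slow
    # ramps soaking up within-range autocorrelation
    t_lo, t_hi = span[0] - 10.0, span[1] + 10.0
    phi_hi = 45.0

    def _ls_fit(model, fun, x0_list, lb, ub, names):
        best = None
        for x0 in x0_list:
            x0 = np.clip(x0, np.asarray(lb) + 1e-9, np.asarray(ub) - 1e-9)
            try:
                res = least_squares(fun, x0, bounds=(lb, ub), max_nfev=2000)
            except Exception:
                continue
            rss = float(2.0 * res.cost)
            if best is None or rss < best[0]:
                best = (rss, res.x, bool(res.success))
        if best is None:
            return MovementModelFit(model, {}, np.inf, n, np.inf, False)
        rss, x, ok = best
        params = dict(zip(names, (float(v) for v in x)))
        return MovementModelFit(
            model, params, rss, n, _gaussian_aicc(rss, n, len(names)), ok
        )

    # disperser: single logistic
    fits.append(
        _ls_fit(
            "disperser",
            lambda p: _logistic(t, *p) - y,
            [np.array([delta0, theta_up, phi]) for phi in phi_starts],
            lb=[1e-6, t_lo, 0.05],
            ub=[np.inf, t_hi, phi_hi],
            names=("delta", "theta", "phi"),
        )
    )

    # migrant: shared-asymptote double logistic
    mig_starts = [
        np.array([delta0, theta_up, phi, max(theta_down, theta_up + 30.0), phi])
        for phi in phi_starts
    ]
    fits.append(
        _ls_fit(
            "migrant",
            lambda p: _double_logistic(t, *p) - y,
            mig_starts,
            lb=[1e-6, t_lo, 0.05, t_lo, 0.05],
            ub=[np.inf, t_hi, phi_hi, t_hi, phi_hi],
            names=("delta", "theta_s", "phi_s", "theta_a", "phi_a"),
        )
    )

    # mixed migrant: separate return asymptote
    mix_starts = [
        np.array(
            [delta0, theta_up, phi, max(theta_down, theta_up + 30.0), phi, 0.5 * delta0]
        )
        for phi in phi_starts
    ]
    fits.append(
        _ls_fit(
            "mixed_migrant",
            lambda p: _double_logistic(t, p[0], p[1], p[2], p[3], p[4], p[5]) - y,
            mix_starts,
            lb=[1e-6, t_lo, 0.05, t_lo, 0.05, 0.0],
            ub=[np.inf, t_hi, phi_hi, t_hi, phi_hi, np.inf],
            names=("delta", "theta_s", "phi_s", "theta_a", "phi_a", "delta2"),
        )
    )

    if all(not f.converged for f in fits):
        raise RuntimeError(f"classification failure: no candidate converged "
                           f"for {series.animal_id}")
    return fits


def classify_tactic(
    fits: list[MovementModelFit],
    min_delta_km: float = 3.0,
    t_span: tuple[float, float] = (1.0, 365.0),
) -> TacticClassification:
    """Assign the space-use tactic from the AICc-ranked candidate fits.

    The lowest-AICc converged candidate wins; a range-shift winner (migrant,
    mixed migrant or disperser) must additionally clear ``min_delta_km``
    between seasonal ranges — an asymptote below that is within-range
    wander, not a movement between ranges — otherwise the next candidate in
    AICc order is considered.  The result is flagged for review when the top
    two eligible candidates sit within 2 AICc or the winning delta is within
    20% of the threshold.
    """
    ranked = sorted((f for f in fits if f.converged), key=lambda f: f.aicc)
    if not ranked:
        raise RuntimeError("no converged candidate to classify")
    notes = []
    eligible = []
    for f in ranked:
        if f.model in ("migrant", "mixed_migrant", "disperser"):
            realized = min(f.params.get("delta", 0.0), f.fitted_amplitude(t_span))
            if realized < min_delta_km:
                notes.append(
                    f"{f.model} skipped: realized range shift {realized:.2f} km "
                    f"< {min_delta_km} km"
                )
                continue
        eligible.append(f)
    if not eligible:  # every candidate was a sub-threshold range shift
        eligible = ranked
        notes.append("no candidate passed the delta threshold; using AICc top")
    chosen = eligible[0]

    flag = False
    if len(eligible) > 1 and (eligible[1].aicc - chosen.aicc) < 2.0:
        flag = True
        notes.append("top two candidates within 2 AICc")
    if chosen.model in ("migrant", "mixed_migrant"):
        realized = min(chosen.params["delta"], chosen.fitted_amplitude(t_span))
        if realized < 1.2 * min_delta_km:
            flag = True
            notes.append("delta within 20% of the migrant threshold")
    return TacticClassification(
        tactic=chosen.model,
        review_flag=flag,
        best_fit=chosen,
        fits=tuple(ranked),
        notes="; ".join(notes),
    )


# ---------------------------------------------------------------------------
# Seasonal logistic fits
# ---------------------------------------------------------------------------


def binary_tactic(tactic: str) -> str:
    """Collapse the five-model tactic onto the binary migrant/resident axis."""
    return "migrant" if tactic in ("migrant", "mixed_migrant") else "resident"


def season_split_day(migrant_fit: MovementModelFit) -> float:
    """Split day between the two seasonal movements: mid-summer plateau."""
    p = migrant_fit.params
    return 0.5 * (p["theta_s"] + p["theta_a"])


def seasonal_series(
    track: Track, migrant_fit: MovementModelFit, season: str
) -> DisplacementSeries:
    """Displacement series restricted to one seasonal movement.

    Spring uses the winter origin (first fix); autumn measures displacement
    from the summer-range origin, taken as the mean position over the
    mid-summer plateau between the two fitted movements.
    """
    split = season_split_day(migrant_fit)
    t = track.julian_days()
    if season == "spring":
        series = compute_displacement(track)
        return series.restrict(-np.inf, split)
    if season != "autumn":
        raise ValueError("season must be 'spring' or 'autumn'")
    p = migrant_fit.params
    lo = p["theta_s"] + 2.0 * p["phi_s"]
    hi = p["theta_a"] - 2.0 * p["phi_a"]
    if hi <= lo:
        lo, hi = split - 5.0, split + 5.0
    plateau = (t >= lo) & (t <= hi)
    xy = track.xy()
    if plateau.sum() >= 3:
        origin = tuple(xy[plateau].mean(axis=0))
    else:
        origin = tuple(xy[np.argmin(np.abs(t - split))])
    series = compute_displacement(track, origin=origin)
    return series.restrict(split, np.inf)


def fit_seasonal_logistic(
    series: DisplacementSeries,
    season: str,
    season_window: tuple[float, float] | None = None,
    phi_starts: tuple[float, ...] = (1.0, 5.0, 15.0),
    noise_floor: bool = True,
) -> SeasonalLogisticFit:
    """Least-squares logistic fit of one seasonal movement.

    Initialization: theta from the steepest observed displacement change,
    delta from the upper-quartile displacement, phi over a small ladder.

    Net displacement is a folded quantity: within-range scatter of scale
    sigma keeps a positive floor (E[nd^2] = d^2 + 2 sigma^2) under the
    series even while the animal sits on its range, which a pure logistic
    can only absorb by inflating the temporal scale.  By default the fitted
    mean is therefore sqrt(delta^2 L(t)^2 + c), with L the unit logistic
    and c >= 0 a nuisance floor; c -> 0 recovers the pure logistic exactly
    and (delta, theta, phi) keep their meaning.  ``noise_floor=False`` fits
    the bare 3-parameter logistic.
    """
    if season_window is not None:
        series = series.restrict(*season_window)
    t, y = series.times, series.nd
    if len(t) < 8:
        raise ValueError("seasonal window holds too few fixes to fit")
    theta_up, _ = _steepest_changes(t, y)
    delta0 = max(float(np.quantile(y, 0.75)), 1e-3)

    def unit_logistic(theta, phi):
        z = np.clip((theta - t) / max(phi, 1e-9), -500.0, 500.0)
        return 1.0 / (1.0 + np.exp(z))

    if noise_floor:

        def resid(p):
            return np.sqrt(p[0] ** 2 * unit_logistic(p[1], p[2]) ** 2 + p[3]) - y

        lb = [1e-6, float(t.min()) - 30.0, 0.02, 0.0]
        ub = [np.inf, float(t.max()) + 30.0, 200.0, 25.0]
        x0_extra = [min(float(np.quantile(y, 0.1)) ** 2, 24.0)]
    else:

        def resid(p):
            return p[0] * unit_logistic(p[1], p[2]) - y

        lb = [1e-6, float(t.min()) - 30.0, 0.02]
        ub = [np.inf, float(t.max()) + 30.0, 200.0]
        x0_extra = []

    best = None
    for phi0 in phi_starts:
        x0 = np.clip(
            [delta0, theta_up, phi0] + x0_extra,
            np.asarray(lb) + 1e-9,
            np.asarray(ub) - 1e-9,
        )
        try:
            res = least_squares(resid, x0, bounds=(lb, ub), max_nfev=2000)
        except Exception:
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res.x, bool(res.success))
    if best is None:
        raise RuntimeError(
            f"seasonal logistic fit failed for {series.animal_id} ({season}); "
            f"n={len(t)}, window=({t.min():.1f}, {t.max():.1f})"
        )
    rss, x, ok = best
    return SeasonalLogisticFit(
        season=season,
        delta=float(x[0]),
        theta=float(x[1]),
        phi=float(x[2]),
        rss=rss,
        n_obs=len(t),
        converged=ok,
    )


# ---------------------------------------------------------------------------
# Migration events
# ---------------------------------------------------------------------------


def extract_migration_event(
    fit: SeasonalLogisticFit,
    track: Track,
    stopover_set=None,
    year: int | None = None,
) -> MigrationEvent:
    """Derive the five migration characteristics from a seasonal fit.

    The migration window is [theta - 2 phi, theta + 2 phi].  Distance roamed
    is the sum of Euclidean step lengths between successive fixes inside the
    window; mean speed is the mean of per-step speeds (km/h).
    """
    if not fit.converged:
        raise ValueError("cannot extract an event from a non-converged fit")
    departure = fit.theta - 2.0 * fit.phi
    arrival = fit.theta + 2.0 * fit.phi
    t = track.julian_days()
    if departure < t.min() - 1e-9 or arrival > t.max() + 1e-9:
        raise ValueError(
            f"migration window [{departure:.1f}, {arrival:.1f}] outside the "
            f"track span [{t.min():.1f}, {t.max():.1f}]"
        )
    inside = (t >= departure) & (t <= arrival)
    if inside.sum() < 2:
        raise ValueError("migration window holds fewer than two fixes")
    xy = track.xy()[inside]
    tt = t[inside]
    steps = np.hypot(*np.diff(xy, axis=0).T)
    dt_h = np.diff(tt) * 24.0
    ok = dt_h > 1e-9
    n_stop = 0
    if stopover_set is not None:
        n_stop = getattr(stopover_set, "n_stopovers", int(stopover_set))
    ts = pd.to_datetime(track.fixes["timestamp"])
    return MigrationEvent(
        animal_id=track.animal_id,
        year=int(year) if year is not None else int(ts.iloc[0].year),
        season=fit.season,
        sex=track.sex,
        departure=departure,
        arrival=arrival,
        duration=4.0 * fit.phi,
        distance_roamed=float(steps.sum()),
        mean_speed=float(np.mean(steps[ok] / dt_h[ok])),
        n_stopovers=n_stop,
        range_distance=fit.delta,
    )


def analyze_track(
    track: Track, min_delta_km: float = 3.0
) -> dict:
    """Classify one track and, if migratory, fit both seasonal movements.

    Returns a dict with keys ``classification``, ``spring_fit``,
    ``autumn_fit`` (fits are None for non-migrants or failed seasons).
    """
    series = compute_displacement(track)
    fits = fit_movement_models(series)
    cls = classify_tactic(
        fits,
        min_delta_km=min_delta_km,
        t_span=(float(series.times.min()), float(series.times.max())),
    )
    out = {"classification": cls, "spring_fit": None, "autumn_fit": None}
    if cls.tactic in ("migrant", "mixed_migrant"):
        base = cls.best_fit
        for season in ("spring", "autumn"):
            try:
                srs = seasonal_series(track, base, season)
                out[f"{season}_fit"] = fit_seasonal_logistic(srs, season)
            except (ValueError, RuntimeError):
                out[f"{season}_fit"] = None
    return out


def events_to_table(events: list[MigrationEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "animal_id": e.animal_id,
                "year": e.year,
                "season": e.season,
                "sex": e.sex,
                "departure": e.departure,
                "arrival": e.arrival,
                "duration": e.duration,
                "distance_roamed": e.distance_roamed,
                "mean_speed": e.mean_speed,
                "n_stopovers": e.n_stopovers,
                "stopover_used": e.stopover_used,
                "range_distance": e.range_distance,
            }
        )
    return pd.DataFrame(rows)
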