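"""Brownian-bridge utilization distributions and stopover detection.

A migratory trajectory segment is turned into a utilization distribution
(UD) by averaging, over time, the Gaussian marginals of Brownian bridges
spanning successive fixes.  The marginal at interior time ``t`` of a bridge
from observed fix ``a`` (time 0) to ``b`` (time T) is Gaussian with mean the
linear interpolation and variance (per coordinate)

    sigma_m^2 * t (T - t) / T + sigma_loc^2 * ((1 - t/T)^2 + (t/T)^2)

where ``sigma_m^2`` is the Brownian motion variance (km^2/h) and
``sigma_loc`` the GPS location-error sd (km).  ``sigma_m^2`` is estimated by
the leave-one-out likelihood of odd-indexed fixes under bridges spanning
their even-indexed neighbours.

Stopovers are the top-quantile cells of the UD (smallest cell set holding
25% of the probability mass by default), clustered by 8-connectivity, with
clusters dropped when they overlap a seasonal range or hold the track for
less than a minimum residence time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize_scalar

from herdtrack.synthetic import Track

__all__ = [
    "BBVariance",
    "UDGridSpec",
    "UDGrid",
    "StopoverCluster",
    "StopoverSet",
    "estimate_bb_variance",
    "make_grid_for_segment",
    "compute_bbmm_ud",
    "identify_stopovers",
]


@dataclass(frozen=True)
class BBVariance:
    sigma_m2: float  # Brownian motion variance, km^2/h
    sigma_loc: float  # location-error sd, km
    loglik: float

    def __post_init__(self) -> None:
        if self.sigma_m2 < 0 or self.sigma_loc < 0:
            raise ValueError("variance components must be non-negative")


@dataclass(frozen=True)
class UDGridSpec:
    """Regular analysis grid; origin is the lower-left cell edge (km)."""

    x0: float
    y0: float
    cell_km: float
    nx: int
    ny: int

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_km
        cy = self.y0 + (np.arange(self.ny) + 0.5) * self.cell_km
        return cx, cy

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        j = int((x - self.x0) / self.cell_km)
        i = int((y - self.y0) / self.cell_km)
        return min(max(i, 0), self.ny - 1), min(max(j, 0), self.nx - 1)


@dataclass(frozen=True)
class UDGrid:
    spec: UDGridSpec
    probs: np.ndarray  # (ny, nx), sums to 1

    def __post_init__(self) -> None:
        if np.any(self.probs < 0):
            raise ValueError("UD probabilities must be non-negative")
        if abs(float(self.probs.sum()) - 1.0) > 1e-6:
            raise ValueError("UD probabilities must sum to 1")


@dataclass(frozen=True)
class StopoverCluster:
    centroid: tuple[float, float]
    cells: tuple[tuple[int, int], ...]
    mass: float
    entry_day: float  # first fix time (Julian day) inside; nan if never
    residence_h: float


@dataclass(frozen=True)
class StopoverSet:
    clusters: tuple[StopoverCluster, ...]
    n_stopovers: int
    dropped: tuple[str, ...] = ()  # one log line per rejected cluster


def _bridge_var(sigma_m2: float, sigma_loc: float, t: np.ndarray, T: float) -> np.ndarray:
    frac = t / T
    return sigma_m2 * t * (T - t) / T + sigma_loc**2 * ((1 - frac) ** 2 + frac**2)


def _segment_arrays(segment: Track) -> tuple[np.ndarray, np.ndarray]:
    xy = segment.xy()
    ts = pd.to_datetime(segment.fixes["timestamp"])
    hours = (ts - ts.iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    return xy, hours


def estimate_bb_variance(segment: Track, sigma_loc: float = 0.02) -> BBVariance:
    """Estimate sigma_m^2 by odd/even leave-one-out maximum likelihood.

    Every odd-indexed fix is predicted by the Brownian bridge spanning its
    even-indexed neighbours; the likelihood is maximised over sigma_m^2 by
    bounded search on a log scale (with the boundary sigma_m^2 = 0 checked
    explicitly).
    """
    if len(segment) < 5:
        raise ValueError("need at least 5 fixes to estimate sigma_m^2")
    xy, hours = _segment_arrays(segment)
    idx = np.arange(1, len(xy) - 1, 2)
    a, b, m = xy[idx - 1], xy[idx + 1], xy[idx]
    T = hours[idx + 1] - hours[idx - 1]
    t = hours[idx] - hours[idx - 1]
    good = T > 1e-9
    a, b, m, T, t = a[good], b[good], m[good], T[good], t[good]
    mu = a + ((t / T)[:, None]) * (b - a)
    sq = ((m - mu) ** 2).sum(axis=1)

    def negll_of(sigma_m2: float) -> float:
        var = np.maximum(_bridge_var(sigma_m2, sigma_loc, t, T), 1e-12)
        return float(np.sum(np.log(2.0 * math.pi * var) + sq / (2.0 * var)))

    res = minimize_scalar(
        lambda u: negll_of(math.exp(u)),
        bounds=(math.log(1e-8), math.log(1e4)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    best_s2, best_nll = math.exp(res.x), res.fun
    nll0 = negll_of(0.0)
    if nll0 <= best_nll:
        best_s2, best_nll = 0.0, nll0
    return BBVariance(sigma_m2=best_s2, sigma_loc=sigma_loc, loglik=-best_nll)


def make_grid_for_segment(
    segment: Track,
    bbvar: BBVariance,
    cell_m: float = 100.0,
    margin_sd: float = 3.0,
) -> UDGridSpec:
    """Grid covering the segment bounding box plus a predictive-sd margin."""
    xy, hours = _segment_arrays(segment)
    T = float(np.max(np.diff(hours))) if len(hours) > 1 else 2.0
    sd_max = math.sqrt(
        max(bbvar.sigma_m2 * T / 4.0 + bbvar.sigma_loc**2, bbvar.sigma_loc**2, 1e-12)
    )
    margin = margin_sd * sd_max
    cell = cell_m / 1000.0
    x0 = xy[:, 0].min() - margin
    y0 = xy[:, 1].min() - margin
    nx = int(math.ceil((xy[:, 0].max() + margin - x0) / cell)) + 1
    ny = int(math.ceil((xy[:, 1].max() + margin - y0) / cell)) + 1
    return UDGridSpec(x0=x0, y0=y0, cell_km=cell, nx=nx, ny=ny)


def compute_bbmm_ud(
    segment: Track,
    bbvar: BBVariance,
    grid: UDGridSpec,
    quad_per_interval: int = 10,
) -> UDGrid:
    """Discretized Brownian-bridge UD of a trajectory segment.

    Time-weighted average of bridge marginals over all fix intervals, with a
    midpoint quadrature of at least ``quad_per_interval`` points per
    interval, evaluated at cell centers and normalized to sum 1.
    """
    if len(segment) < 2:
        raise ValueError("need at least 2 fixes for a bridge")
    xy, hours = _segment_arrays(segment)
    # coverage check: bounding box + 3 predictive sd inside grid
    T_max = float(np.max(np.diff(hours)))
    sd_max = math.sqrt(
        max(bbvar.sigma_m2 * T_max / 4.0 + bbvar.sigma_loc**2, 1e-12)
    )
    margin = 3.0 * sd_max
    if (
        xy[:, 0].min() - margin < grid.x0
        or xy[:, 1].min() - margin < grid.y0
        or xy[:, 0].max() + margin > grid.x0 + grid.nx * grid.cell_km
        or xy[:, 1].max() + margin > grid.y0 + grid.ny * grid.cell_km
    ):
        raise ValueError("grid does not cover the segment with a 3-sd margin")

    cx, cy = grid.centers()
    acc = np.zeros((grid.ny, grid.nx))
    total_T = hours[-1] - hours[0]
    if total_T <= 0:
        raise ValueError("segment has zero duration")
    tiny = grid.cell_km * 1e-3
    for k in range(len(xy) - 1):
        T = hours[k + 1] - hours[k]
        if T <= 1e-9:
            continue
        a, b = xy[k], xy[k + 1]
        tq = (np.arange(quad_per_interval) + 0.5) / quad_per_interval * T
        w = (T / quad_per_interval) / total_T
        var = _bridge_var(bbvar.sigma_m2, bbvar.sigma_loc, tq, T)
        mu = a[None, :] + (tq / T)[:, None] * (b - a)[None, :]
        for q in range(quad_per_interval):
            sd = math.sqrt(var[q])
            if sd < tiny:  # point-mass limit
                i, j = grid.cell_of(mu[q, 0], mu[q, 1])
                acc[i, j] += w
                continue
            px = np.exp(-0.5 * ((cx - mu[q, 0]) / sd) ** 2)
            py = np.exp(-0.5 * ((cy - mu[q, 1]) / sd) ** 2)
            dens = np.outer(py, px) / (2.0 * math.pi * sd * sd)
            acc += w * dens * grid.cell_km**2
    s = acc.sum()
    if s <= 0:
        raise ValueError("UD accumulated zero mass; grid misconfigured")
    return UDGrid(spec=grid, probs=acc / s)


def _longest_true_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def _top_mass_mask(probs: np.ndarray, quantile: float) -> np.ndarray:
    """Smallest set of highest-probability cells holding ``quantile`` mass."""
    flat = probs.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    n_keep = int(np.searchsorted(csum, quantile)) + 1
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:n_keep]] = True
    return mask.reshape(probs.shape)


def identify_stopovers(
    ud: UDGrid,
    segment: Track,
    quantile: float = 0.25,
    min_residence_h: float = 12.0,
    exclude_ranges: list[tuple[float, float, float]] | None = None,
    threshold_mode: str = "mass",
    max_drift_km: float = 0.75,
    slow_step_factor: float = 0.5,
    min_slow_fraction: float = 0.2,
    min_slow_run_h: float = 10.0,
) -> StopoverSet:
    """Stopovers from the top-quantile cells of the UD.

    ``threshold_mode='mass'`` (default) selects the smallest cell set holding
    the top ``quantile`` of probability mass; ``'percell'`` instead keeps
    cells above the per-cell (1 - quantile) probability percentile.  Selected
    cells are clustered by 8-connectivity; clusters are then dropped (each
    with a log line) when they

    * overlap an excluded seasonal range (circles ``(x, y, radius_km)``),
    * hold the track for less than ``min_residence_h``, or
    * are pass-throughs rather than dwells, judged on the cluster-core
      fixes: the mean position over the first and second half of the visit
      drifts more than ``max_drift_km``; or the visit lacks a sustained
      dwell signature — at least ``min_slow_fraction`` of its fixes, and an
      unbroken run of at least ``min_slow_run_h`` hours, moving at
      dwell-like speed (step length below ``slow_step_factor`` times the
      segment-wide median).  A stopover is a sustained reduced-movement
      episode; slow corridor travel keeps en-route step lengths and chance
      loiters do not sustain them.  These stationarity checks stand in for
      the visual assessment of candidate stopovers.
    """
    probs = ud.probs
    if threshold_mode == "mass":
        mask = _top_mass_mask(probs, quantile)
    elif threshold_mode == "percell":
        thr = np.quantile(probs[probs > 0], 1.0 - quantile)
        mask = probs >= thr
    else:
        raise ValueError("threshold_mode must be 'mass' or 'percell'")

    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    xy, hours = _segment_arrays(segment)
    t_jul = segment.julian_days()
    fix_dt_h = float(np.median(np.diff(hours))) if len(hours) > 1 else 2.0
    spec = ud.spec
    cx, cy = spec.centers()

    fix_cells = np.array([spec.cell_of(x, y) for x, y in xy])

    # membership on clusters dilated by one cell, so fixes on a cell edge
    # still count toward residence
    dilated = ndimage.grey_dilation(labels, size=(3, 3))
    dilated[labels > 0] = labels[labels > 0]

    steps = np.hypot(*np.diff(xy, axis=0).T)
    # per-fix movement scale: mean of adjacent step lengths
    fix_step = np.empty(len(xy))
    if len(steps):
        fix_step[0], fix_step[-1] = steps[0], steps[-1]
        if len(xy) > 2:
            fix_step[1:-1] = 0.5 * (steps[:-1] + steps[1:])
    else:
        fix_step[:] = 0.0
    med_step_all = float(np.median(fix_step)) if len(fix_step) else 0.0

    clusters: list[StopoverCluster] = []
    dropped: list[str] = []
    for lab in range(1, n_lab + 1):
        cells = np.argwhere(labels == lab)
        mass = float(probs[labels == lab].sum())
        wts = probs[cells[:, 0], cells[:, 1]]
        centroid = (
            float(np.average(cx[cells[:, 1]], weights=wts)),
            float(np.average(cy[cells[:, 0]], weights=wts)),
        )
        in_cluster = dilated[fix_cells[:, 0], fix_cells[:, 1]] == lab
        residence = float(in_cluster.sum() * fix_dt_h)
        # stationarity statistics use the core cells only: passage fixes in
        # the dilated fringe would dilute a genuine dwell's signature
        in_core = labels[fix_cells[:, 0], fix_cells[:, 1]] == lab
        if not in_core.any():
            in_core = in_cluster
        entry = float(t_jul[in_cluster][0]) if in_cluster.any() else float("nan")
        cluster = StopoverCluster(
            centroid=centroid,
            cells=tuple(map(tuple, cells)),
            mass=mass,
            entry_day=entry,
            residence_h=residence,
        )
        if exclude_ranges:
            # judged at the use-weighted centroid: a mid-route dwell whose
            # fringe cells brush the range circle is still a stopover
            overlap = False
            for rx, ry, rr in exclude_ranges:
                if math.hypot(centroid[0] - rx, centroid[1] - ry) <= rr:
                    overlap = True
                    break
            if overlap:
                dropped.append(
                    f"cluster at ({centroid[0]:.2f}, {centroid[1]:.2f}) overlaps a "
                    "seasonal range"
                )
                continue
        if residence < min_residence_h:
            dropped.append(
                f"cluster at ({centroid[0]:.2f}, {centroid[1]:.2f}) residence "
                f"{residence:.1f} h < {min_residence_h} h"
            )
            continue
        visit = xy[in_core]
        half = len(visit) // 2
        if half >= 2:
            drift = float(
                np.hypot(*(visit[half:].mean(axis=0) - visit[:half].mean(axis=0)))
            )
            if drift > max_drift_km:
                dropped.append(
                    f"cluster at ({centroid[0]:.2f}, {centroid[1]:.2f}) drifts "
                    f"{drift:.2f} km during the visit (pass-through)"
                )
                continue
        # en-route scale for this cluster: median step over the fixes not
        # visiting it — the segment-wide median collapses onto the dwell
        # scale when a long dwell dominates the window
        if (~in_cluster).sum() >= 5:
            med_step_travel = float(np.median(fix_step[~in_cluster]))
        else:
            med_step_travel = med_step_all
        if med_step_travel > 0 and in_core.any():
            slow_all = fix_step < slow_step_factor * med_step_travel
            frac = float(slow_all[in_core].mean())
            run = _longest_true_run(slow_all & in_cluster) * fix_dt_h
            if frac < min_slow_fraction or run < min_slow_run_h:
                dropped.append(
                    f"cluster at ({centroid[0]:.2f}, {centroid[1]:.2f}) lacks a "
                    f"sustained dwell signature (slow-fix fraction {frac:.2f}, "
                    f"longest slow run {run:.0f} h); not a dwell"
                )
                continue
        clusters.append(cluster)
    clusters.sort(key=lambda c: c.entry_day if np.isfinite(c.entry_day) else np.inf)
    return StopoverSet(
        clusters=tuple(clusters), n_stopovers=len(clusters), dropped=tuple(dropped)
    )
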