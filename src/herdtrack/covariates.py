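"""Daily activity proportions, kernel home ranges, and landscape covariates."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from herdtrack.nsd import MigrationEvent
from herdtrack.synthetic import ActivitySeries, LandscapeGrid, Track

__all__ = [
    "DailyActivity",
    "HomeRange",
    "CovariateRecord",
    "daily_activity_proportion",
    "arcsine_rescale",
    "kernel_home_range",
    "build_covariates",
]


@dataclass(frozen=True)
class DailyActivity:
    animal_id: str
    date: object  # datetime.date, UTC calendar day
    n_values: int
    prop_active: float
    retained: bool  # n_values >= 5
    stopover_state: str = "no_stopover_user"


@dataclass(frozen=True)
class HomeRange:
    """A fixed-kernel utilization contour for one animal-season."""

    animal_id: str
    season: str
    level: float
    area_km2: float
    cells: np.ndarray  # boolean mask over the KDE grid
    grid_x: np.ndarray
    grid_y: np.ndarray
    barycenter: tuple[float, float]
    degenerate: bool = False

    def radius_km(self) -> float:
        """Radius of the circle with the contour's area (for overlap tests)."""
        return math.sqrt(self.area_km2 / math.pi)


@dataclass(frozen=True)
class CovariateRecord:
    animal_id: str
    year: int
    season: str
    dist_coast_km: float
    elev_diff_m: float
    range_distance_km: float
    region: int

    def __post_init__(self) -> None:
        if self.dist_coast_km < 0 or self.elev_diff_m < 0:
            raise ValueError("distances must be non-negative")


def daily_activity_proportion(
    activity: ActivitySeries,
    threshold: int | None = None,
    min_values: int = 5,
) -> list[DailyActivity]:
    """Proportion of activity values above threshold per UTC calendar day.

    Days with fewer than ``min_values`` values are marked not retained.
    """
    thr = activity.active_threshold if threshold is None else threshold
    ts = pd.to_datetime(activity.timestamps)
    df = pd.DataFrame({"date": ts.dt.date, "count": activity.counts})
    out = []
    for date, grp in df.groupby("date", sort=True):
        n = len(grp)
        prop = float((grp["count"] > thr).mean())
        out.append(
            DailyActivity(
                animal_id=activity.animal_id,
                date=date,
                n_values=n,
                prop_active=prop,
                retained=n >= min_values,
            )
        )
    return out


def arcsine_rescale(p, variant: str = "literal"):
    """Arcsine activity-proportion transform, rescaled onto [0, 1].

    ``variant='literal'`` computes arcsin(p) * 2 / pi; ``variant='sqrt'``
    the conventional variance-stabilizing arcsin(sqrt(p)) * 2 / pi.  Both are
    monotone on [0, 1] with f(0) = 0 and f(1) = 1.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if variant == "literal":
        out = np.arcsin(arr) * 2.0 / math.pi
    elif variant == "sqrt":
        out = np.arcsin(np.sqrt(arr)) * 2.0 / math.pi
    else:
        raise ValueError("variant must be 'literal' or 'sqrt'")
    return float(out) if out.ndim == 0 else out


def kernel_home_range(
    fixes: np.ndarray,
    animal_id: str = "",
    season: str = "",
    level: float = 0.95,
    bandwidth_scale: float = 1.0,
    grid_cells: int = 120,
) -> HomeRange:
    """Fixed-kernel utilization contour of a cloud of fixes.

    Bivariate Gaussian KDE with the normal-reference bandwidth scaled by
    ``bandwidth_scale``; the contour is the smallest grid-cell set holding
    ``level`` of the estimated mass.  Identical fixes degenerate to a
    flagged one-cell range.
    """
    fixes = np.asarray(fixes, dtype=float)
    if len(fixes) < 30:
        raise ValueError("need at least 30 fixes for a kernel range")
    bary = (float(fixes[:, 0].mean()), float(fixes[:, 1].mean()))
    spread = fixes.std(axis=0)
    if np.all(spread < 1e-9):
        warnings.warn("degenerate home range: all fixes identical", stacklevel=2)
        eps = 0.05
        return HomeRange(
            animal_id=animal_id,
            season=season,
            level=level,
            area_km2=eps * eps,
            cells=np.ones((1, 1), dtype=bool),
            grid_x=np.array([bary[0]]),
            grid_y=np.array([bary[1]]),
            barycenter=bary,
            degenerate=True,
        )
    kde = gaussian_kde(fixes.T)
    kde.set_bandwidth(kde.factor * bandwidth_scale)
    pad = 3.0 * float(spread.max())
    gx = np.linspace(fixes[:, 0].min() - pad, fixes[:, 0].max() + pad, grid_cells)
    gy = np.linspace(fixes[:, 1].min() - pad, fixes[:, 1].max() + pad, grid_cells)
    xx, yy = np.meshgrid(gx, gy)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    cell_area = (gx[1] - gx[0]) * (gy[1] - gy[0])
    mass = dens * cell_area
    mass = mass / mass.sum()
    flat = mass.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    n_keep = int(np.searchsorted(csum, level)) + 1
    cells = np.zeros(flat.shape, dtype=bool)
    cells[order[:n_keep]] = True
    cells = cells.reshape(mass.shape)
    return HomeRange(
        animal_id=animal_id,
        season=season,
        level=level,
        area_km2=float(cells.sum() * cell_area),
        cells=cells,
        grid_x=gx,
        grid_y=gy,
        barycenter=bary,
    )


def build_covariates(
    track: Track,
    winter_range: HomeRange,
    landscape: LandscapeGrid,
    event: MigrationEvent,
) -> CovariateRecord:
    """Landscape/movement covariates for one migration event.

    Distance to coast is the winter-range barycenter's distance to the x = 0
    coastline; elevation difference is the absolute difference between the
    elevation at the last fix before departure and the first fix after
    arrival; range distance is the fitted logistic asymptote carried on the
    event; the region label is taken at the winter barycenter.
    """
    t = track.julian_days()
    xy = track.xy()
    before = np.flatnonzero(t <= event.departure)
    after = np.flatnonzero(t >= event.arrival)
    if len(before) == 0 or len(after) == 0:
        raise ValueError("track does not bracket the migration window")
    x0, y0 = xy[before[-1]]
    x1, y1 = xy[after[0]]
    elev_diff = abs(landscape.elevation_at(x0, y0) - landscape.elevation_at(x1, y1))
    bx, by = winter_range.barycenter
    return CovariateRecord(
        animal_id=track.animal_id,
        year=event.year,
        season=event.season,
        dist_coast_km=abs(bx),
        elev_diff_m=float(elev_diff),
        range_distance_km=float(event.range_distance),
        region=landscape.region_at(bx, by),
    )
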