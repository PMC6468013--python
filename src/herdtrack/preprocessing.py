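"""Fix-table cleaning applied before any analysis.

Two steps: discard the acclimation window after collaring, and screen
positional outliers with a sustained-speed rule plus an out-and-back "spike"
rule (single fixes reached and left at implausible speed with a near-reversal
turning angle).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from herdtrack.synthetic import Track, replace_track_fixes

__all__ = ["trim_capture_window", "screen_outliers"]


def trim_capture_window(track: Track, hours: float = 24.0) -> Track:
    """Drop all fixes within ``hours`` of the first fix (capture handling).

    Emits a warning and returns an empty track if nothing survives.
    """
    if len(track) == 0:
        raise ValueError("track must be nonempty")
    ts = pd.to_datetime(track.fixes["timestamp"])
    keep = (ts - ts.iloc[0]) >= pd.Timedelta(hours=hours)
    out = track.fixes.loc[keep.to_numpy()]
    if out.empty:
        warnings.warn(
            f"trim_capture_window removed every fix of {track.animal_id}",
            stacklevel=2,
        )
    return replace_track_fixes(track, out)


def _step_speeds(fixes: pd.DataFrame) -> np.ndarray:
    """Speed (km/h) of each step i -> i+1; length n-1."""
    xy = fixes[["x_km", "y_km"]].to_numpy()
    ts = pd.to_datetime(fixes["timestamp"])
    dt_h = np.diff(ts.astype("int64").to_numpy()) / 3.6e12
    d = np.hypot(*np.diff(xy, axis=0).T)
    return d / np.maximum(dt_h, 1e-9)


def _turn_angles(fixes: pd.DataFrame) -> np.ndarray:
    """Absolute turning angle (deg) at each interior fix; length n-2.

    180 degrees = full reversal (out-and-back).
    """
    xy = fixes[["x_km", "y_km"]].to_numpy()
    v = np.diff(xy, axis=0)
    a, b = v[:-1], v[1:]
    dot = (a * b).sum(axis=1)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    cos = np.clip(dot / np.maximum(na * nb, 1e-12), -1.0, 1.0)
    return 180.0 - np.degrees(np.arccos(cos))  # 180 when b reverses a


def screen_outliers(
    track: Track,
    max_speed_kmh: float = 15.0,
    spike_angle_deg: float = 170.0,
    spike_speed_kmh: float = 10.0,
    max_passes: int = 20,
) -> tuple[Track, int]:
    """Remove positional outliers; returns (cleaned track, n removed).

    Rules, applied iteratively until stable (so the screen is idempotent on
    its own output):

    * spike: an interior fix whose incoming and outgoing speeds both exceed
      ``spike_speed_kmh`` and whose turning reversal exceeds
      ``spike_angle_deg`` is removed;
    * sustained speed: a fix entered faster than ``max_speed_kmh`` is
      removed.

    Spikes are handled first since a single displaced fix otherwise implicates
    its (valid) neighbours through the speed rule.
    """
    fixes = track.fixes.reset_index(drop=True)
    removed = 0
    for _ in range(max_passes):
        n = len(fixes)
        if n < 3:
            break
        speeds = _step_speeds(fixes)
        reversal = _turn_angles(fixes)
        spike = (
            (speeds[:-1] > spike_speed_kmh)
            & (speeds[1:] > spike_speed_kmh)
            & (reversal > spike_angle_deg)
        )
        if spike.any():
            drop = np.flatnonzero(spike) + 1  # interior index offset
            fixes = fixes.drop(fixes.index[drop]).reset_index(drop=True)
            removed += len(drop)
            continue
        fast = speeds > max_speed_kmh
        if fast.any():
            drop = np.flatnonzero(fast)[:1] + 1  # one at a time: speeds shift
            fixes = fixes.drop(fixes.index[drop]).reset_index(drop=True)
            removed += 1
            continue
        break
    return replace_track_fixes(track, fixes), removed
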