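"""Encounter segmentation and per-track dive-behaviour metrics.

A deep dive splits into two phases: the *initial descent* from the surface and
the *at depth* (presumed foraging) phase, which starts — irreversibly — the
first time the whale comes within 200 m of the local seafloor.  Descent angle
is summarised as the peak of a kernel density over per-segment angles, swim
speed as per-phase medians of step speeds on the smoothed positions, and
altitude as depth of the nearest bathymetry node minus whale depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.stats import gaussian_kde

from .localize import Track
from .scene import Bathymetry

__all__ = [
    "Phase",
    "Encounter",
    "segment_encounters",
    "altitude_above_seafloor",
    "classify_phases",
    "descent_angle",
    "swim_speeds",
]


class Phase(str, Enum):
    INITIAL_DESCENT = "initial_descent"
    AT_DEPTH = "at_depth"


@dataclass
class Encounter:
    """A contiguous block of detections with no gap exceeding the threshold."""

    encounter_id: int
    start: float
    end: float
    member_tracks: set = field(default_factory=set)

    @property
    def duration(self) -> float:
        return self.end - self.start


def segment_encounters(detection_times, gap_minutes: float = 30.0,
                       ids=None) -> list[Encounter]:
    """Split detection times into encounters at gaps strictly exceeding
    ``gap_minutes`` (a gap of exactly the threshold does not split).

    ``ids``, if given, is a parallel sequence of individual identifiers used
    to fill each encounter's membership set.
    """
    times = np.asarray(detection_times, dtype=float)
    if times.size == 0:
        return []
    order = np.argsort(times, kind="stable")
    times = times[order]
    ids_sorted = None if ids is None else np.asarray(ids, dtype=object)[order]
    gap_s = gap_minutes * 60.0
    breaks = np.nonzero(np.diff(times) > gap_s)[0] + 1
    encounters = []
    for eid, chunk in enumerate(np.split(np.arange(times.size), breaks)):
        members = set() if ids_sorted is None else set(ids_sorted[chunk])
        encounters.append(Encounter(
            encounter_id=eid, start=float(times[chunk[0]]),
            end=float(times[chunk[-1]]), member_tracks=members))
    return encounters


def _track_positions(track, smoothed=False) -> np.ndarray:
    if isinstance(track, Track):
        return track.best_positions if smoothed else track.positions
    return np.asarray(track, dtype=float).reshape(-1, 3)


def altitude_above_seafloor(track, bathymetry: Bathymetry,
                            interpolate: bool = False) -> np.ndarray:
    """Per-point altitude (m): seafloor depth at the nearest grid node minus
    whale depth.  Set ``interpolate`` for bilinear bathymetry lookup instead
    of nearest-node.  Raises for points outside the grid."""
    pos = _track_positions(track)
    floor = bathymetry.depth_at(pos[:, 0], pos[:, 1], interpolate=interpolate)
    return floor - pos[:, 2]


def classify_phases(track, bathymetry: Bathymetry,
                    threshold_m: float = 200.0) -> list[Phase]:
    """One-way phase labels: initial descent until the first point within
    ``threshold_m`` (inclusive) of the seafloor, at depth thereafter.  A track
    that never comes within the threshold is all initial descent."""
    alt = altitude_above_seafloor(track, bathymetry)
    labels = [Phase.INITIAL_DESCENT] * len(alt)
    hit = np.nonzero(alt <= threshold_m)[0]
    if hit.size:
        for k in range(int(hit[0]), len(alt)):
            labels[k] = Phase.AT_DEPTH
    return labels


def _segment_angles(positions: np.ndarray) -> np.ndarray:
    """Per-segment pitch angles (deg), negative downward, relative to
    horizontal; zero-length segments are skipped."""
    d = np.diff(positions, axis=0)
    horiz = np.hypot(d[:, 0], d[:, 1])
    nonzero = (horiz > 0) | (d[:, 2] != 0)
    if not nonzero.any():
        raise ValueError("all segments have zero length")
    # depth is positive down: a descending segment (d_depth > 0) is negative
    return np.degrees(np.arctan2(-d[nonzero, 2], horiz[nonzero]))


def descent_angle(track, phases=None, grid_step: float = 0.1,
                  sd_window_deg: float = 20.0):
    """Descent angle of a track: the mode of a Gaussian KDE over per-segment
    angles, with a standard deviation over angles within ``sd_window_deg`` of
    that peak.

    ``track`` may be a :class:`~whaletrack.localize.Track` (smoothed positions
    are used when present) or an (n, 3) position array.  ``phases`` restricts
    the computation to initial-descent points.  Returns
    ``(peak_deg, sd_deg, angles)``.
    """
    pos = _track_positions(track, smoothed=True)
    if phases is not None:
        mask = np.asarray([p == Phase.INITIAL_DESCENT for p in phases])
        pos = pos[mask]
    if len(pos) < 2:
        raise ValueError("need at least 2 descent-phase points")
    angles = _segment_angles(pos)
    grid = np.arange(-90.0, 90.0 + grid_step / 2, grid_step)
    if np.std(angles) < 1e-9:
        peak = float(angles[0])
    else:
        kde = gaussian_kde(angles, bw_method="silverman")
        peak = float(grid[np.argmax(kde(grid))])
    near = angles[np.abs(angles - peak) <= sd_window_deg]
    sd = float(np.std(near, ddof=1)) if near.size > 1 else 0.0
    return peak, sd, angles


def swim_speeds(track: Track, phases, min_descent_s: float = 300.0,
                min_at_depth_s: float = 600.0) -> dict:
    """Median swim speed (m/s) per dive phase from smoothed positions.

    Step speed is 3D Euclidean distance over the time interval; each step is
    assigned the phase of its starting point.  A phase shorter than its
    minimum duration (descent 5 min, at depth 10 min by default) is reported
    as NaN.
    """
    if track.smoothed_positions is None:
        raise ValueError("swim_speeds requires smoothed positions")
    t = track.times
    dt = np.diff(t)
    if np.any(dt == 0):
        raise ValueError("zero time interval between points")
    step = np.linalg.norm(np.diff(track.smoothed_positions, axis=0), axis=1)
    speed = step / dt
    phase_arr = np.asarray([p.value for p in phases])
    out = {}
    for phase, min_s in ((Phase.INITIAL_DESCENT, min_descent_s),
                         (Phase.AT_DEPTH, min_at_depth_s)):
        mask = phase_arr == phase.value
        if not mask.any():
            out[phase.value] = float("nan")
            continue
        idx = np.nonzero(mask)[0]
        duration = float(t[idx[-1]] - t[idx[0]])
        if duration < min_s:
            out[phase.value] = float("nan")
            continue
        step_mask = mask[:-1]
        out[phase.value] = float(np.median(speed[step_mask])) if step_mask.any() else float("nan")
    return out
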