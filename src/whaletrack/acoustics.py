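"""Propagation and beam-pattern models shared by the scene generator and the
detection-probability simulation.

Transmission loss (TL) is pluggable: any callable
``tl(range_m, source_depth_m, receiver_depth_m) -> dB`` works.  The default is
spherical spreading plus linear absorption, appropriate for the ~40 kHz clicks
of deep-diving beaked whales over the few-kilometre ranges modelled here.
Precomputed range x depth TL tables (e.g. exported from a ray-tracing run) can
be loaded with :class:`TableTL`.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.special import j1

__all__ = [
    "SphericalSpreadingTL",
    "TableTL",
    "off_axis_attenuation",
]


class SphericalSpreadingTL:
    """TL = 20*log10(r / 1 m) + alpha * r.

    Parameters
    ----------
    absorption_db_per_m : float
        Linear absorption coefficient alpha, default 0.01 dB/m (seawater at
        ~40 kHz).  Depth arguments are accepted for interface compatibility
        and ignored.
    """

    def __init__(self, absorption_db_per_m: float = 0.01):
        if absorption_db_per_m < 0:
            raise ValueError("absorption coefficient must be >= 0")
        self.absorption_db_per_m = float(absorption_db_per_m)

    def __call__(self, range_m, source_depth_m=None, receiver_depth_m=None):
        r = np.asarray(range_m, dtype=float)
        if np.any(r <= 0):
            raise ValueError("range must be positive (click at phone position?)")
        return 20.0 * np.log10(r) + self.absorption_db_per_m * r


class TableTL:
    """Transmission loss interpolated from a precomputed range x depth table.

    The table is a long-format delimited text file with columns
    ``range_m, depth_m, tl_db`` covering a regular (range, depth) grid, as one
    would export from a ray-traced propagation run.  Bilinear interpolation
    inside the grid; nearest-edge values outside it.  Depth refers to the
    source depth; the receiver depth is fixed by the run that produced the
    table.
    """

    def __init__(self, ranges_m, depths_m, tl_db):
        ranges_m = np.asarray(ranges_m, dtype=float)
        depths_m = np.asarray(depths_m, dtype=float)
        tl_db = np.asarray(tl_db, dtype=float)
        if tl_db.shape != (ranges_m.size, depths_m.size):
            raise ValueError("tl_db must have shape (n_ranges, n_depths)")
        self._interp = RegularGridInterpolator(
            (ranges_m, depths_m), tl_db, bounds_error=False, fill_value=None
        )
        self.ranges_m = ranges_m
        self.depths_m = depths_m

    @classmethod
    def from_csv(cls, path, sep=","):
        import pandas as pd

        df = pd.read_csv(path, sep=sep)
        required = {"range_m", "depth_m", "tl_db"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"TL table missing columns: {sorted(missing)}")
        ranges = np.unique(df["range_m"].to_numpy(float))
        depths = np.unique(df["depth_m"].to_numpy(float))
        grid = (
            df.pivot_table(index="range_m", columns="depth_m", values="tl_db")
            .reindex(index=ranges, columns=depths)
            .to_numpy(float)
        )
        if np.any(~np.isfinite(grid)):
            raise ValueError("TL table does not cover a full regular grid")
        return cls(ranges, depths, grid)

    def __call__(self, range_m, source_depth_m, receiver_depth_m=None):
        r = np.asarray(range_m, dtype=float)
        d = np.broadcast_to(np.asarray(source_depth_m, dtype=float), r.shape)
        pts = np.column_stack([np.ravel(r), np.ravel(d)])
        out = self._interp(pts)
        return out.reshape(r.shape) if r.shape else float(out[0])


def off_axis_attenuation(theta_deg, directivity_index, cap_db=40.0):
    """Off-axis attenuation of a directional click, in dB (>= 0).

    Circular-piston beam pattern ``-20*log10|2*J1(x)/x|`` with
    ``x = ka*sin(theta)`` and the large-ka mapping ``ka = 10**(DI/20)`` from
    the directivity index.  The attenuation is capped (default 40 dB) to avoid
    the pattern's nulls going to infinity, and everything behind the animal
    (theta > 90 deg) is assigned the cap.  ``directivity_index == 0`` denotes
    an omnidirectional source: 0 dB at every angle.

    Parameters
    ----------
    theta_deg : array_like
        Angle between the click axis and the source-to-receiver direction,
        degrees in [0, 180].
    directivity_index : float
        On-axis gain over omnidirectional, dB; 0 means omnidirectional.
    cap_db : float
        Maximum attenuation, dB.
    """
    if directivity_index < 0:
        raise ValueError("directivity index must be >= 0")
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    if directivity_index == 0:
        return np.zeros_like(theta) if theta.shape else 0.0
    ka = 10.0 ** (directivity_index / 20.0)
    behind = theta > np.pi / 2
    x = ka * np.sin(np.clip(theta, 0.0, np.pi / 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        pattern = np.where(x == 0.0, 1.0, 2.0 * j1(np.where(x == 0.0, 1.0, x)) / np.where(x == 0.0, 1.0, x))
        att = -20.0 * np.log10(np.abs(pattern))
    att = np.where(np.isfinite(att), att, cap_db)
    att = np.minimum(att, cap_db)
    att = np.where(behind, cap_db, att)
    return att if att.shape else float(att)
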