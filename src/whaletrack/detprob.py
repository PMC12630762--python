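"""Monte Carlo model of the probability that a click is detected on both
4-hydrophone arrays, binned over the modelled area.

One iteration places ``n_whales`` echolocating whales uniformly over the area
with random azimuth, assigns every whale that iteration's source level and
directivity, computes the received level at each array (source level minus
transmission loss minus off-axis beam attenuation) and counts a whale as
detected iff the received level meets the threshold on *both* arrays.  The
area is divided into square bins and the per-bin probability is detected
count over total count.  The full model runs a grid of (source level x
directivity x replicate) iterations — 3 x 3 x 15 = 135 by default — and the
final per-bin probability is the mean over iterations; across deployments,
the mean is weighted by deployment duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acoustics import SphericalSpreadingTL, off_axis_attenuation
from .scene import Bathymetry, Environment

__all__ = [
    "SimConfig",
    "ProbabilityGrid",
    "run_iteration",
    "run_model",
    "aggregate",
    "off_axis_attenuation",
]


@dataclass
class SimConfig:
    """Parameters of the detection-probability simulation (defaults follow the
    modelled study setup: 10,000 whales over an 8 x 8 km area in 100 m bins,
    source level 221-223 dB pp, directivity index 23-25 dB, 112 dB pp
    threshold on both arrays, 135 iterations)."""

    n_whales: int = 10_000
    area: tuple[float, float] = (8000.0, 8000.0)
    bin_size: float = 100.0
    source_level_range: tuple[float, float] = (221.0, 223.0)
    directivity_range: tuple[float, float] = (23.0, 25.0)
    threshold_db: float = 112.0
    n_sl_values: int = 3
    n_di_values: int = 3
    n_replicates: int = 15
    depth_placement: tuple = ("uniform_altitude", 50.0, 250.0)
    pitch: tuple = ("fixed", 0.0)

    def __post_init__(self):
        if self.n_whales <= 0:
            raise ValueError("n_whales must be positive")
        for span in self.area:
            if abs(span / self.bin_size - round(span / self.bin_size)) > 1e-9:
                raise ValueError("area must be divisible by bin_size")
        for rng in (self.source_level_range, self.directivity_range):
            if rng[0] > rng[1]:
                raise ValueError("ranges must be ordered (lo, hi)")

    @property
    def n_iterations(self) -> int:
        return self.n_sl_values * self.n_di_values * self.n_replicates

    def iteration_params(self):
        """The (source_level, directivity) assignment of each iteration: a
        grid of evenly spaced levels crossed with replicate seeds."""
        sls = np.linspace(*self.source_level_range, self.n_sl_values)
        dis = np.linspace(*self.directivity_range, self.n_di_values)
        return [(float(sl), float(di))
                for _ in range(self.n_replicates) for sl in sls for di in dis]


@dataclass
class ProbabilityGrid:
    """Detected/total counts and probability on a regular 2D bin grid."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    detected: np.ndarray
    total: np.ndarray
    probability_override: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.x_edges = np.asarray(self.x_edges, float)
        self.y_edges = np.asarray(self.y_edges, float)
        self.detected = np.asarray(self.detected, float)
        self.total = np.asarray(self.total, float)

    @property
    def shape(self):
        return self.detected.shape

    @property
    def probability(self) -> np.ndarray:
        """Per-bin probability: detected / total where total > 0, NaN in
        unoccupied bins (or the stored aggregate probability)."""
        if self.probability_override is not None:
            return self.probability_override
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.detected / self.total, np.nan)

    def same_binning(self, other: "ProbabilityGrid") -> bool:
        return (self.x_edges.shape == other.x_edges.shape
                and np.allclose(self.x_edges, other.x_edges)
                and np.allclose(self.y_edges, other.y_edges))


def _draw_depths(cfg: SimConfig, x, y, bathymetry, rng):
    kind = cfg.depth_placement[0]
    if kind == "fixed_depth":
        return np.full_like(x, float(cfg.depth_placement[1]))
    if kind == "uniform_altitude":
        lo, hi = cfg.depth_placement[1:3]
        floor = bathymetry.depth_at(x, y)
        return floor - rng.uniform(lo, hi, size=x.shape)
    raise ValueError(f"unknown depth placement: {kind!r}")


def _draw_pitch(cfg: SimConfig, n, rng):
    kind = cfg.pitch[0]
    if kind == "fixed":
        return np.full(n, float(cfg.pitch[1]))
    if kind == "uniform":
        return rng.uniform(cfg.pitch[1], cfg.pitch[2], size=n)
    raise ValueError(f"unknown pitch spec: {cfg.pitch[0]!r}")


def _received_levels(positions, axes, array, env, tl_model, source_level, directivity):
    offset = array.origin[None, :] - positions
    r = np.linalg.norm(offset, axis=1)
    if np.any(r == 0):
        raise ValueError("simulated whale exactly at an array position")
    cos_t = np.einsum("ij,ij->i", axes, offset) / r
    theta = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    tl = np.asarray(tl_model(r, positions[:, 2], array.origin[2]), float)
    return source_level - tl - off_axis_attenuation(theta, directivity)


def run_iteration(config: SimConfig, arrays, bathymetry: Bathymetry,
                  env: Environment, tl_model=None, seed: int = 0,
                  source_level: float | None = None,
                  directivity: float | None = None) -> ProbabilityGrid:
    """One Monte Carlo iteration: place whales, propagate, bin.

    ``source_level``/``directivity`` fix the iteration's parameter assignment;
    if omitted they are drawn uniformly from the configured ranges.  The area
    is centred on the origin of the scene frame (the midpoint between the two
    arrays).
    """
    cfg = config
    rng = np.random.default_rng(seed)
    wx, wy = cfg.area
    for arr in arrays:
        if abs(arr.origin[0]) > wx / 2 or abs(arr.origin[1]) > wy / 2:
            raise ValueError("arrays must lie inside the modelled area")
    if tl_model is None:
        tl_model = SphericalSpreadingTL(env.absorption_db_per_m)
    if source_level is None:
        source_level = float(rng.uniform(*cfg.source_level_range))
    if directivity is None:
        directivity = float(rng.uniform(*cfg.directivity_range))

    n = cfg.n_whales
    x = rng.uniform(-wx / 2, wx / 2, size=n)
    y = rng.uniform(-wy / 2, wy / 2, size=n)
    depth = _draw_depths(cfg, x, y, bathymetry, rng)
    azimuth = rng.uniform(0.0, 360.0, size=n)
    pitch = _draw_pitch(cfg, n, rng)
    az, pi_ = np.radians(azimuth), np.radians(pitch)
    axes = np.column_stack([
        np.cos(pi_) * np.sin(az),      # east
        np.cos(pi_) * np.cos(az),      # north
        -np.sin(pi_),                  # depth positive down
    ])
    positions = np.column_stack([x, y, depth])

    detected = np.ones(n, dtype=bool)
    for arr in arrays:
        rl = _received_levels(positions, axes, arr, env, tl_model,
                              source_level, directivity)
        detected &= rl >= cfg.threshold_db

    x_edges = np.arange(-wx / 2, wx / 2 + cfg.bin_size / 2, cfg.bin_size)
    y_edges = np.arange(-wy / 2, wy / 2 + cfg.bin_size / 2, cfg.bin_size)
    total, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
    det, _, _ = np.histogram2d(x[detected], y[detected], bins=(x_edges, y_edges))
    return ProbabilityGrid(x_edges=x_edges, y_edges=y_edges, detected=det, total=total)


def run_model(config: SimConfig, arrays, bathymetry, env, tl_model=None,
              seed: int = 0) -> list[ProbabilityGrid]:
    """Run the full iteration grid (source level x directivity x replicate),
    one seeded iteration each, and return the per-iteration grids."""
    seeds = np.random.SeedSequence(seed).generate_state(config.n_iterations)
    return [
        run_iteration(config, arrays, bathymetry, env, tl_model,
                      seed=int(s), source_level=sl, directivity=di)
        for s, (sl, di) in zip(seeds, config.iteration_params())
    ]


def aggregate(grids, weights=None, normalize: bool = False) -> ProbabilityGrid:
    """Weighted mean of per-bin probabilities over grids.

    With equal (or no) weights this is the plain mean over model iterations;
    passing deployment durations as ``weights`` gives the deployment-weighted
    site map.  Bins empty in an iteration are ignored in that iteration's
    contribution (NaN-aware mean).  ``normalize`` rescales the result so the
    maximum bin equals 1.
    """
    grids = list(grids)
    if not grids:
        raise ValueError("no grids to aggregate")
    first = grids[0]
    for g in grids[1:]:
        if not first.same_binning(g):
            raise ValueError("mismatched bin edges")
    if weights is None:
        weights = np.ones(len(grids))
    weights = np.asarray(weights, dtype=float)
    probs = np.stack([g.probability for g in grids])
    mask = np.isfinite(probs)
    w = weights[:, None, None] * mask
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(w.sum(axis=0) > 0,
                     np.nansum(probs * w, axis=0) / w.sum(axis=0), np.nan)
    if normalize:
        peak = np.nanmax(p)
        if peak > 0:
            p = p / peak
    total = np.sum([g.total for g in grids], axis=0)
    detected = np.sum([g.detected for g in grids], axis=0)
    return ProbabilityGrid(x_edges=first.x_edges, y_edges=first.y_edges,
                           detected=detected, total=total,
                           probability_override=p)
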