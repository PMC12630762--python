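"""Synthetic scenes: bathymetry, array geometry, dive trajectories, click
emission, propagation/detection, and optional click waveforms.

Everything lives in a local Cartesian east/north frame in metres whose origin
is the midpoint between the two seafloor arrays.  The third coordinate of every
stored position is **depth, positive down**; "altitude" always means local
seafloor depth minus whale depth.  Direction (unit) vectors use the same frame,
so a vector pointing up has a negative third component.

All stochastic operations take an explicit integer seed and are reproducible
bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acoustics import SphericalSpreadingTL, off_axis_attenuation

__all__ = [
    "PAIR_ORDER",
    "Bathymetry",
    "ArrayGeometry",
    "Environment",
    "DiveConfig",
    "DiveTrajectory",
    "ClickEvent",
    "ReceiverDetection",
    "generate_bathymetry",
    "simulate_dive",
    "emit_clicks",
    "propagate_and_detect",
    "synthesize_click_waveform",
    "true_tdoas",
]

# Fixed hydrophone-pair order for all six TDOAs: (1,2),(1,3),(1,4),(2,3),(2,4),(3,4)
# (0-based indices below).  The TDOA sign convention throughout the package is
# tau_ij = t_i - t_j (arrival at phone i minus arrival at phone j).
PAIR_ORDER: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


# ---------------------------------------------------------------------------
# bathymetry


@dataclass
class Bathymetry:
    """Regular seafloor-depth grid (metres, positive down).

    ``depth`` has shape ``(ny, nx)`` with ``depth[j, i]`` at ``(x[i], y[j])``.
    """

    x: np.ndarray
    y: np.ndarray
    depth: np.ndarray
    cell_size: float

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        for ax in (self.x, self.y):
            if ax.size < 2 or np.any(np.diff(ax) <= 0):
                raise ValueError("bathymetry axes must be monotone with >= 2 nodes")
        if self.depth.shape != (self.y.size, self.x.size):
            raise ValueError("depth grid shape does not match axes")
        if np.any(self.depth <= 0):
            raise ValueError("all depths must be > 0 (positive down)")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return float(self.x[0]), float(self.x[-1]), float(self.y[0]), float(self.y[-1])

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (
            (x >= self.x[0]) & (x <= self.x[-1]) & (y >= self.y[0]) & (y <= self.y[-1])
        )

    def depth_at(self, x, y, interpolate: bool = False):
        """Seafloor depth at (x, y): nearest grid node by default, bilinear if
        ``interpolate``.  Raises for points outside the grid extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(self.contains(x, y)):
            raise ValueError("point outside bathymetry extent")
        if interpolate:
            from scipy.interpolate import RegularGridInterpolator

            f = RegularGridInterpolator((self.y, self.x), self.depth)
            out = f(np.column_stack([np.ravel(y), np.ravel(x)]))
            return out.reshape(x.shape) if x.shape else float(out[0])
        ix = np.abs(self.x[None, :] - np.ravel(x)[:, None]).argmin(axis=1)
        iy = np.abs(self.y[None, :] - np.ravel(y)[:, None]).argmin(axis=1)
        out = self.depth[iy, ix]
        return out.reshape(x.shape) if x.shape else float(out[0])


def _extent_bounds(extent):
    extent = np.asarray(extent, dtype=float).ravel()
    if extent.size == 2:  # (width, height) centred on the origin
        return -extent[0] / 2, extent[0] / 2, -extent[1] / 2, extent[1] / 2
    if extent.size == 4:
        return tuple(extent)
    raise ValueError("extent must be (width, height) or (xmin, xmax, ymin, ymax)")


def generate_bathymetry(kind: str, params: dict, extent, cell_size: float) -> Bathymetry:
    """Analytic seafloor surfaces: ``flat``, ``slope`` or ``canyon``.

    ``flat``: params ``{"depth"}``.
    ``slope``: ``{"base_depth", "gradient_x"[, "gradient_y"]}`` — depth
    increases linearly eastward (and optionally northward) from the grid
    centre.
    ``canyon``: ``{"base_depth", "excess", "width_sigma"[, "axis_y"]}`` — a
    Gaussian channel of extra depth running east-west at ``axis_y``.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    xmin, xmax, ymin, ymax = _extent_bounds(extent)
    if xmax - xmin < cell_size or ymax - ymin < cell_size:
        raise ValueError("extent smaller than one cell")
    x = np.arange(xmin, xmax + cell_size / 2, cell_size)
    y = np.arange(ymin, ymax + cell_size / 2, cell_size)
    xx, yy = np.meshgrid(x, y)
    if kind == "flat":
        depth = np.full_like(xx, float(params["depth"]))
    elif kind == "slope":
        base = float(params["base_depth"])
        gx = float(params.get("gradient_x", 0.0))
        gy = float(params.get("gradient_y", 0.0))
        x0, y0 = (xmin + xmax) / 2, (ymin + ymax) / 2
        depth = base + gx * (xx - x0) + gy * (yy - y0)
    elif kind == "canyon":
        base = float(params["base_depth"])
        excess = float(params["excess"])
        sigma = float(params["width_sigma"])
        axis_y = float(params.get("axis_y", 0.0))
        depth = base + excess * np.exp(-((yy - axis_y) ** 2) / (2 * sigma**2))
    else:
        raise ValueError(f"unknown bathymetry kind: {kind!r}")
    return Bathymetry(x=x, y=y, depth=depth, cell_size=float(cell_size))


# ---------------------------------------------------------------------------
# arrays and environment


@dataclass
class ArrayGeometry:
    """One 4-hydrophone small-aperture array.

    ``origin`` is the array reference point (east, north, depth); the four
    ``phone_offsets`` are metres relative to it and must not be coplanar.
    """

    array_id: str
    origin: np.ndarray
    phone_offsets: np.ndarray
    altitude_above_seafloor: float = 6.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.phone_offsets = np.asarray(self.phone_offsets, dtype=float)
        if self.phone_offsets.shape != (4, 3):
            raise ValueError("exactly 4 phone offsets of dimension 3 required")
        rel = self.phone_offsets - self.phone_offsets[0]
        if np.linalg.matrix_rank(rel[1:], tol=1e-9) < 3:
            raise ValueError("hydrophones must not be coplanar")

    @property
    def phone_positions(self) -> np.ndarray:
        return self.origin[None, :] + self.phone_offsets

    @property
    def aperture(self) -> float:
        """Largest inter-phone separation, metres."""
        p = self.phone_offsets
        return float(
            max(np.linalg.norm(p[i] - p[j]) for i, j in PAIR_ORDER)
        )

    @classmethod
    def regular_tetrahedron(cls, array_id: str, origin, edge: float = 1.0,
                            altitude_above_seafloor: float = 6.0) -> "ArrayGeometry":
        """Regular tetrahedron with a horizontal base (three phones in a
        horizontal plane, apex above the base centroid), edge length ``edge``.
        The origin sits at the base centroid."""
        r = edge / np.sqrt(3.0)  # base circumradius
        h = edge * np.sqrt(2.0 / 3.0)
        ang = np.radians([90.0, 210.0, 330.0])
        offsets = np.zeros((4, 3))
        offsets[:3, 0] = r * np.cos(ang)
        offsets[:3, 1] = r * np.sin(ang)
        offsets[3] = (0.0, 0.0, -h)  # apex is shallower (depth positive down)
        return cls(array_id=array_id, origin=origin, phone_offsets=offsets,
                   altitude_above_seafloor=altitude_above_seafloor)


def default_array_pair(separation: float = 1000.0, seafloor_depth: float = 1300.0,
                       edge: float = 1.0, altitude: float = 6.0):
    """Two tetrahedral arrays ``separation`` metres apart (east-west), sitting
    ``altitude`` metres above a seafloor of the given depth, origin midway."""
    z = seafloor_depth - altitude
    a = ArrayGeometry.regular_tetrahedron("A", (-separation / 2, 0.0, z), edge, altitude)
    b = ArrayGeometry.regular_tetrahedron("B", (separation / 2, 0.0, z), edge, altitude)
    return a, b


@dataclass
class Environment:
    """Acoustic environment: scalar sound speed (m/s), linear absorption
    (dB/m) and the receiver sample rate (Hz)."""

    sound_speed: float = 1500.0
    absorption_db_per_m: float = 0.01
    sample_rate: float = 100_000.0

    def __post_init__(self):
        if not (1400.0 <= self.sound_speed <= 1600.0):
            raise ValueError("sound_speed must be within [1400, 1600] m/s")
        if self.absorption_db_per_m < 0:
            raise ValueError("absorption must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


# ---------------------------------------------------------------------------
# dive simulation


@dataclass
class DiveConfig:
    """Parameters of one simulated deep foraging dive.

    The whale descends from the surface on a fixed heading at
    ``descent_angle_deg`` (negative below horizontal) until it enters the
    configured altitude band above the seafloor, then forages in a correlated
    random walk constrained to that band.  Echolocation starts below
    ``click_start_depth`` (deep dives only).
    """

    start_xy: tuple[float, float] = (0.0, 0.0)
    heading_deg: float = 90.0           # compass: 0 = north, 90 = east
    descent_angle_deg: float = -68.8
    descent_speed: float = 1.5          # m/s along-path
    at_depth_speed: float = 1.0
    duration_s: float = 3600.0
    dt: float = 1.0
    altitude_band: tuple[float, float] = (50.0, 200.0)
    click_start_depth: float = 400.0
    heading_sigma_deg: float = 12.0     # per-step heading jitter at depth
    angle_sigma_deg: float = 0.0        # per-step descent-angle jitter
    vertical_sigma: float = 0.3         # m per step, altitude random walk at depth


@dataclass
class DiveTrajectory:
    """Time-stamped 3D positions of one whale with its echolocation state."""

    whale_id: str
    times: np.ndarray
    positions: np.ndarray               # (n, 3): east, north, depth (+down)
    echolocating: np.ndarray            # (n,) bool
    descent_angle_param: float
    speed_param: float
    n_descent: int = 0                  # truth: number of descent-phase samples

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.echolocating = np.asarray(self.echolocating, dtype=bool)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.positions[:, 2] < 0):
            raise ValueError("depth must be >= 0")

    @property
    def echolocation_duration(self) -> float:
        """Total time (s) spent with the echolocation flag on."""
        if not self.echolocating.any():
            return 0.0
        dt = np.diff(self.times)
        return float(dt[self.echolocating[:-1]].sum())


def _heading_unit(heading_deg: float) -> np.ndarray:
    h = np.radians(heading_deg)
    return np.array([np.sin(h), np.cos(h)])  # east, north


def simulate_dive(config: DiveConfig, bathymetry: Bathymetry, seed: int,
                  whale_id: str = "w0") -> DiveTrajectory:
    """Simulate one deep dive.

    Descent is a straight line at ``descent_angle_deg`` (exactly straight when
    ``angle_sigma_deg == 0``); once the whale is within the altitude band it
    switches, irreversibly, to a correlated random walk that reflects off the
    band's edges.  Output is identical for identical seed.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    lo, hi = cfg.altitude_band
    if not (0 <= lo < hi):
        raise ValueError("altitude band must satisfy 0 <= lo < hi")
    n = int(np.floor(cfg.duration_s / cfg.dt)) + 1
    times = np.arange(n) * cfg.dt
    pos = np.zeros((n, 3))
    pos[0, :2] = cfg.start_xy
    if not bathymetry.contains(*cfg.start_xy):
        raise ValueError("dive start point outside bathymetry extent")

    heading = cfg.heading_deg
    at_depth = False
    clipped = False
    for k in range(1, n):
        x, y, d = pos[k - 1]
        floor = bathymetry.depth_at(x, y)
        if not at_depth and floor - d <= hi:
            at_depth = True
        if not at_depth:
            ang = cfg.descent_angle_deg
            if cfg.angle_sigma_deg > 0:
                ang = ang + rng.normal(0.0, cfg.angle_sigma_deg)
            a = np.radians(ang)
            step = cfg.descent_speed * cfg.dt
            horiz = step * np.cos(a) * _heading_unit(heading)
            dd = -step * np.sin(a)  # ang negative => depth increases
            new = np.array([x + horiz[0], y + horiz[1], d + dd])
        else:
            heading = heading + rng.normal(0.0, cfg.heading_sigma_deg)
            step = cfg.at_depth_speed * cfg.dt
            horiz = step * _heading_unit(heading)
            alt = floor - d
            alt_new = alt + rng.normal(0.0, cfg.vertical_sigma)
            # reflect into the band
            if alt_new < lo:
                alt_new = lo + (lo - alt_new)
            if alt_new > hi:
                alt_new = hi - (alt_new - hi)
            alt_new = float(np.clip(alt_new, lo, hi))
            xn, yn = x + horiz[0], y + horiz[1]
            if not bathymetry.contains(xn, yn):
                heading += 180.0  # bounce off the grid edge
                xn, yn = x - horiz[0], y - horiz[1]
            new = np.array([xn, yn, bathymetry.depth_at(xn, yn) - alt_new])
        floor_new = bathymetry.depth_at(new[0], new[1])
        if new[2] > floor_new:
            new[2] = floor_new
            clipped = True
        if new[2] < 0:
            new[2] = 0.0
        pos[k] = new
    if clipped:
        warnings.warn("trajectory clipped at the seafloor", stacklevel=2)

    floor_all = bathymetry.depth_at(pos[:, 0], pos[:, 1])
    altitudes = floor_all - pos[:, 2]
    switch = np.nonzero(altitudes <= hi)[0]
    n_descent = int(switch[0]) if switch.size else n
    echolocating = pos[:, 2] >= cfg.click_start_depth
    return DiveTrajectory(
        whale_id=whale_id, times=times, positions=pos, echolocating=echolocating,
        descent_angle_param=cfg.descent_angle_deg, speed_param=cfg.descent_speed,
        n_descent=n_descent,
    )


# ---------------------------------------------------------------------------
# click emission


@dataclass
class ClickEvent:
    whale_id: str
    emit_time: float
    position: np.ndarray        # (3,) east, north, depth
    axis_direction: np.ndarray  # (3,) unit vector along instantaneous velocity
    source_level: float         # dB pp re 1 uPa @ 1 m
    directivity_index: float    # dB


def emit_clicks(trajectory: DiveTrajectory, inter_click_interval: float, seed: int,
                jitter_frac: float = 0.0,
                source_level_range: tuple[float, float] = (221.0, 223.0),
                directivity_range: tuple[float, float] = (23.0, 25.0)) -> list[ClickEvent]:
    """Regular echolocation clicks while the whale's echolocation flag is on.

    Click times advance by ICI * (1 + jitter_frac * U(-1, 1)); position and
    axis come from linear interpolation of the trajectory, the axis following
    the instantaneous velocity.  Source level and directivity are drawn
    uniformly per click from the configured ranges.  A trajectory that never
    echolocates yields an empty list.
    """
    if inter_click_interval <= 0:
        raise ValueError("inter_click_interval must be > 0")
    rng = np.random.default_rng(seed)
    t = trajectory.times
    p = trajectory.positions
    on = trajectory.echolocating
    if not on.any():
        return []
    # segment velocities (per sample interval)
    dt = np.diff(t)
    vel = np.diff(p, axis=0) / dt[:, None]

    clicks: list[ClickEvent] = []
    tc = float(t[np.argmax(on)])
    t_end = float(t[-1])
    while tc <= t_end:
        k = int(np.searchsorted(t, tc, side="right") - 1)
        k = min(k, len(t) - 2)
        if on[k]:
            frac = (tc - t[k]) / dt[k]
            position = p[k] + frac * (p[k + 1] - p[k])
            v = vel[k]
            nv = np.linalg.norm(v)
            axis = v / nv if nv > 0 else np.array([1.0, 0.0, 0.0])
            clicks.append(ClickEvent(
                whale_id=trajectory.whale_id, emit_time=tc, position=position,
                axis_direction=axis,
                source_level=float(rng.uniform(*source_level_range)),
                directivity_index=float(rng.uniform(*directivity_range)),
            ))
        step = inter_click_interval
        if jitter_frac > 0:
            step *= 1.0 + jitter_frac * rng.uniform(-1.0, 1.0)
        tc += step
    return clicks


# ---------------------------------------------------------------------------
# propagation and detection


@dataclass
class ReceiverDetection:
    """One click as received by one 4-hydrophone array."""

    array_id: str
    whale_id: str | None        # truth label; None for real data
    arrival_time: float         # s, at the array reference point
    received_level: float       # dB pp re 1 uPa
    tdoas: np.ndarray           # six values, PAIR_ORDER, tau_ij = t_i - t_j

    def __post_init__(self):
        self.tdoas = np.asarray(self.tdoas, dtype=float).reshape(6)


def true_tdoas(position, geometry: ArrayGeometry, sound_speed: float) -> np.ndarray:
    """Exact spherical-wavefront TDOAs (s) of a source at ``position`` across
    the six phone pairs, sign convention tau_ij = t_i - t_j."""
    p = np.asarray(position, float).reshape(3)
    tt = np.linalg.norm(geometry.phone_positions - p[None, :], axis=1) / sound_speed
    return np.array([tt[i] - tt[j] for i, j in PAIR_ORDER])


def propagate_and_detect(clicks, arrays, env: Environment, tl_model=None,
                         threshold_db: float = 112.0, tdoa_jitter_s: float = 5e-6,
                         seed: int | None = None) -> list[ReceiverDetection]:
    """Propagate clicks to each array and keep those at or above threshold.

    RL = SL - TL(range) - off-axis attenuation(theta, DI); a click is kept for
    an array iff RL >= ``threshold_db`` (112 dB pp by default).  Arrival time
    is emit time plus slant range over sound speed; TDOAs are the exact
    geometric values plus i.i.d. Gaussian jitter of sigma ``tdoa_jitter_s``
    (set 0 for noiseless).
    """
    if tl_model is None:
        tl_model = SphericalSpreadingTL(env.absorption_db_per_m)
    rng = np.random.default_rng(seed)
    out: list[ReceiverDetection] = []
    for click in clicks:
        for arr in arrays:
            offset = arr.origin - click.position
            r = float(np.linalg.norm(offset))
            if r == 0.0:
                raise ValueError("click exactly at the array reference point")
            cos_t = float(np.dot(click.axis_direction, offset) / r)
            theta = float(np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0))))
            rl = (click.source_level
                  - float(tl_model(r, click.position[2], arr.origin[2]))
                  - float(off_axis_attenuation(theta, click.directivity_index)))
            if rl < threshold_db:
                continue
            tdoas = true_tdoas(click.position, arr, env.sound_speed)
            if tdoa_jitter_s > 0:
                tdoas = tdoas + rng.normal(0.0, tdoa_jitter_s, size=6)
            out.append(ReceiverDetection(
                array_id=arr.array_id, whale_id=click.whale_id,
                arrival_time=click.emit_time + r / env.sound_speed,
                received_level=rl, tdoas=tdoas,
            ))
    return out


# ---------------------------------------------------------------------------
# waveform synthesis


def synthesize_click_waveform(detection: ReceiverDetection, env: Environment,
                              duration_samples: int = 256,
                              center_freq: float = 40_000.0,
                              envelope_sigma_s: float = 40e-6,
                              snr_db: float | None = None,
                              seed: int | None = None) -> np.ndarray:
    """Four-channel snippet containing one click at each channel's true offset.

    The click is a Gaussian-windowed tone (default 40 kHz, sigma 40 us, which
    keeps essentially all energy in the 20-60 kHz band).  Each channel's click
    centre is displaced by that phone's arrival-time offset, reconstructed
    from the detection's TDOAs relative to phone 1, so sub-sample shifts are
    represented exactly.  Amplitude scales with received level; optional white
    noise at ``snr_db`` (peak signal over noise sigma).
    """
    fs = env.sample_rate
    tau = detection.tdoas
    # per-phone arrival offsets relative to phone 1: t_j - t_1 = -tau_1j
    rel = np.array([0.0, -tau[0], -tau[1], -tau[2]])
    rel = rel - rel.mean()
    if duration_samples / fs < 10 * envelope_sigma_s:
        raise ValueError("window shorter than the click envelope")
    t = (np.arange(duration_samples) - duration_samples / 2) / fs
    amp = 10.0 ** (detection.received_level / 20.0)
    wave = np.zeros((4, duration_samples))
    for ch in range(4):
        tt = t - rel[ch]
        wave[ch] = amp * np.exp(-(tt**2) / (2 * envelope_sigma_s**2)) * np.sin(
            2 * np.pi * center_freq * tt
        )
    if snr_db is not None and np.isfinite(snr_db):
        rng = np.random.default_rng(seed)
        wave = wave + rng.normal(0.0, amp * 10.0 ** (-snr_db / 20.0), size=wave.shape)
    return wave
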