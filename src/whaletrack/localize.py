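"""TDOA measurement, DOA inversion, cross-array association, two-ray
cross-fixes with jackknife confidence intervals, track smoothing, and array
self-calibration.

Conventions (documented once, used everywhere):

* the six hydrophone pairs are ordered (1,2),(1,3),(1,4),(2,3),(2,4),(3,4);
* the TDOA sign is ``tau_ij = t_i - t_j``;
* under a plane-wave arrival from unit direction ``u`` (array -> source),
  ``tau_ij = -(p_i - p_j) . u / c``;
* positions and unit vectors use the east/north/depth(+down) frame of
  :mod:`whaletrack.scene`; elevation is positive upward, azimuth is compass
  degrees (0 = north, 90 = east) in [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.stats import t as student_t

from .scene import PAIR_ORDER, ArrayGeometry

__all__ = [
    "TDOASet",
    "DOAEstimate",
    "TrackPoint",
    "Track",
    "measure_tdoa",
    "estimate_doa",
    "associate_click_trains",
    "cross_fix",
    "jackknife_ci",
    "smooth_track",
    "calibrate_receivers",
    "baseline_matrix",
    "plane_wave_tdoas",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class TDOASet:
    """Six TDOAs of one click at one array, with per-pair validity flags."""

    array_id: str
    click_time: float
    tdoas: np.ndarray
    valid: np.ndarray = None

    def __post_init__(self):
        self.tdoas = np.asarray(self.tdoas, dtype=float).reshape(6)
        if self.valid is None:
            self.valid = np.ones(6, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool).reshape(6)

    @property
    def closure_residual(self) -> float:
        """Three-term closure tau_12 + tau_23 - tau_13 (exactly 0 for
        jitter-free TDOAs)."""
        t = self.tdoas
        return float(t[0] + t[3] - t[1])


@dataclass
class DOAEstimate:
    """Unit direction from one array toward the source for one click."""

    array_id: str
    click_time: float
    unit_vector: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self):
        self.unit_vector = np.asarray(self.unit_vector, dtype=float).reshape(3)

    @property
    def azimuth(self) -> float:
        u = self.unit_vector
        return float(np.degrees(np.arctan2(u[0], u[1])) % 360.0)

    @property
    def elevation(self) -> float:
        # depth is positive down, so upward elevation flips the sign
        return float(np.degrees(np.arcsin(np.clip(-self.unit_vector[2], -1.0, 1.0))))


@dataclass
class TrackPoint:
    time: float
    position: np.ndarray
    ci95: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n_jackknife: int = 0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.ci95 = np.asarray(self.ci95, dtype=float).reshape(3)


@dataclass
class Track:
    """A sequence of cross-fixed 3D positions for one individual."""

    whale_id: str
    times: np.ndarray
    positions: np.ndarray
    ci95: np.ndarray = None
    smoothed_positions: np.ndarray = None
    source_arrays: frozenset = frozenset()

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.ci95 is None:
            self.ci95 = np.zeros_like(self.positions)
        self.ci95 = np.asarray(self.ci95, dtype=float).reshape(-1, 3)
        if self.smoothed_positions is not None:
            self.smoothed_positions = np.asarray(self.smoothed_positions, float).reshape(-1, 3)
            if len(self.smoothed_positions) != len(self.positions):
                raise ValueError("smoothed and raw sequences must be the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("track times must be strictly increasing")

    def __len__(self):
        return len(self.times)

    @property
    def best_positions(self) -> np.ndarray:
        return self.smoothed_positions if self.smoothed_positions is not None else self.positions

    @property
    def points(self) -> list[TrackPoint]:
        return [TrackPoint(t, p, c) for t, p, c in zip(self.times, self.positions, self.ci95)]


# ---------------------------------------------------------------------------
# TDOA measurement from waveforms


def _xcorr_lag(a: np.ndarray, b: np.ndarray, upsample: int = 16) -> float:
    """Lag (samples, possibly fractional) maximizing the cross-correlation of
    a and b, in the tau = t_a - t_b sense, in units of one sample.

    The correlation is band-limited-upsampled (FFT resampling) before the
    parabolic sub-sample refinement; for narrowband clicks this also resolves
    the carrier-cycle ambiguity, since the true continuous peak is the global
    maximum of the interpolated correlation.
    """
    c = signal.correlate(a, b, mode="full")
    if not np.any(c):
        raise ValueError("flat/zero signal: no correlation peak")
    fine = signal.resample(c, len(c) * upsample)
    k = int(np.argmax(fine))
    pos = k / upsample
    if 0 < k < len(fine) - 1:
        y0, y1, y2 = fine[k - 1], fine[k], fine[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            pos += 0.5 * (y0 - y2) / denom / upsample
    return float(pos - (len(b) - 1))


def measure_tdoa(window: np.ndarray, sample_rate: float,
                 highpass_cutoff: float = 20_000.0,
                 array_id: str = "", click_time: float = 0.0) -> TDOASet:
    """Measure the six pairwise TDOAs from a 4-channel click window.

    Channels are high-pass filtered (4th-order Butterworth, zero phase,
    default cutoff 20 kHz) and cross-correlated per pair; the peak lag gets
    parabolic sub-sample interpolation.  The window must be at least 50 us of
    samples.  Filtering is skipped for windows too short to filter stably.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[0] != 4:
        raise ValueError("window must have shape (4, n_samples)")
    n = w.shape[1]
    if n < max(2, int(round(50e-6 * sample_rate))):
        raise ValueError("window shorter than 50 us")
    if highpass_cutoff and highpass_cutoff > 0 and n > 24:
        sos = signal.butter(4, highpass_cutoff, btype="highpass", fs=sample_rate,
                            output="sos")
        w = signal.sosfiltfilt(sos, w, axis=1, padlen=min(24, n - 1))
    tdoas = np.array([_xcorr_lag(w[i], w[j]) / sample_rate for i, j in PAIR_ORDER])
    return TDOASet(array_id=array_id, click_time=click_time, tdoas=tdoas)


# ---------------------------------------------------------------------------
# DOA inversion


def baseline_matrix(geometry: ArrayGeometry) -> np.ndarray:
    """(6, 3) matrix of phone-pair baselines p_i - p_j in pair order."""
    p = geometry.phone_offsets
    return np.array([p[i] - p[j] for i, j in PAIR_ORDER])


def plane_wave_tdoas(unit_vector, geometry: ArrayGeometry, sound_speed: float) -> np.ndarray:
    """Forward model: the six TDOAs of a plane wave from direction ``u``."""
    u = np.asarray(unit_vector, dtype=float).reshape(3)
    return -(baseline_matrix(geometry) @ u) / sound_speed


def estimate_doa(tdoaset: TDOASet, geometry: ArrayGeometry, sound_speed: float) -> DOAEstimate:
    """Least-squares plane-wave DOA from a set of TDOAs.

    Solves ``B u = -c tau`` over the valid pairs and normalizes ``u``; at
    least three valid pairs spanning 3D are required.
    """
    valid = tdoaset.valid
    if valid.sum() < 3:
        raise ValueError("need at least 3 valid TDOA pairs")
    B = baseline_matrix(geometry)[valid]
    rhs = -sound_speed * tdoaset.tdoas[valid]
    sv = np.linalg.svd(B, compute_uv=False)
    if sv[-1] < 1e-9 * sv[0]:
        raise ValueError("rank-deficient geometry: phones (or valid pairs) coplanar")
    u, *_ = np.linalg.lstsq(B, rhs, rcond=None)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("degenerate TDOA set (zero direction)")
    u = u / norm
    resid = tdoaset.tdoas[valid] + (B @ u) / sound_speed
    return DOAEstimate(array_id=tdoaset.array_id, click_time=tdoaset.click_time,
                       unit_vector=u, residual_rms=float(np.sqrt(np.mean(resid**2))))


def _doa_batch(tdoas: np.ndarray, geometry: ArrayGeometry, sound_speed: float,
               drop_pair: int | None = None) -> np.ndarray:
    """Vectorized plane-wave inversion for (n, 6) TDOAs -> (n, 3) unit vectors.
    Optionally drops one pair index (jackknife subsets)."""
    B = baseline_matrix(geometry)
    tau = np.atleast_2d(tdoas)
    if drop_pair is not None:
        keep = np.ones(6, dtype=bool)
        keep[drop_pair] = False
        B = B[keep]
        tau = tau[:, keep]
    pinv = np.linalg.pinv(B)
    u = -(sound_speed * tau) @ pinv.T
    n = np.linalg.norm(u, axis=1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("degenerate TDOA set (zero direction)")
    return u / n


# ---------------------------------------------------------------------------
# click-train association


def _train_xcorr_peak(times_a, times_b, t0, t1, bin_s, max_lag, norm="overlap"):
    """(peak, lag) of the normalized cross-correlation of two binned event
    trains over the interval [t0, t1]; positive lag: b trails a.

    ``norm="overlap"`` divides by the smaller train's energy (overlap
    coefficient: a train fully contained in the other scores 1 even when the
    arrays detect very different subsets); ``norm="cosine"`` divides by the
    geometric mean of both energies.
    """
    nbins = int(np.ceil((t1 - t0) / bin_s)) + 1
    max_shift = int(np.ceil(max_lag / bin_s))

    def binned(times):
        v = np.zeros(nbins)
        idx = np.floor((np.asarray(times, float) - t0) / bin_s).astype(int)
        np.add.at(v, np.clip(idx, 0, nbins - 1), 1.0)
        return v

    a, b = binned(times_a), binned(times_b)
    shifts = np.arange(-max_shift, max_shift + 1)
    # corr(s) = sum_n a[n] * b[n + s]  -> positive s: b trails a
    full = signal.correlate(b, a, mode="full")
    center = len(a) - 1
    vals = full[center + shifts[0]: center + shifts[-1] + 1]
    ea, eb = np.sum(a**2), np.sum(b**2)
    denom = min(ea, eb) if norm == "overlap" else np.sqrt(ea * eb)
    vals = vals / denom
    k = int(np.argmax(vals))
    return float(vals[k]), float(shifts[k] * bin_s)


def associate_click_trains(trains_a: dict, trains_b: dict, max_lag: float = 2.0,
                           threshold: float = 0.5, bin_s: float = 0.02,
                           window_s: float | None = None, min_clicks: int = 10,
                           norm: str = "overlap"):
    """Pair click trains across arrays by normalized cross-correlation.

    Trains are mappings id -> sorted event times (s).  Each train is binned to
    ``bin_s`` counts, every (a, b) pair is cross-correlated over lags up to
    ``max_lag`` with cosine normalization, and pairs with peak >= ``threshold``
    are assigned one-to-one greedily by descending peak.

    With the default ``window_s=None`` the whole trains are correlated at
    once, which suits a constant lag.  For long tracks the inter-array lag
    drifts as the whale moves, smearing the global peak; setting ``window_s``
    correlates the trains in windows of that length (those holding at least
    ``min_clicks`` clicks of each train) and scores a pair by the *median*
    per-window peak, with the median per-window lag reported.

    Returns a list of ``(id_a, id_b, lag_s, peak)`` tuples; ``lag_s`` is the
    time by which train b trails train a at the correlation peak.
    """
    for trains in (trains_a, trains_b):
        for k, v in trains.items():
            if len(v) == 0:
                raise ValueError(f"empty click train: {k!r}")
    t0 = min(min(np.min(v) for v in trains_a.values()),
             min(np.min(v) for v in trains_b.values()))
    t1 = max(max(np.max(v) for v in trains_a.values()),
             max(np.max(v) for v in trains_b.values()))

    candidates = []
    for ka, a_times in trains_a.items():
        a_times = np.asarray(a_times, float)
        for kb, b_times in trains_b.items():
            b_times = np.asarray(b_times, float)
            if window_s is None:
                peak, lag = _train_xcorr_peak(a_times, b_times, t0, t1, bin_s, max_lag, norm)
            else:
                peaks, lags = [], []
                for w0 in np.arange(t0, t1, window_s):
                    aw = a_times[(a_times >= w0) & (a_times < w0 + window_s)]
                    bw = b_times[(b_times >= w0 - max_lag)
                                 & (b_times < w0 + window_s + max_lag)]
                    if len(aw) < min_clicks or len(bw) < min_clicks:
                        continue
                    p, l = _train_xcorr_peak(aw, bw, w0 - max_lag,
                                             w0 + window_s + max_lag, bin_s,
                                             max_lag, norm)
                    peaks.append(p)
                    lags.append(l)
                if not peaks:
                    continue
                peak, lag = float(np.median(peaks)), float(np.median(lags))
            candidates.append((peak, ka, kb, lag))
    candidates.sort(key=lambda c: -c[0])
    used_a, used_b, out = set(), set(), []
    for peak, ka, kb, lag in candidates:
        if peak < threshold or ka in used_a or kb in used_b:
            continue
        used_a.add(ka)
        used_b.add(kb)
        out.append((ka, kb, lag, peak))
    return out


# ---------------------------------------------------------------------------
# cross-fix and jackknife CI


def _ray_midpoint(o1, d1, o2, d2, min_angle_deg):
    """Midpoint of the mutual perpendicular between rays o + s*d, s >= 0."""
    cosang = np.clip(np.dot(d1, d2), -1.0, 1.0)
    if np.degrees(np.arccos(abs(cosang))) < min_angle_deg:
        raise ValueError("rays are (near-)parallel: no stable intersection")
    w0 = o1 - o2
    b = cosang
    d = np.dot(d1, w0)
    e = np.dot(d2, w0)
    denom = 1.0 - b * b
    s = (b * e - d) / denom
    t = (e - b * d) / denom
    if s < 0 or t < 0:
        raise ValueError("negative ray parameter: source behind an array")
    return 0.5 * ((o1 + s * d1) + (o2 + t * d2))


def cross_fix(doa_a, doa_b, origin_a, origin_b, min_angle_deg: float = 0.05) -> np.ndarray:
    """3D position from two DOA rays: midpoint of their mutual perpendicular.

    ``doa_a``/``doa_b`` may be :class:`DOAEstimate` objects or raw unit
    vectors.  Both ray parameters must be non-negative (the source must lie in
    front of both arrays), and the rays must subtend at least
    ``min_angle_deg``.
    """
    d1 = np.asarray(getattr(doa_a, "unit_vector", doa_a), float).reshape(3)
    d2 = np.asarray(getattr(doa_b, "unit_vector", doa_b), float).reshape(3)
    o1 = np.asarray(origin_a, float).reshape(3)
    o2 = np.asarray(origin_b, float).reshape(3)
    return _ray_midpoint(o1, d1 / np.linalg.norm(d1), o2, d2 / np.linalg.norm(d2),
                         min_angle_deg)


def _crossfix_batch(ua, ub, oa, ob):
    """Vectorized mutual-perpendicular midpoints for (n,3) ray directions."""
    b = np.einsum("ij,ij->i", ua, ub)
    d = ua @ (oa - ob)
    e = ub @ (oa - ob)
    denom = 1.0 - b * b
    s = (b * e - d) / denom
    t = (e - b * d) / denom
    pa = oa[None, :] + s[:, None] * ua
    pb = ob[None, :] + t[:, None] * ub
    return 0.5 * (pa + pb), s, t


def jackknife_localize_batch(tdoas_a: np.ndarray, tdoas_b: np.ndarray,
                             geometry_a: ArrayGeometry, geometry_b: ArrayGeometry,
                             sound_speed: float, confidence: float = 0.95,
                             strategy: str = "paired"):
    """Vectorized cross-fix + jackknife CIs for n clicks at once.

    Returns ``(positions (n,3), ci95 (n,3), n_subsets)``.  See
    :func:`jackknife_ci` for the statistical definition.
    """
    tdoas_a = np.atleast_2d(tdoas_a)
    tdoas_b = np.atleast_2d(tdoas_b)
    oa, ob = geometry_a.origin, geometry_b.origin
    ua = _doa_batch(tdoas_a, geometry_a, sound_speed)
    ub = _doa_batch(tdoas_b, geometry_b, sound_speed)
    pos, _, _ = _crossfix_batch(ua, ub, oa, ob)

    if strategy == "paired":
        subsets = [(k, k) for k in range(6)]
    elif strategy == "per_array":
        subsets = [(k, None) for k in range(6)] + [(None, k) for k in range(6)]
    else:
        raise ValueError(f"unknown jackknife strategy: {strategy!r}")
    reps = np.empty((len(subsets),) + pos.shape)
    for m, (ka, kb) in enumerate(subsets):
        uak = _doa_batch(tdoas_a, geometry_a, sound_speed, drop_pair=ka)
        ubk = _doa_batch(tdoas_b, geometry_b, sound_speed, drop_pair=kb)
        reps[m], _, _ = _crossfix_batch(uak, ubk, oa, ob)
    n = len(subsets)
    mean = reps.mean(axis=0)
    var = (n - 1) / n * np.sum((reps - mean) ** 2, axis=0)
    tq = student_t.ppf(0.5 + confidence / 2.0, df=n - 1)
    return pos, tq * np.sqrt(var), n


def jackknife_ci(tdoa_sets, geometry_pair, sound_speed: float,
                 confidence: float = 0.95, strategy: str = "paired") -> TrackPoint:
    """Cross-fix one click and attach jackknife confidence intervals.

    The position uses all six TDOA pairs from both arrays.  Uncertainty comes
    from leave-one-pair-out re-localizations: the default ``paired`` strategy
    drops the same pair index from both arrays (six subsets, each a
    five-of-six localization); ``per_array`` drops one pair from one array at
    a time (twelve subsets).  Per axis, the jackknife variance is
    ``(n-1)/n * sum((theta_k - theta_bar)**2)`` and the CI half-width is the
    Student-t quantile at ``confidence`` with n-1 degrees of freedom times the
    jackknife SE.
    """
    set_a, set_b = tdoa_sets
    geom_a, geom_b = geometry_pair
    if not (set_a.valid.all() and set_b.valid.all()):
        raise ValueError("jackknife requires all six TDOA pairs per array")
    pos, ci, n = jackknife_localize_batch(
        set_a.tdoas, set_b.tdoas, geom_a, geom_b, sound_speed,
        confidence=confidence, strategy=strategy)
    return TrackPoint(time=set_a.click_time, position=pos[0], ci95=ci[0], n_jackknife=n)


# ---------------------------------------------------------------------------
# smoothing


def _kalman_cv(times, positions, meas_sigma, accel_sigma, rts: bool = True):
    """Constant-velocity Kalman filter with optional RTS backward pass,
    axes independent.

    State per axis is (position, velocity); process noise is discrete white
    acceleration with standard deviation ``accel_sigma``.  The default runs
    the Rauch-Tung-Striebel smoother after the forward filter, which removes
    the forward filter's lag and roughly halves the velocity error — the
    appropriate choice for offline track analysis.
    """
    n = len(times)
    q = accel_sigma**2
    xs = np.zeros((n, 2, 3))
    Ps = np.zeros((n, 2, 2, 3))
    Fs = np.zeros((n, 2, 2))
    xp = np.zeros((n, 2, 3))
    Pp = np.zeros((n, 2, 2, 3))
    x = np.zeros((2, 3))
    x[0] = positions[0]
    P = np.zeros((2, 2, 3))
    P[0, 0] = meas_sigma[0] ** 2
    P[1, 1] = 4.0  # generous initial velocity variance (2 m/s)^2
    xs[0], Ps[0] = x, P
    for k in range(1, n):
        dt = times[k] - times[k - 1]
        F = np.array([[1.0, dt], [0.0, 1.0]])
        Fs[k] = F
        Q = q * np.array([[dt**4 / 4, dt**3 / 2], [dt**3 / 2, dt**2]])
        # predict (per axis)
        x = np.einsum("ij,ja->ia", F, x)
        P = np.einsum("ij,jka,lk->ila", F, P, F) + Q[:, :, None]
        xp[k], Pp[k] = x, P
        # update with z = positions[k]
        r = meas_sigma[k] ** 2
        S = P[0, 0] + r
        K = P[:, 0] / S  # (2, 3)
        innov = positions[k] - x[0]
        x = x + K * innov[None, :]
        P = P - np.einsum("ia,ja->ija", K, P[0])
        xs[k], Ps[k] = x.copy(), P.copy()
    if rts:
        for k in range(n - 2, -1, -1):
            F = Fs[k + 1]
            for a in range(3):
                C = Ps[k][:, :, a] @ F.T @ np.linalg.inv(Pp[k + 1][:, :, a])
                xs[k][:, a] += C @ (xs[k + 1][:, a] - xp[k + 1][:, a])
                Ps[k][:, :, a] += C @ (Ps[k + 1][:, :, a] - Pp[k + 1][:, :, a]) @ C.T
    return xs[:, 0, :]


def _moving_average(a: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average preserving length (window shrinks at the ends)."""
    import pandas as pd

    return (
        pd.DataFrame(a).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def smooth_track(track: Track, process_noise: float = 0.1, window: int = 5,
                 measurement_floor: float = 10.0, rts: bool = True) -> Track:
    """Kalman-filter then moving-average a track's positions.

    A constant-velocity Kalman filter (process acceleration noise
    ``process_noise`` m/s^2, two-pass RTS smoothing by default) uses each
    point's 95% CI as its measurement noise (converted to a 1-sigma value,
    floored at ``measurement_floor`` metres), and a centred moving average
    (default 5 points) smooths the filtered positions.  Raw positions and
    point count are preserved.
    """
    if len(track) < 3:
        raise ValueError("need at least 3 points to smooth")
    sigma = np.maximum(track.ci95 / 1.959963984540054, measurement_floor)
    sigma = np.mean(sigma, axis=1)  # shared scalar noise per point
    filtered = _kalman_cv(track.times, track.positions, sigma, process_noise, rts=rts)
    smoothed = _moving_average(filtered, window)
    return Track(whale_id=track.whale_id, times=track.times,
                 positions=track.positions, ci95=track.ci95,
                 smoothed_positions=smoothed, source_arrays=track.source_arrays)


# ---------------------------------------------------------------------------
# array self-calibration from ship noise


def calibrate_receivers(ship_positions: np.ndarray, measured_tdoas: np.ndarray,
                        initial_guess: np.ndarray, sound_speed: float = 1500.0,
                        tol: float = 1e-10):
    """Invert hydrophone positions from ship-noise TDOAs at known positions.

    For each ship position s the modelled TDOA of receiver pair (i, j) is
    ``(|s - p_i| - |s - p_j|) / c``; the receiver positions are found by
    nonlinear least squares against the measured TDOAs over all receiver
    pairs in lexicographic order.  ``initial_guess`` has shape
    ``(n_receivers, 3)``; with n receivers, ``measured_tdoas`` has shape
    ``(n_ship, n*(n-1)/2)``.  Returns ``(positions, rms_residual_s)``.

    Absolute positions are only observable when the receivers are spread
    over a baseline comparable to their distance from the ship track (e.g.
    instruments hundreds of metres apart) — for a single 1 m-aperture array
    the TDOAs degenerate to plane-wave bearings.  Raises if the ship
    positions are (near-)collinear in the horizontal plane, which leaves the
    geometry unconstrained.
    """
    from itertools import combinations

    from scipy.optimize import least_squares

    ship = np.asarray(ship_positions, dtype=float).reshape(-1, 3)
    guess = np.asarray(initial_guess, dtype=float).reshape(-1, 3)
    n_rec = len(guess)
    if n_rec < 2:
        raise ValueError("need at least 2 receivers")
    pairs = list(combinations(range(n_rec), 2))
    tdoas = np.asarray(measured_tdoas, dtype=float).reshape(len(ship), len(pairs))
    if len(ship) < 4:
        raise ValueError("need at least 4 ship positions")
    centered = ship[:, :2] - ship[:, :2].mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-6 * max(sv[0], 1.0):
        raise ValueError(
            f"ill-conditioned: ship track is collinear (singular values {sv})")

    def model(flat):
        p = flat.reshape(n_rec, 3)
        tt = np.linalg.norm(ship[:, None, :] - p[None, :, :], axis=2) / sound_speed
        return np.stack([tt[:, i] - tt[:, j] for i, j in pairs], axis=1)

    def resid(x):
        return (model(x) - tdoas).ravel()

    sol = least_squares(resid, guess.ravel(), xtol=tol, ftol=tol, gtol=tol)
    if not sol.success:
        raise RuntimeError(f"calibration did not converge: {sol.message}")
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return sol.x.reshape(n_rec, 3), rms
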