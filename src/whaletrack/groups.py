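"""Group size and coordination metrics for co-diving whales.

Two complementary proximity metrics: *pairs distance* (time-matched 3D
distance between two simultaneously tracked whales, averaged per wall-clock
minute) and *lane distance* (time-free: both tracks resampled to 1 m
arc-length spacing, each point of one matched to the nearest point of the
other, averaged over 10 m arc-length bins).  Subgroups come from
single-linkage clustering of the unweighted mean pairs distances with a
1000 m cutoff, with pairs that never temporally overlap within 10 minutes
forced apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree

from .localize import Track

__all__ = [
    "PairDistanceSeries",
    "SubgroupPartition",
    "group_size",
    "pairs_distance",
    "lane_distance",
    "closest_approach_lag",
    "find_subgroups",
    "track_density",
]

# stand-in for an infinite inter-whale distance inside scipy's linkage,
# far above any plausible cutoff in metres
_FAR = 1e15


@dataclass
class PairDistanceSeries:
    """Mean 3D distance between two whales per wall-clock minute bin."""

    id_a: str
    id_b: str
    minute_starts: np.ndarray   # s, bin left edges (multiples of 60)
    mean_m: np.ndarray

    def __post_init__(self):
        self.minute_starts = np.asarray(self.minute_starts, dtype=float)
        self.mean_m = np.asarray(self.mean_m, dtype=float)

    def __len__(self):
        return len(self.mean_m)


@dataclass
class SubgroupPartition:
    encounter_id: int
    labels: dict                       # whale_id -> subgroup label (1-based)
    linkage_matrix: np.ndarray | None = None
    ids: list = field(default_factory=list)

    @property
    def n_subgroups(self) -> int:
        return len(set(self.labels.values()))

    @property
    def mean_subgroup_size(self) -> float:
        sizes = np.bincount(list(self.labels.values()))
        sizes = sizes[sizes > 0]
        return float(sizes.mean())


# ---------------------------------------------------------------------------


def group_size(per_array_ids: dict, cross_array_pairings) -> int:
    """Number of distinct individuals across both arrays.

    ``per_array_ids`` maps array id -> set of per-array track ids;
    ``cross_array_pairings`` lists ``(id_on_A, id_on_B)`` identities (extra
    association metadata in longer tuples is ignored).  A whale seen on only
    one array still counts.  Raises if any per-array id appears in more than
    one pairing.
    """
    arrays = sorted(per_array_ids)
    if len(arrays) != 2:
        raise ValueError("expected ids for exactly two arrays")
    ids_a, ids_b = (set(per_array_ids[a]) for a in arrays)
    seen_a, seen_b = set(), set()
    merged = 0
    for pair in cross_array_pairings:
        a, b = pair[0], pair[1]
        if a in seen_a or b in seen_b:
            raise ValueError(f"inconsistent pairing: {a!r} or {b!r} paired twice")
        seen_a.add(a)
        seen_b.add(b)
        if a in ids_a and b in ids_b:
            merged += 1
    return len(ids_a) + len(ids_b) - merged


def pairs_distance(track_a: Track, track_b: Track, match_tol_s: float = 5.0,
                   bin_s: float = 60.0) -> PairDistanceSeries:
    """Per-minute mean 3D distance between two simultaneously tracked whales.

    Each point of track A is matched to the nearest-in-time point of track B
    (within ``match_tol_s``); matched distances are averaged per wall-clock
    minute.  Non-overlapping tracks give an empty series.
    """
    ta, tb = track_a.times, track_b.times
    pa, pb = track_a.best_positions, track_b.best_positions
    idx = np.searchsorted(tb, ta)
    idx = np.clip(idx, 1, len(tb) - 1) if len(tb) > 1 else np.zeros(len(ta), int)
    left = np.abs(tb[idx - 1] - ta) if len(tb) > 1 else np.full(len(ta), np.inf)
    right = np.abs(tb[idx] - ta)
    nearest = np.where(left <= right, idx - 1, idx) if len(tb) > 1 else idx
    dt = np.abs(tb[nearest] - ta)
    ok = dt <= match_tol_s
    if not ok.any():
        return PairDistanceSeries(track_a.whale_id, track_b.whale_id,
                                  np.array([]), np.array([]))
    dist = np.linalg.norm(pa[ok] - pb[nearest[ok]], axis=1)
    minute = np.floor(ta[ok] / bin_s).astype(int)
    uniq = np.unique(minute)
    means = np.array([dist[minute == m].mean() for m in uniq])
    return PairDistanceSeries(track_a.whale_id, track_b.whale_id,
                              uniq * bin_s, means)


def _resample_arclength(positions: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a polyline to uniform arc-length spacing (default 1 m)."""
    p = np.asarray(positions, dtype=float).reshape(-1, 3)
    if len(p) < 2:
        raise ValueError("need at least 2 points to resample")
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        raise ValueError("zero-length track")
    grid = np.arange(0.0, s[-1] + spacing / 2, spacing)
    return np.column_stack([np.interp(grid, s, p[:, k]) for k in range(3)])


def lane_distance(track_a: Track, track_b: Track, bin_m: float = 10.0,
                  spacing_m: float = 1.0):
    """Time-free proximity of two tracks ("lane distance").

    Both tracks (smoothed positions when available) are resampled to
    ``spacing_m`` arc-length spacing; for each resampled point of A the
    distance to the nearest point of B is taken, regardless of time, and the
    values are averaged over consecutive ``bin_m`` arc-length bins along A.
    Returns ``(bin_centers_m, mean_m)``.  Note the metric is asymmetric at the
    binning level; swap the arguments (or average both directions) for a
    symmetrized variant.
    """
    a = _resample_arclength(track_a.best_positions, spacing_m)
    b = _resample_arclength(track_b.best_positions, spacing_m)
    d, _ = cKDTree(b).query(a)
    per_bin = max(1, int(round(bin_m / spacing_m)))
    nbin = len(a) // per_bin
    if nbin == 0:
        return np.array([0.5 * per_bin * spacing_m]), np.array([d.mean()])
    trimmed = d[: nbin * per_bin].reshape(nbin, per_bin)
    centers = (np.arange(nbin) + 0.5) * per_bin * spacing_m
    return centers, trimmed.mean(axis=1)


def closest_approach_lag(track_a: Track, track_b: Track) -> float:
    """Absolute time lag (s) between the two points — one per track — that
    minimize spatial distance over all point pairs."""
    pa, pb = track_a.best_positions, track_b.best_positions
    d, j = cKDTree(pb).query(pa)
    i = int(np.argmin(d))
    return float(abs(track_a.times[i] - track_b.times[int(j[i])]))


def _pair_mean_distance(track_a, track_b, overlap_minutes):
    """Inter-whale distance for subgrouping: the unweighted mean of the
    per-minute pairs distances, infinite when the tracks do not temporally
    overlap within ``overlap_minutes``.  Tracks within the temporal-overlap
    rule but with no shared minutes (disjoint by less than the rule) fall
    back to the time-free closest-approach distance."""
    gap = max(track_a.times[0] - track_b.times[-1],
              track_b.times[0] - track_a.times[-1])
    if gap > overlap_minutes * 60.0:
        return np.inf
    series = pairs_distance(track_a, track_b)
    if len(series) == 0:
        d, _ = cKDTree(track_b.best_positions).query(track_a.best_positions)
        return float(d.min())
    return float(series.mean_m.mean())


def find_subgroups(encounter_tracks: dict, distance_cutoff: float = 1000.0,
                   overlap_minutes: float = 10.0,
                   encounter_id: int = 0) -> SubgroupPartition:
    """Single-linkage subgroups of the whales in one encounter.

    The inter-whale distance is the unweighted mean of the per-minute pairs
    distances over shared minutes; pairs that do not temporally overlap within
    ``overlap_minutes`` get an (effectively) infinite distance, which forces
    them into separate subgroups exactly as the ``distance_cutoff`` does.
    The single-linkage tree is cut at ``distance_cutoff``: merges at height
    strictly greater than the cutoff are split.
    """
    ids = sorted(encounter_tracks)
    if len(ids) < 2:
        raise ValueError("need at least 2 whales to form subgroups")
    m = len(ids)
    condensed = []
    for i in range(m):
        for j in range(i + 1, m):
            d = _pair_mean_distance(encounter_tracks[ids[i]],
                                    encounter_tracks[ids[j]], overlap_minutes)
            condensed.append(min(d, _FAR))
    Z = linkage(np.asarray(condensed), method="single")
    flat = fcluster(Z, t=distance_cutoff, criterion="distance")
    return SubgroupPartition(encounter_id=encounter_id,
                             labels=dict(zip(ids, (int(v) for v in flat))),
                             linkage_matrix=Z, ids=ids)


def track_density(tracks, bin_size: float = 10.0, extent=None):
    """2D grid counting, per bin, the number of distinct whales whose track
    enters the bin (each whale counted at most once per bin).

    ``extent`` is ``(xmin, xmax, ymin, ymax)``; by default it is taken from
    the data and padded to whole bins.  Returns ``(x_edges, y_edges, counts)``
    with ``counts[ix, iy]``.
    """
    tracks = list(tracks)
    if extent is None:
        if not tracks:
            edges = np.array([0.0, bin_size])
            return edges, edges, np.zeros((1, 1))
        allp = np.vstack([t.best_positions[:, :2] for t in tracks])
        xmin = np.floor(allp[:, 0].min() / bin_size) * bin_size
        ymin = np.floor(allp[:, 1].min() / bin_size) * bin_size
        xmax = np.ceil(allp[:, 0].max() / bin_size) * bin_size
        ymax = np.ceil(allp[:, 1].max() / bin_size) * bin_size
    else:
        xmin, xmax, ymin, ymax = extent
    x_edges = np.arange(xmin, xmax + bin_size / 2, bin_size)
    y_edges = np.arange(ymin, ymax + bin_size / 2, bin_size)
    counts = np.zeros((len(x_edges) - 1, len(y_edges) - 1))
    for t in tracks:
        p = t.best_positions
        h, _, _ = np.histogram2d(p[:, 0], p[:, 1], bins=(x_edges, y_edges))
        counts += h > 0
    return x_edges, y_edges, counts
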