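"""Group size, pair proximity metrics, subgroup clustering, track density."""

import numpy as np
import pytest

from whaletrack.groups import (
    closest_approach_lag,
    find_subgroups,
    group_size,
    lane_distance,
    pairs_distance,
    track_density,
)
from whaletrack.localize import Track

from conftest import straight_track


def _static_track(xyz, t0, t1, dt=1.0, whale_id="w"):
    t = np.arange(t0, t1 + dt / 2, dt)
    pos = np.tile(np.asarray(xyz, float), (len(t), 1))
    return Track(whale_id, t, pos, smoothed_positions=pos.copy())


class TestGroupSize:
    def test_union_after_identity_merge(self):
        ids = {"A": {"w1", "w2"}, "B": {"w2b", "w3"}}
        assert group_size(ids, [("w2", "w2b")]) == 3

    def test_single_whale_single_array(self):
        assert group_size({"A": {"w1"}, "B": set()}, []) == 1

    def test_fully_paired_same_whales(self):
        ids = {"A": {"w1", "w2", "w3"}, "B": {"w1", "w2", "w3"}}
        pairs = [("w1", "w1"), ("w2", "w2"), ("w3", "w3")]
        assert group_size(ids, pairs) == 3

    def test_double_pairing_rejected(self):
        ids = {"A": {"w1"}, "B": {"x", "y"}}
        with pytest.raises(ValueError):
            group_size(ids, [("w1", "x"), ("w1", "y")])


class TestPairsDistance:
    def test_static_pair_constant_distance(self):
        a = _static_track([0.0, 0.0, 1000.0], 0.0, 599.0)
        b = _static_track([300.0, 0.0, 1000.0], 0.0, 599.0)
        series = pairs_distance(a, b)
        assert len(series) == 10
        assert np.allclose(series.mean_m, 300.0)

    def test_disjoint_time_ranges_give_empty_series(self):
        a = _static_track([0, 0, 1000], 0.0, 100.0)
        b = _static_track([10, 0, 1000], 5000.0, 5100.0)
        assert len(pairs_distance(a, b)) == 0

    def test_converging_tracks_match_brute_force(self):
        a = straight_track([0, 0, 1000], [1.0, 0, 0], 300)
        b = straight_track([600, 0, 1000], [-1.0, 0, 0], 300)
        series = pairs_distance(a, b)
        for m, mean in zip(series.minute_starts, series.mean_m):
            mask = (a.times >= m) & (a.times < m + 60)
            expected = np.mean(np.abs(600 - 2.0 * a.times[mask]))
            assert mean == pytest.approx(expected, abs=1e-9)

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(0)
        a = straight_track([0, 0, 1000], [1.0, 0.3, 0], 240)
        pb = np.cumsum(rng.normal(0, 1, (240, 3)), axis=0) + [200, 0, 1000]
        b = Track("b", a.times.copy(), pb, smoothed_positions=pb.copy())
        s1 = pairs_distance(a, b)
        s2 = pairs_distance(b, a)
        assert np.allclose(s1.mean_m, s2.mean_m)


class TestLaneDistance:
    def test_parallel_tracks_interior_bins(self):
        a = straight_track([0, 0, 1000], [1.0, 0, 0], 500)
        b = straight_track([0, 100.0, 1000], [1.0, 0, 0], 500)
        _, vals = lane_distance(a, b)
        assert np.allclose(vals[2:-2], 100.0, atol=1e-6)

    def test_identical_tracks_have_zero_lane_distance(self):
        a = straight_track([0, 0, 1000], [1.0, 0.5, 0], 300)
        _, vals = lane_distance(a, a)
        assert np.allclose(vals, 0.0, atol=1e-9)

    def test_perpendicular_crossing_minimum_at_crossing(self):
        a = straight_track([-200, 0, 1000], [1.0, 0, 0], 400)
        b = straight_track([0, -200.0, 1000], [0, 1.0, 0], 400)
        centers, vals = lane_distance(a, b)
        k = np.argmin(vals)
        # crossing is 200 m along track a
        assert abs(centers[k] - 200.0) <= 10.0
        assert vals[k] < 5.0
        # values increase monotonically away from the crossing
        assert np.all(np.diff(vals[k:]) > -1e-9)
        assert np.all(np.diff(vals[:k + 1]) < 1e-9)

    def test_matches_brute_force_nearest_point(self):
        rng = np.random.default_rng(5)
        pa = np.cumsum(rng.normal(0, 2, (50, 3)), axis=0) + [0, 0, 1000]
        pb = np.cumsum(rng.normal(0, 2, (50, 3)), axis=0) + [80, 0, 1000]
        a = Track("a", np.arange(50.0), pa, smoothed_positions=pa.copy())
        b = Track("b", np.arange(50.0), pb, smoothed_positions=pb.copy())
        from whaletrack.groups import _resample_arclength

        ra, rb = _resample_arclength(pa), _resample_arclength(pb)
        brute = np.array([np.min(np.linalg.norm(rb - p, axis=1)) for p in ra])
        nbin = len(ra) // 10
        expected = brute[: nbin * 10].reshape(nbin, 10).mean(axis=1)
        _, vals = lane_distance(a, b)
        assert np.allclose(vals, expected, atol=1e-9)

    def test_swap_symmetry_within_binning_tolerance(self):
        a = straight_track([0, 0, 1000], [1.0, 0, 0], 400)
        b = straight_track([0, 150.0, 1000], [1.0, 0, 0], 400)
        _, v1 = lane_distance(a, b)
        _, v2 = lane_distance(b, a)
        assert abs(np.median(v1) - np.median(v2)) < 1.0


class TestClosestApproachLag:
    def test_constructed_sixty_second_lag(self):
        # A ends near the origin at t = 100; B passes the origin at t = 160
        a = straight_track([-100, 0, 1000], [1.0, 0, 0], 101)          # ends at 0
        b_t = np.arange(110.0, 211.0)
        b_pos = np.column_stack([np.zeros(101), np.arange(-50.0, 51.0),
                                 np.full(101, 1000.0)])
        b = Track("b", b_t, b_pos, smoothed_positions=b_pos.copy())
        assert closest_approach_lag(a, b) == pytest.approx(60.0)

    def test_simultaneous_closest_points_give_zero_lag(self):
        a = straight_track([-100, 50, 1000], [1.0, 0, 0], 201)
        b = straight_track([-100, -50, 1000], [1.0, 0, 0], 201)
        assert closest_approach_lag(a, b) == 0.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(5):
            pa = np.cumsum(rng.normal(0, 2, (60, 3)), axis=0) + [0, 0, 1000]
            pb = np.cumsum(rng.normal(0, 2, (70, 3)), axis=0) + [50, 30, 1000]
            a = Track("a", np.arange(60.0), pa, smoothed_positions=pa.copy())
            b = Track("b", np.arange(0.0, 140.0, 2.0), pb,
                      smoothed_positions=pb.copy())
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            assert closest_approach_lag(a, b) == pytest.approx(
                abs(a.times[i] - b.times[j]))


def single_linkage_oracle(dist, cutoff):
    """From-scratch single-linkage flat clustering: merge the two closest
    clusters while their distance is <= cutoff."""
    n = dist.shape[0]
    clusters = [{i} for i in range(n)]
    while len(clusters) > 1:
        best = (np.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(dist[i, j] for i in clusters[a] for j in clusters[b])
                if d < best[0]:
                    best = (d, (a, b))
        if best[0] > cutoff:
            break
        a, b = best[1]
        clusters[a] |= clusters[b]
        del clusters[b]
    labels = np.empty(n, dtype=int)
    for k, members in enumerate(clusters):
        for i in members:
            labels[i] = k
    return labels


class TestFindSubgroups:
    def _static(self, xyz, t0=0.0, t1=600.0, wid="w"):
        return _static_track(xyz, t0, t1, whale_id=wid)

    def test_forced_split_by_cutoff(self):
        tracks = {
            "w1": self._static([0, 0, 1000]),
            "w2": self._static([400.0, 0, 1000]),
            "w3": self._static([0, 1500.0, 1000]),
        }
        part = find_subgroups(tracks)  # d(1,2)=400; d(1,3)=1500; d(2,3)~1552
        labels = part.labels
        assert labels["w1"] == labels["w2"] != labels["w3"]
        assert part.n_subgroups == 2

    def test_pair_below_cutoff_is_one_subgroup(self):
        tracks = {"w1": self._static([0, 0, 1000]),
                  "w2": self._static([500.0, 0, 1000])}
        part = find_subgroups(tracks)
        assert part.n_subgroups == 1
        assert part.mean_subgroup_size == 2.0

    def test_no_temporal_overlap_forces_split_despite_proximity(self):
        tracks = {"w1": self._static([0, 0, 1000], 0.0, 600.0),
                  "w2": self._static([10.0, 0, 1000], 1500.0, 2100.0)}
        # gap of 900 s > 10 min -> infinite distance -> separate subgroups
        part = find_subgroups(tracks)
        assert part.n_subgroups == 2

    def test_infinite_cutoff_gives_one_subgroup(self):
        tracks = {f"w{k}": self._static([2000.0 * k, 0, 1000], wid=f"w{k}")
                  for k in range(4)}
        part = find_subgroups(tracks, distance_cutoff=np.inf)
        assert part.n_subgroups == 1

    def test_zero_cutoff_gives_all_singletons(self):
        tracks = {f"w{k}": self._static([100.0 + 50.0 * k, 0, 1000], wid=f"w{k}")
                  for k in range(4)}
        part = find_subgroups(tracks, distance_cutoff=0.0)
        assert part.n_subgroups == 4

    def test_sum_of_subgroup_sizes_equals_group_size(self):
        tracks = {f"w{k}": self._static([700.0 * k, 0, 1000], wid=f"w{k}")
                  for k in range(5)}
        part = find_subgroups(tracks)
        sizes = np.bincount(list(part.labels.values()))
        assert sizes.sum() == 5

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_from_scratch_oracle_on_random_instances(self, trial):
        rng = np.random.default_rng(5000 + trial)
        n = int(rng.integers(2, 7))
        # random 1D whale placements -> Euclidean distance matrix
        coords = rng.uniform(0, 3000, n)
        tracks = {f"w{k}": self._static([coords[k], 0.0, 1000.0], wid=f"w{k}")
                  for k in range(n)}
        dist = np.abs(coords[:, None] - coords[None, :])
        part = find_subgroups(tracks, distance_cutoff=1000.0)
        oracle = single_linkage_oracle(dist, 1000.0)
        got = np.array([part.labels[f"w{k}"] for k in range(n)])
        # same partition up to label renaming
        for i in range(n):
            for j in range(n):
                assert (got[i] == got[j]) == (oracle[i] == oracle[j])


class TestTrackDensity:
    def test_single_track_marks_crossed_bins_once(self):
        a = straight_track([0.5, 5.0, 1000], [1.0, 0, 0], 500)  # 500 m east
        x_edges, y_edges, counts = track_density([a], bin_size=10.0,
                                                 extent=(0, 500, 0, 10))
        assert counts.shape == (50, 1)
        assert np.all(counts == 1.0)

    def test_two_identical_tracks_count_twice(self):
        a = straight_track([0.5, 5.0, 1000], [1.0, 0, 0], 500, whale_id="a")
        b = straight_track([0.5, 5.0, 1000], [1.0, 0, 0], 500, whale_id="b")
        _, _, counts = track_density([a, b], bin_size=10.0, extent=(0, 500, 0, 10))
        assert np.all(counts == 2.0)

    def test_matches_brute_force_membership(self, rng):
        tracks = []
        for k in range(3):
            p = np.cumsum(rng.normal(0, 5, (200, 3)), axis=0) + [500, 500, 1000]
            tracks.append(Track(f"w{k}", np.arange(200.0), p,
                                smoothed_positions=p.copy()))
        x_edges, y_edges, counts = track_density(tracks, bin_size=10.0,
                                                 extent=(0, 1000, 0, 1000))
        brute = np.zeros_like(counts)
        for tr in tracks:
            seen = set()
            for x, y, _ in tr.best_positions:
                ix = int(np.floor((x - 0) / 10.0))
                iy = int(np.floor((y - 0) / 10.0))
                if 0 <= ix < brute.shape[0] and 0 <= iy < brute.shape[1]:
                    seen.add((ix, iy))
            for ix, iy in seen:
                brute[ix, iy] += 1
        assert np.array_equal(counts, brute)

    def test_empty_track_set_gives_zero_grid(self):
        _, _, counts = track_density([], bin_size=10.0)
        assert counts.sum() == 0
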