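"""End-to-end scenario runner: scene -> detections -> localization ->
dive metrics -> group analysis -> detection-probability report.

A scenario is described by a nested config dict (usually loaded from YAML;
see :func:`default_scene_config` for the full schema with defaults).  Every
random draw is funnelled through one seeded generator per stage, derived from
the single master seed, so a rerun with the same config is byte-identical.

Per-array click-train identities come from the detection table's
``truth_whale_id`` column — the stand-in for the study workflow's manual
DOA-based track sorting, which is out of scope here — while the *cross-array*
association is computed from the click trains themselves by normalized
cross-correlation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import dive, groups, io
from .detprob import SimConfig, aggregate, run_model
from .localize import Track, associate_click_trains, jackknife_localize_batch, smooth_track
from .scene import (
    ArrayGeometry,
    DiveConfig,
    Environment,
    default_array_pair,
    emit_clicks,
    generate_bathymetry,
    propagate_and_detect,
    simulate_dive,
)

__all__ = [
    "default_scene_config",
    "run_scenario",
    "localize_detections",
    "presence_summary",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid or incomplete scenario configuration."""


def default_scene_config() -> dict:
    """Default scenario: three coordinated whales diving between two
    tetrahedral arrays 1 km apart on a flat 1300 m seafloor."""
    return {
        "seed": 0,
        "bathymetry": {"kind": "flat", "params": {"depth": 1300.0},
                       "extent": [3000.0, 3000.0], "cell_size": 100.0},
        "arrays": {"separation": 1000.0, "edge": 1.0, "altitude": 6.0},
        "environment": {"sound_speed": 1500.0, "absorption_db_per_m": 0.01,
                        "sample_rate": 100000.0},
        "whales": [
            {"whale_id": "w1", "start_xy": [-150.0, -100.0], "heading_deg": 60.0},
            {"whale_id": "w2", "start_xy": [60.0, 150.0], "heading_deg": 80.0},
            {"whale_id": "w3", "start_xy": [180.0, -60.0], "heading_deg": 100.0},
        ],
        "dive": {"descent_angle_deg": -68.8, "descent_speed": 1.5,
                 "at_depth_speed": 1.0, "duration_s": 2400.0, "dt": 1.0,
                 "altitude_band": [50.0, 200.0], "click_start_depth": 400.0,
                 "heading_sigma_deg": 10.0, "vertical_sigma": 0.3},
        "clicks": {"inter_click_interval": 0.4, "jitter_frac": 0.05,
                   "source_level_range": [221.0, 223.0],
                   "directivity_range": [23.0, 25.0]},
        "detection": {"threshold_db": 112.0, "tdoa_jitter_s": 5e-6},
        "association": {"max_lag": 2.0, "threshold": 0.5, "bin_s": 0.05,
                        "window_s": 45.0, "click_match_tol_s": 0.7},
        "smoothing": {"process_noise": 0.1, "window": 5},
        "encounters": {"gap_minutes": 30.0},
        "phases": {"threshold_m": 200.0},
        "speeds": {"min_descent_s": 300.0, "min_at_depth_s": 600.0},
        "subgroups": {"distance_cutoff": 1000.0, "overlap_minutes": 10.0},
        "density": {"bin_size": 10.0},
        "detprob": {"enabled": True, "n_whales": 2000, "n_sl_values": 3,
                    "n_di_values": 3, "n_replicates": 1, "bin_size": 200.0,
                    "area": [3000.0, 3000.0]},
    }


def _merged(defaults: dict, override: dict) -> dict:
    out = dict(defaults)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merged(out[k], v)
        else:
            out[k] = v
    return out


def _build_scene(cfg: dict):
    try:
        b = cfg["bathymetry"]
        if "file" in b:
            path = Path(b["file"])
            if not path.exists():
                raise ConfigError(f"bathymetry.file does not exist: {path}")
            from .io import read_esri_ascii

            bathy = read_esri_ascii(path)
        else:
            bathy = generate_bathymetry(b["kind"], b["params"], b["extent"], b["cell_size"])
        a = cfg["arrays"]
        if "origins" in a:
            arrays = tuple(
                ArrayGeometry.regular_tetrahedron(aid, origin, a.get("edge", 1.0),
                                                  a.get("altitude", 6.0))
                for aid, origin in zip(("A", "B"), a["origins"])
            )
        else:
            arrays = default_array_pair(a["separation"],
                                        float(b["params"].get("depth", 1300.0)),
                                        a.get("edge", 1.0), a.get("altitude", 6.0))
        env = Environment(**cfg["environment"])
    except KeyError as exc:
        raise ConfigError(f"missing configuration field: {exc}") from None
    return bathy, arrays, env


def presence_summary(detection_times, effort_intervals, bin_s: float = 60.0) -> float:
    """Fraction (in [0, 1]) of effort bins containing at least one detection.

    ``effort_intervals`` is a sequence of (start, end) monitored intervals in
    seconds; each is divided into ``bin_s`` bins (a ragged final bin counts).
    Raises on zero effort.
    """
    times = np.sort(np.asarray(detection_times, dtype=float))
    total, positive = 0, 0
    for t0, t1 in effort_intervals:
        if t1 <= t0:
            continue
        edges = np.arange(t0, t1, bin_s)
        for lo in edges:
            hi = min(lo + bin_s, t1)
            total += 1
            k = np.searchsorted(times, lo, side="left")
            if k < times.size and times[k] < hi:
                positive += 1
    if total == 0:
        raise ValueError("zero effort: no valid effort intervals")
    return positive / total


def localize_detections(detections, arrays, env, association_cfg=None,
                        smoothing_cfg=None):
    """Detections -> smoothed per-whale tracks plus association metadata.

    Per-array trains are grouped by their truth whale id, associated across
    arrays by click-train cross-correlation, matched click-by-click at the
    association lag, cross-fixed with jackknife CIs, and smoothed.
    Returns ``(tracks, per_array_ids, pairings)``.
    """
    acfg = _merged(default_scene_config()["association"], association_cfg or {})
    scfg = _merged(default_scene_config()["smoothing"], smoothing_cfg or {})
    geom = {a.array_id: a for a in arrays}
    if len(geom) != 2:
        raise ConfigError("localization needs exactly two arrays")
    ids = sorted(geom)
    by_array: dict[str, dict[str, list]] = {aid: {} for aid in ids}
    for d in detections:
        if d.array_id not in by_array:
            continue
        if d.whale_id is None:
            raise ConfigError(
                "detections lack truth_whale_id; per-array train identities "
                "are required for automated association")
        by_array[d.array_id].setdefault(d.whale_id, []).append(d)
    for aid in ids:
        for wid in by_array[aid]:
            by_array[aid][wid].sort(key=lambda d: d.arrival_time)

    trains_a = {w: np.array([d.arrival_time for d in ds])
                for w, ds in by_array[ids[0]].items()}
    trains_b = {w: np.array([d.arrival_time for d in ds])
                for w, ds in by_array[ids[1]].items()}
    pairings = []
    if trains_a and trains_b:
        pairings = associate_click_trains(
            trains_a, trains_b, max_lag=acfg["max_lag"],
            threshold=acfg["threshold"], bin_s=acfg["bin_s"],
            window_s=acfg.get("window_s"))

    tracks = []
    # Click-by-click matching needs no lag correction: the inter-array
    # arrival offset is bounded by separation / c, and an off-by-one click
    # mismatch displaces the fix by less than the whale moves in one ICI.
    tol = acfg["click_match_tol_s"]
    for wa, wb, _lag, _peak in pairings:
        da = by_array[ids[0]][wa]
        tb = trains_b[wb]
        ta = trains_a[wa]
        target = ta
        j = np.clip(np.searchsorted(tb, target), 0, len(tb) - 1)
        jm = np.where((j > 0) & (np.abs(tb[j - 1] - target) < np.abs(tb[j] - target)),
                      j - 1, j)
        ok = np.abs(tb[jm] - target) <= tol
        if ok.sum() < 3:
            continue
        det_a = [da[k] for k in np.nonzero(ok)[0]]
        det_b = [by_array[ids[1]][wb][k] for k in jm[ok]]
        tdoas_a = np.array([d.tdoas for d in det_a])
        tdoas_b = np.array([d.tdoas for d in det_b])
        pos, ci, _n = jackknife_localize_batch(
            tdoas_a, tdoas_b, geom[ids[0]], geom[ids[1]], env.sound_speed)
        # emission times: arrival at A minus modelled travel time
        t_emit = np.array([d.arrival_time for d in det_a]) - np.linalg.norm(
            pos - geom[ids[0]].origin[None, :], axis=1) / env.sound_speed
        order = np.argsort(t_emit)
        keep = order[np.concatenate([[True], np.diff(t_emit[order]) > 0])]
        finite = np.isfinite(pos[keep]).all(axis=1)
        keep = keep[finite]
        if keep.size < 3:
            continue
        track = Track(whale_id=wa, times=t_emit[keep], positions=pos[keep],
                      ci95=ci[keep], source_arrays=frozenset(ids))
        tracks.append(smooth_track(track, process_noise=scfg["process_noise"],
                                   window=scfg["window"]))
    per_array_ids = {aid: set(by_array[aid]) for aid in ids}
    return tracks, per_array_ids, pairings


def run_scenario(config: dict | None = None, out_dir="scenario_out",
                 seed: int | None = None) -> dict:
    """Run the full pipeline and write all outputs plus a manifest.

    Returns the manifest dict.  Outputs: ``bathymetry.asc``,
    ``detections.csv``, ``tracks.csv``, ``track_metrics.csv``,
    ``encounters.csv``, ``detection_probability.csv``, ``manifest.json``.
    """
    cfg = _merged(default_scene_config(), config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bathy, arrays, env = _build_scene(cfg)
    master = np.random.SeedSequence(cfg["seed"])
    stage_seeds = np.random.default_rng(master).integers(0, 2**31 - 1, size=4)

    # --- scene ---
    dive_defaults = cfg["dive"]
    trajectories = []
    clicks = []
    whale_rng = np.random.default_rng(stage_seeds[0])
    for wcfg in cfg["whales"]:
        dcfg_dict = _merged(dive_defaults, {k: v for k, v in wcfg.items()
                                            if k != "whale_id"})
        dcfg_dict["start_xy"] = tuple(dcfg_dict["start_xy"])
        dcfg_dict["altitude_band"] = tuple(dcfg_dict["altitude_band"])
        dcfg = DiveConfig(**dcfg_dict)
        wseed = int(whale_rng.integers(0, 2**31 - 1))
        traj = simulate_dive(dcfg, bathy, seed=wseed, whale_id=wcfg["whale_id"])
        trajectories.append(traj)
        ccfg = cfg["clicks"]
        clicks.extend(emit_clicks(
            traj, ccfg["inter_click_interval"],
            seed=int(whale_rng.integers(0, 2**31 - 1)),
            jitter_frac=ccfg["jitter_frac"],
            source_level_range=tuple(ccfg["source_level_range"]),
            directivity_range=tuple(ccfg["directivity_range"])))
    detections = propagate_and_detect(
        clicks, arrays, env, threshold_db=cfg["detection"]["threshold_db"],
        tdoa_jitter_s=cfg["detection"]["tdoa_jitter_s"], seed=int(stage_seeds[1]))

    io.write_esri_ascii(bathy, out / "bathymetry.asc")
    io.write_detections(detections, out / "detections.csv")

    # --- localization ---
    tracks, per_array_ids, pairings = localize_detections(
        detections, arrays, env, cfg["association"], cfg["smoothing"])
    io.write_tracks(tracks, out / "tracks.csv")

    # --- dive metrics ---
    import pandas as pd

    metric_rows = []
    track_phases = {}
    for t in tracks:
        phases = dive.classify_phases(t, bathy, cfg["phases"]["threshold_m"])
        track_phases[t.whale_id] = phases
        alt = dive.altitude_above_seafloor(t, bathy)
        at_depth = np.array([p == dive.Phase.AT_DEPTH for p in phases])
        try:
            angle, angle_sd, _ = dive.descent_angle(t, phases)
        except ValueError:
            angle, angle_sd = float("nan"), float("nan")
        speeds = dive.swim_speeds(t, phases, cfg["speeds"]["min_descent_s"],
                                  cfg["speeds"]["min_at_depth_s"])
        n_desc = int((~at_depth).sum())
        metric_rows.append({
            "whale_id": t.whale_id,
            "n_points": len(t),
            "start_s": t.times[0], "end_s": t.times[-1],
            "descent_duration_s": (t.times[n_desc - 1] - t.times[0]) if n_desc > 1 else 0.0,
            "at_depth_duration_s": (t.times[-1] - t.times[n_desc]) if n_desc < len(t) else 0.0,
            "descent_angle_deg": angle, "descent_angle_sd_deg": angle_sd,
            "median_speed_descent_ms": speeds["initial_descent"],
            "median_speed_at_depth_ms": speeds["at_depth"],
            "median_altitude_m": float(np.median(alt[at_depth])) if at_depth.any() else float("nan"),
        })
    pd.DataFrame(metric_rows).to_csv(out / "track_metrics.csv", index=False,
                                     float_format="%.12g")

    # --- encounters and groups ---
    det_times = np.array([d.arrival_time for d in detections])
    det_ids = [d.whale_id for d in detections]
    encounters = dive.segment_encounters(det_times, cfg["encounters"]["gap_minutes"],
                                         ids=det_ids)
    track_by_id = {t.whale_id: t for t in tracks}
    enc_rows = []
    for enc in encounters:
        size = groups.group_size(per_array_ids, pairings)
        enc_tracks = {w: track_by_id[w] for w in enc.member_tracks
                      if w in track_by_id}
        if len(enc_tracks) >= 2:
            part = groups.find_subgroups(enc_tracks,
                                         cfg["subgroups"]["distance_cutoff"],
                                         cfg["subgroups"]["overlap_minutes"],
                                         encounter_id=enc.encounter_id)
            n_sub, mean_sub = part.n_subgroups, part.mean_subgroup_size
        else:
            n_sub, mean_sub = (1, 1.0) if enc_tracks else (0, float("nan"))
        enc_rows.append({
            "encounter_id": enc.encounter_id, "start_s": enc.start,
            "end_s": enc.end, "group_size": size, "n_subgroups": n_sub,
            "mean_subgroup_size": mean_sub,
        })
    pd.DataFrame(enc_rows).to_csv(out / "encounters.csv", index=False,
                                  float_format="%.12g")

    # --- detection probability ---
    dp = cfg["detprob"]
    if dp.get("enabled", True):
        sim = SimConfig(n_whales=dp["n_whales"], area=tuple(dp["area"]),
                        bin_size=dp["bin_size"], n_sl_values=dp["n_sl_values"],
                        n_di_values=dp["n_di_values"],
                        n_replicates=dp["n_replicates"],
                        threshold_db=cfg["detection"]["threshold_db"])
        grids = run_model(sim, arrays, bathy, env, seed=int(stage_seeds[2]))
        final = aggregate(grids)
        io.grid_to_frame(final).to_csv(out / "detection_probability.csv",
                                       index=False, float_format="%.12g")

    # --- manifest ---
    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": cfg,
        "stage_seeds": [int(s) for s in stage_seeds],
        "n_clicks": len(clicks),
        "n_detections": len(detections),
        "n_tracks": len(tracks),
        "truth_echolocation_duration_s": {
            t.whale_id: t.echolocation_duration for t in trajectories},
        "outputs": {f: hashlib.sha256((out / f).read_bytes()).hexdigest()
                    for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
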