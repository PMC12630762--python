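# whaletrack

Passive-acoustic 3D tracking of deep-diving toothed whales from paired
small-aperture hydrophone arrays, with the downstream dive-behaviour and
group-behaviour analyses and a Monte Carlo probability-of-detection model.

The package is aimed at marine-bioacoustics and movement-ecology researchers
working with seafloor recorder deployments in which two 4-hydrophone
tetrahedral arrays (~1 m hydrophone spacing, ~1 km apart, sampling at
100 kHz) record echolocation clicks of deep divers such as goose-beaked
whales. Because raw multi-month acoustic data are impractical to ship with an
analysis package, `whaletrack` includes a first-class synthetic-scene
generator — bathymetry, dive trajectories, click emission, propagation and
per-array detections — so every stage of the chain is testable end to end.

## The method

**Direction of arrival.** A click arriving at a 4-phone array with phone
positions $p_i$ gives six pairwise time differences
$\tau_{ij} = t_i - t_j$. Under a plane-wave arrival from unit direction $u$
(array → source), $\tau_{ij} = -(p_i - p_j)\cdot u / c$; stacking the six
baselines into $B$, the DOA is the least-squares solution of
$B u = -c\,\tau$, normalized to the unit sphere.

**Cross-fix.** The DOA rays from the two arrays rarely intersect exactly; the
3D position is the midpoint of their mutual perpendicular segment, requiring
both ray parameters ≥ 0 (source in front of both arrays).

**Jackknife confidence intervals.** Each click is re-localized six times
using five of the six TDOA pairs (the same pair dropped from both arrays);
with re-localizations $\theta_k$ and their mean $\bar\theta$, the jackknife
variance per axis is $\frac{n-1}{n}\sum_k(\theta_k-\bar\theta)^2$ and the
95% CI half-width is $t_{0.975,\,n-1}$ times the jackknife SE.

**Smoothing.** A constant-velocity Kalman filter (RTS two-pass by default)
weighted by the per-point CIs, followed by a centred moving average.

**Dive metrics.** Altitude = nearest-node bathymetry depth − whale depth;
the dive is *initial descent* until the whale first comes within 200 m of
the seafloor (inclusive, one-way), *at depth* after; descent angle is the
Gaussian-KDE mode of per-segment pitch angles (SD over angles within 20° of
the mode); swim speeds are per-phase medians of step speeds on the smoothed
track, with 5-min (descent) / 10-min (at depth) minimum-duration filters.

**Detection probability.** Monte Carlo: 10,000 whales placed uniformly over
an 8 × 8 km area with random azimuth, source level 221–223 dB pp re 1 µPa,
directivity index 23–25 dB (circular-piston beam, $ka = 10^{DI/20}$,
attenuation capped at 40 dB); a click counts as detected when the received
level SL − TL − off-axis attenuation meets the 112 dB pp threshold on *both*
arrays. Per-100 m-bin probabilities are averaged over a 135-iteration
parameter sweep and duration-weighted across deployments. Transmission loss
is pluggable (analytic spherical spreading + absorption by default, or a
precomputed range × depth table).

**Groups.** Encounters split at detection gaps exceeding 30 min; group size
is the distinct-individual count across both arrays after click-train
cross-correlation association. Pair coordination is quantified by per-minute
*pairs distance* and time-free *lane distance* (1 m arc-length resampling,
nearest point of the other track, 10 m bins), closest-approach time lags,
and single-linkage subgrouping with a 1000 m cutoff and a 10-min
temporal-overlap rule.

## Worked example

Localize one click received on both arrays, with jackknife CIs:

```python
import numpy as np
import whaletrack as wt
from whaletrack.localize import TDOASet, jackknife_ci

# two tetrahedral arrays 1 km apart, 6 m above a 1300 m seafloor
array_a, array_b = wt.default_array_pair(separation=1000.0, seafloor_depth=1300.0)
env = wt.Environment()           # 1500 m/s, 0.01 dB/m, 100 kHz

# a whale clicking 1.5 km from both arrays, with 10 us TDOA jitter
whale = np.array([0.0, 1280.6, 694.0])   # east, north, depth (m)
rng = np.random.default_rng(0)
tdoa_a = wt.true_tdoas(whale, array_a, env.sound_speed) + rng.normal(0, 10e-6, 6)
tdoa_b = wt.true_tdoas(whale, array_b, env.sound_speed) + rng.normal(0, 10e-6, 6)

point = jackknife_ci(
    (TDOASet("A", 0.0, tdoa_a), TDOASet("B", 0.0, tdoa_b)),
    (array_a, array_b), env.sound_speed)
print("position (m):   ", np.round(point.position, 1))
print("95% CI (m):     ", np.round(point.ci95, 1))
print("error (m):      ", round(float(np.linalg.norm(point.position - whale)), 1))
```

prints

```
position (m):    [ -16.  1250.2  706.7]
95% CI (m):      [ 7.4 61.8 32.5]
error (m):       36.6
```

i.e. a single 10 µs-jittered click 1.5 km out localizes to a few tens of
metres, with the along-bearing axis (north, here) the least constrained —
exactly the anisotropy the jackknife CIs report. Track-level smoothing then
reduces this error by roughly a further factor of five.

The whole pipeline — three coordinated simulated whales through detection,
association, localization, dive metrics, group statistics and the detection
probability map — runs from the shell:

```bash
whaletrack run-all --seed 1 --out scenario_out
# -> 3 tracks from 25758 detections; outputs in scenario_out
```

writing `detections.csv`, `tracks.csv`, `track_metrics.csv`,
`encounters.csv`, `detection_probability.csv`, `bathymetry.asc` and a
`manifest.json` of seeds, parameters and output hashes. Subcommands
`simulate`, `localize`, `calibrate`, `metrics`, `groups` and `detprob` run
the stages separately on files.

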