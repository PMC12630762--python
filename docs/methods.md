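# Methods

This note records the models behind `whaletrack`, the defaults that matter,
and the choices made where the design was genuinely open. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate frame and conventions

All positions are local Cartesian east/north metres with the origin at the
midpoint between the two arrays; the third coordinate is **depth, positive
down**. Altitude always means local seafloor depth minus whale depth.
Direction vectors share the frame (so "up" has a negative third component);
azimuth is compass degrees (0 = north, 90 = east), elevation positive upward.

Hydrophone pairs are always ordered (1,2),(1,3),(1,4),(2,3),(2,4),(3,4) and
the TDOA sign is τᵢⱼ = tᵢ − tⱼ, so a plane wave from direction u gives
τᵢⱼ = −(pᵢ−pⱼ)·u/c. These conventions are arbitrary but load-bearing: every
file format and API documents them, and the forward model, the inversion and
the simulator all share them.

## Synthetic scenes

The generator emulates the statistical structure the downstream analysis
assumes, not ocean physics:

* **Bathymetry** — analytic flat / sloped / Gaussian-canyon surfaces on a
  regular grid (1200–1350 m typical depths), plus ESRI ASCII import.
* **Dives** — a straight descent from the surface at a configurable pitch
  (default −68.8°, the package's reference value for the species' steep
  initial descent) at 1.5 m/s, switching irreversibly to a correlated random
  walk confined to a 50–200 m altitude band above the seafloor at 1.0 m/s,
  with per-step heading jitter (default σ = 10–12°) and a reflected
  random-walk altitude. Dives last ~40–60 min; sampling is 1 s.
* **Clicks** — emitted while the whale is below the clicking start depth
  (default 400 m: echolocation on deep dives only), at a regular
  inter-click interval (default 0.4 s, a typical beaked-whale value; the ICI,
  click duration and depth distribution are assumptions, not measured
  inputs) with fractional jitter, the acoustic axis following the velocity.
  Source level 221–223 dB pp re 1 µPa and directivity index 23–25 dB are
  drawn uniformly per click.
* **Detection** — received level = SL − TL − off-axis attenuation; a click
  is kept when RL ≥ 112 dB pp (inclusive). Arrival time is emit time plus
  slant range over a scalar sound speed (default 1500 m/s). TDOAs are exact
  spherical-wavefront values plus i.i.d. Gaussian jitter (default σ = 5 µs),
  which stands in for waveform-level measurement noise at desk-scale speed.
* **Waveforms** (optional) — a Gaussian-windowed 40 kHz tone (σ = 40 µs,
  placing ≥ 99% of energy in 20–60 kHz) placed at each channel's exact
  arrival offset, for testing the correlation-based TDOA measurement.

What the generator does **not** emulate: buzzes, surface behaviour and
ascents, refracting sound-speed profiles, reverberation, clock drift, or
interfering sound sources. Tests passing on these scenes therefore validate
the *analysis chain*, not its robustness to every field condition.

## TDOA measurement

Four-channel click windows are high-pass filtered (4th-order zero-phase
Butterworth, 20 kHz cutoff — skipped for windows too short to filter
stably) and cross-correlated per pair. The correlation is band-limited
upsampled 16× (FFT resampling) before parabolic refinement of the peak:
plain parabolic interpolation on a 100 kHz-sampled correlation of a ~40 kHz
click can lock onto the wrong carrier cycle, while the interpolated global
maximum is the true continuous-time peak. Windows must span at least 50 µs.

## DOA, cross-fix and jackknife CIs

The DOA is the unconstrained least-squares solution of B u = −cτ over the
valid pairs (≥ 3, spanning 3D), normalized afterwards; the pre-normalization
residual RMS is reported. The plane-wave approximation across a 1 m aperture
biases positions by well under a metre at kilometre ranges.

The cross-fix is the midpoint of the mutual perpendicular between the two
DOA rays, rejecting near-parallel geometry (< 0.05°) and negative ray
parameters.

Jackknife CIs re-localize with one TDOA pair dropped. The default ("paired")
strategy drops the same pair index from both arrays — six subsets, each a
five-of-six-pairs localization, Student-t with 5 df — because the six pairs
play symmetric roles on the two identical arrays; a "per_array" strategy
(twelve subsets, 11 df) is available behind a flag since which set of six
the original workflow jackknifes is ambiguous. The six TDOAs of a 4-phone
array carry only three independent delays, so the jackknife is over
correlated observations; its empirical per-axis coverage under 10 µs jitter
is measured by the acceptance suite rather than assumed.

## Track smoothing

A constant-velocity Kalman filter per axis, with discrete white-acceleration
process noise (default σₐ = 0.1 m/s²) and measurement σ from each point's
95% CI (floored at 10 m), followed by a centred 5-point moving average.
The filter runs forward-backward (RTS) by default — the right choice for
offline track analysis, halving velocity error and removing lag; forward-only
filtering is available via `rts=False`. At the track ends the centred moving
average shrinks asymmetrically, displacing the last points by roughly one
step; interior points are unaffected.

For descent-angle estimation specifically, the analyses in this package
smooth with σₐ = 0.02 m/s²: a steadily descending whale manoeuvres far less
than the general default assumes (0.1 m/s² integrates to ~3 m/s of velocity
wander over a 13-min descent), and excess process noise leaks measurement
noise into the velocity estimate, biasing the per-segment angle mode toward
horizontal.

## Cross-array association

Click trains are binned and cross-correlated over lags up to 2 s. Two
departures from a plain global normalized cross-correlation, both needed for
long tracks:

* **Windowed scoring** — the inter-array lag drifts by up to ±separation/c
  (~±0.7 s) as the whale moves, smearing a whole-track correlation peak;
  the pipeline correlates 45 s windows (in which the lag is essentially
  constant) and scores a pair by the *median* per-window peak.
* **Overlap normalization** — the beam is directional, so the two arrays
  detect strongly asymmetric subsets of a train; cosine normalization caps
  a correct match at √(n_A/n_B). Dividing by the smaller train's energy
  (overlap coefficient) scores a contained train as 1 regardless of
  asymmetry. Cosine remains available (`norm="cosine"`), and independent
  Poisson trains still score far below the 0.5 acceptance threshold.

Accepted pairs are assigned one-to-one greedily by descending peak.
Click-by-click matching across arrays then uses plain nearest arrival time
with a separation/c tolerance: an off-by-one-click mismatch displaces a fix
by less than the whale moves in one ICI (< 1 m), far below jitter error, so
lag-corrected matching would add complexity without accuracy.

In the end-to-end pipeline, *per-array* train identities are taken from the
detection table's `truth_whale_id` column — the stand-in for the manual
DOA-sorting step of the original workflow, which is interactive and out of
scope here. The cross-array association itself is always computed.

## Dive metrics

* Encounters split where the detection gap strictly exceeds 30 min.
* Altitude uses nearest-node bathymetry lookup ("closest bathymetric
  value"); bilinear interpolation is available behind a flag.
* The 200 m phase threshold is read as inclusive ("within 200 m"), and the
  switch is one-way.
* Descent angle: per-segment pitch = atan2(−Δdepth, horizontal distance);
  Gaussian KDE with Silverman bandwidth (the kernel and bandwidth are
  unspecified upstream; Silverman is the standard default), argmax on a
  0.1° grid over [−90°, 90°]; SD over angles within 20° of the peak. A
  zero-variance sample short-circuits the KDE.
* Swim speeds: step distance over step time on smoothed positions, median
  per phase; phases shorter than 5 min (descent) / 10 min (at depth) are
  reported as missing.

## Detection probability

Whales are placed uniformly over the area (centred on the array midpoint)
with uniform random azimuth; depth placement defaults to a uniform 50–250 m
altitude band above the local seafloor and pitch to 0° (horizontal axis) —
both unspecified upstream, chosen to match the simulated at-depth behaviour,
and configurable. The beam is a circular piston, attenuation
−20·log₁₀|2J₁(ka·sinθ)/x| with ka = 10^(DI/20) (large-ka mapping), capped
at 40 dB and fixed at the cap behind the animal (θ > 90°); DI = 0 is treated
as exactly omnidirectional, which makes closed-form validation possible.
The 135 iterations are a 3 source-level × 3 directivity × 15 replicate grid
spanning the stated ranges (the exact upstream sweep is unpublished; the
count and ranges match). Aggregation is the per-bin NaN-aware mean of
iteration probabilities, optionally duration-weighted across deployments and
max-normalized to [0, 1].

## Group behaviour

Pairs distance matches points nearest-in-time within 5 s (tolerance
unspecified upstream) and averages per wall-clock minute. Lane distance
resamples both smoothed tracks to 1 m arc length and averages
nearest-point distances over 10 m *arc-length* bins along the first track
(the binning axis is ambiguous upstream; arc-length bins preserve the
"lanes" picture, and the metric's residual asymmetry is bounded by the
binning). Subgrouping clusters the unweighted mean per-minute distances by
single linkage, cut at 1000 (read as metres); pairs that do not temporally
overlap within 10 min get infinite distance, which forces the stated split;
pairs inside the 10-min rule but with no shared minutes fall back to the
time-free closest-approach distance, since their mean pairs distance is
undefined. Track density counts distinct whales entering each 10 m bin,
evaluated at the tracks' sampled points (sample finely relative to the bin).

## Numerical choices and degenerate inputs

Rank deficiency in the DOA inversion is detected by singular-value ratio
(10⁻⁹); near-parallel cross-fix rays are rejected below 0.05°; receiver
calibration (nonlinear least squares over ship-noise TDOAs at known
positions) rejects horizontally collinear ship tracks by singular-value
test and requires receivers spread on baselines comparable to the ship
range for absolute observability. Zero-length track segments are skipped in
angle estimation; empty click trains, zero effort, and points outside the
bathymetry raise immediately.

## Problem sizes

The default scenario uses three whales, 40-minute dives at 1 s sampling,
0.4 s ICI (~16k clicks, ~26k array-detections) on a 3 × 3 km flat-bottom
scene; the detection-probability acceptance check runs 10,000 whales × 9
iterations on the full 8 × 8 km / 100 m grid; localization accuracy and CI
coverage use 500 jittered clicks/trials. These sizes give stable statistics
for every check while keeping the whole suite fast on a single CPU.

## Known limitations

* Plane-wave DOA inversion (sub-metre bias at km ranges, grows at short
  range); no refraction — straight-ray propagation with scalar sound speed.
* The piston beam with the large-ka DI mapping and a hard 40 dB cap is a
  coarse model of a real click's frequency-dependent beam.
* Automated association replaces expert manual track cleaning; per-array
  identity assignment is not solved here (truth labels stand in).
* Jackknife CIs are over correlated TDOA pairs (3 independent delays in 6
  pairs); coverage is validated empirically under the simulated noise model
  only.
* Lane distance is asymmetric at the binning level; the symmetrized variant
  is just the swapped call averaged by the user.
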