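# Methods

## Coordinate conventions

Pose files carry image coordinates: origin top-left, y increasing
downward, 0-based frame indices. All geometry flips to a y-up
mathematical frame internally, so every reported angle is
counter-clockwise-positive when the video is viewed normally, in
degrees in (−180, 180]. The rail the prey rides is the image x-axis,
rightward positive. The pixel pitch (`mm_per_px`, default 0.5) is a
required calibration input: the recordings this package targets carry
a scale bar but no stored pitch, so it cannot be inferred from a file.

## Track cleaning

Pose estimators occasionally emit confident mislabels and flag
occlusions with low per-point likelihood. Cleaning is likelihood
gating (threshold 0.9, the conventional operating point for these
estimators' confidence output) followed by linear interpolation of
interior gaps in frame index, independently per coordinate. Leading
and trailing gaps are filled by constant extension — extrapolating
motion past the recording boundary would invent data. Interpolation is
exact on affine trajectories and idempotent on its own output. An
optional jump-distance gate (displacement > J px/frame) exists for
confident mislabels the likelihood gate misses, but is off by default
because no principled J is known for this rig.

Smoothing (centered moving average, window 5 frames ≈ 56 ms at 90 fps,
shrinking symmetrically at the edges) is applied **only** inside
derivative estimation. Stored coordinates are never smoothed: positions
are the primary data and stay authoritative.

## Kinematic variables

With head = eye midpoint, body axis = mantle end → head:

- α = signed angle from the body axis to the head→prey direction,
  where the prey reference point is the shrimp eye midpoint (strikes
  target the anterior body; the hook is a rig artifact). Configurable
  to hook or centroid.
- β (per eye) = signed angle from the body axis to the mantle-end→eye
  direction. Only one labeled point per eye exists, so this is a
  point-based proxy for the ocular axis; vergence appears as the
  excursion Δβ. This construction is an interpretation the landmark
  set supports, not a certified optical measurement.
- δ (per side) = signed angle from the body axis to the head→club-tip
  direction, reported only while the tentacle is extended beyond
  0.35 × mantle length; below that the retracted clubs sit between the
  arms and the tip label carries no direction.
- θ (per side) = signed angle from the head→tip axis to the tip's
  displacement over a centered 5-frame window, undefined when the tip
  moves less than 2 px over the window. A terminal change in θ is the
  signature of in-flight strike correction.
- Horizontal speeds: central difference of the smoothed x coordinate
  × fps × mm/px. The trial's mantle-length scale is the **median** of
  per-frame |head − mantle end|, robust to the soft-body shape change
  these animals show.
- Target distance: |prey − head| / mantle scale, in mantle lengths
  (ML). Horizontal distance is displacement, not cumulative path.

All angle operations are equivariant under rotation and translation
and antisymmetric under left-right mirroring; the test suite checks
these properties against an independent two-point trigonometry oracle.

## Phase and event segmentation

**Prey phases.** |v| < 5 mm/s is stationary, 5–50 mm/s slow,
≥ 50 mm/s fast; the split sits midway between the rig's 25 and
75 mm/s legs. Labels are median-filtered over 5 frames. Reversals are
velocity sign changes between moving frames, requiring both adjacent
sign-runs to persist ≥ 3 frames (the speed estimate is noisier at the
series edges where the smoothing window shrinks).

**Attention episodes.** Attention is operationalised purely from body
alignment — maximal intervals with |α| ≤ 30°, interruptions shorter
than 0.5 s merged, episodes shorter than 1 s dropped. This is a
reconstruction: published attention times were hand-scored and no
detection thresholds exist to match, so the packaged per-episode table
is the reference for duration statistics, and re-detection is
validated against the simulator's scripted windows instead.

**Strikes.** Per side, extension e(t) = |tip − head| / mantle scale.
An event starts where e crosses 0.5 ML upward with de/dt ≥ 2 ML/s and
lasts until e falls back below 0.5 ML; left/right detections with
onsets within 100 ms merge (the tentacles are shot as a pair). Δβ is
the max−min excursion of each β over [onset − 0.5 s, end]. Strike
*success* is never inferred from kinematics — contact cannot be
resolved from five labeled points; it comes from simulator ground
truth or an annotation column.

## Rank statistics

Wilcoxon matched-pairs signed-rank (paired speed summaries) and
Mann–Whitney U (attention durations with vs without a strike attempt).
Both use exact enumeration nulls for small samples — all 2ⁿ sign
assignments (n ≤ 15) and all C(n, n₁) group labelings (n₁+n₂ ≤ 20) —
which handle midrank ties without approximation; larger samples use
the normal approximation with tie and continuity corrections. The
switchover sizes mirror common statistical-package defaults. Two-sided
p is the null probability of a deviation from the null mean at least
as large as observed; both enumeration nulls are symmetric, so this
equals doubling the smaller tail. The 29-episode attention comparison
therefore runs as normal approximation with continuity correction. The
published "spread vs norm" comparisons are reconstructed as a
one-sample sign-flip location test against the stated norm (1 ML;
perpendicular); the original variant is undocumented and this
reconstruction is clearly labeled as such.

## The simulator

The generator reproduces the study conditions: 120 s sessions at
90 fps in a 2048 × 2048 px frame at 0.5 mm/px; a 250 mm rail with a
25 mm/s leftward leg and a 75 mm/s rightward leg joined by
instantaneous reversals; a sub-adult-sized mantle (80 mm, within the
6–10 cm range of the study animals).

The cuttlefish is a delayed velocity-matching tracker. During
attention windows its horizontal velocity is the commanded prey
velocity 150 ms earlier, scaled by a phase gain — 0.9 in the slow leg,
0.05 in the fast leg, encoding the empirical finding that the animals
keep up with slow prey and freeze when it runs. Heading turns toward
the prey at a saccade rate (600 °/s) when more than 20° off and at a
smooth tracking rate (90 °/s) otherwise, modeling the saccadic body
turns these animals use; outside attention the agent sits still,
heading 90° off-prey. Commanded strikes extend the club tips
ballistically over 120 ms (a free parameter; no measured strike
duration exists, but it is consistent with the sub-second seizure
windows in published frame sequences) to a peak of 1.8 ML, aimed at
either the delayed observed prey position or that position
extrapolated by the delay (visual prediction), with an optional
terminal bearing rotation over the final 30% of the extension. The
ejected tentacles travel to a fixed world target (anchored at the
head's strike-onset position). Success is the minimum club–prey
distance over the fine-sampled sweep falling inside a 5 mm capture
radius — the order of a shrimp body half-width, a simulator choice,
not a measured value. Under these dynamics a non-predictive strike
misses slow prey by ≈ 5.9 mm (delay plus tentacle travel time at
25 mm/s) and fast prey by ≈ 11 mm, while a predictive strike on
constant-velocity prey lands by construction: prediction is what makes
delayed strikes succeed.

Rendering places eyes at ± 0.12 ML lateral of the head, the mantle end
1 ML behind it, and shrimp landmarks at fixed offsets around the rail
point, converts to image pixels (y flipped), adds Gaussian landmark
noise (σ = 1 px default), and draws occlusions as independent
Bernoulli events (p = 0.02 default) whose points are displaced by up
to ± 80 px with likelihood in [0, 0.5] — confident mislabels the
likelihood gate must catch; visible points get likelihood in
[0.95, 1]. Output is bit-reproducible for a given seed.

**What the simulator does not emulate** — and hence what passing tests
do not show about real recordings: body deformation (the rendered
animal is rigid, so β is constant up to noise and Δβ carries no
vergence signal); water-surface ripple artifacts; correlated or
drifting pose errors (noise is i.i.d.); prey escape behaviour (the
shrimp is rigidly rail-mounted); and 3-D effects. A pure
velocity-matching tracker also drifts relative to the prey (its mean
slow-leg speed is 22.5 < 25 mm/s), so over long sessions the prey can
leave tentacle reach; the agent is clamped at the tank walls, and
strike scenarios command strikes while the prey is within reach, which
is also when real animals strike.

## Problem sizes and numerical choices

The acceptance computation uses one default 120 s trial (10 800
frames), noise-free, and reports the pipeline's mean |prey speed| over
generator-labeled slow and fast frames; recovery is within 0.5% of the
commanded 25 / 75 mm/s. Strike-detection validation sweeps 100 seeded
15 s trials with one randomized strike each. Angle ties at exactly
±180° are reported as +180; degenerate geometry (zero-length axes,
coincident points) raises typed errors rather than returning NaN from
public single-frame operations, while the bulk pipeline marks such
frames NaN and carries on. Interpolated values are flagged per frame
and per part, so downstream analyses can exclude them.
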