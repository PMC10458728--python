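# Methods

This note documents the models, conventions and design choices behind
`flydetector`, in the spirit of a methods section: what is computed, under
which assumptions, and what the synthetic validation does and does not show.

## World model and coordinate conventions

The tunnel is an axis-aligned box: x runs from the entrance (x = 0) toward
the exit, y is lateral (left-positive when facing +x), z is up, origin at
the entrance floor centre.  Default dimensions are 1.56 × 0.28 × 0.28 m;
the barrier plane sits at x = 1.26 m (0.30 m before the exit, matching the
field configuration the defaults emulate).  Image coordinates are u
(columns, rightward) and v (rows, downward); for the nadir cameras used
here u grows with world x and v grows as y decreases, so an image-frame
heading is the negative of the world yaw.  Yaw is reported in (−180°, 180°].

**Barrier kinematics.**  The gap width w(t) is a symmetric triangle wave
between `d_min` (default 0.02 m) and `d_max` (default 0.10 m) whose slope
magnitude is the gear-rack linear speed v_c = 2π f_p r_c / i.  The gap is
centred on the tunnel axis, so each panel edge moves at v_c/2; w(t) is
continuous with period 2(d_max − d_min)/v_c.  The constant-speed alternating
law is the simplest waveform consistent with a stepper motor driven at a
fixed pulse rate with periodic direction reversal; the triangle wave is a
modelling choice, as is attributing v_c to the opening *rate* (rather than
to each edge individually — the two readings differ by a factor of two and
cannot both hold for a centred gap).  Default pulse frequency 64 Hz with
r_c = 10 mm and i = 64 gives v_c ≈ 0.063 m/s, a full open–close cycle every
≈ 2.5 s — slow relative to a bee's transit, as in a behavioural experiment.

**Detectability distance.**  D = d / tan(δ/2) with δ the ommatidial visual
angle (default 5°).  The quotient form is used: it is the distance at which
a gap of width d subtends exactly δ, and it is the reading under which the
companion design rule "tunnel length > 2D" is satisfiable for centimetre
gaps (a product d·tan(δ/2) would make the rule trivially true at
sub-millimetre scales and the constraint meaningless).

**Wall texture.**  White noise filtered by 1/|f| in the Fourier domain and
binarised at the median, giving a two-level random pattern whose radially
averaged amplitude spectrum has a log–log slope near −1 over the central
frequency decade.  The generator is deterministic per seed.

## Synthetic imaging

The renderer replaces the physical rig and is deliberately minimal: a light
floor (grey level 200) with the wall texture shown as bands along the image
edges, the barrier as two dark panels (level 60) leaving the instantaneous
gap, and the insect as a filled dark ellipse (level 30, body 13 × 4 mm by
default) rotated by yaw, Gaussian-blurred (σ = 1 px) with optional additive
pixel noise.  Two camera models are preconfigured: the detection camera
(30 fps, 960 × 360 px, 620 mm horizontal footprint, nadir over the tunnel
centre) and the high-speed framing camera (163 fps, 640 × 480 px,
46.8° × 36° field of view, nadir over the barrier region at 0.6 m height,
≈ 0.62 mm/px on the flight plane).

Simulated flights are constant-speed advances with an optional sinusoidal
lateral "scanning" oscillation and low-pass-filtered Gaussian jitter
(smoothed over ≈ 60 ms so the path stays flyable); yaw follows the velocity
direction.  All randomness flows from explicit integer seeds.

What the renderer does *not* emulate: wing beat, body pitch/roll, motion
blur, lighting gradients, shadows, multiple insects, lens distortion.
Consequently the validation results bound algorithmic error (segmentation,
moments, queueing logic, projection) rather than photometric robustness on
real footage.

## Trigger

Background subtraction uses a pixelwise-median background with an absolute
difference threshold (default 30 grey levels) — deterministic and exact for
a fixed camera; an adaptive mixture model can be substituted behind the
same interface.  Connected components are filtered to a configurable area
window (default 50–5000 px²); more than one qualifying component is an
"ambiguous detection" and the frame is skipped with state preserved (the
single-insect guard).

The direction statistic over a full queue of n centroids (default n = 5)
telescopes to (last − first)/n; its sign increments or decrements the Flag
counter each frame (sliding window).  When the insect has been absent for
`exit_patience` consecutive frames (default 3), the trigger fires iff Flag
reaches the signed threshold (default ±1) for the configured direction,
then resets.

**Short-crossing fallback.**  At 8 m/s a 620 mm field at 30 fps yields only
2–3 detection frames, fewer than the queue length, yet the rig this package
models is specified to trigger reliably up to 8 m/s.  The exit decision
therefore falls back to the same statistic computed over *all* detections
of the crossing whenever the queue never filled and at least two detections
exist.  With fewer than two detections no direction can be defined and the
trigger stays silent — which is exactly what produces the accuracy collapse
above ≈ 9.3 m/s (620 mm · 30 fps / 9.3 m/s = 2 frames).

## Pose and gap extraction

Yaw is the orientation of the equivalent ellipse, θ = ½·atan2(2μ₁₁,
μ₂₀ − μ₀₂) from the blob's second central moments; the 180° axis ambiguity
is resolved toward the centroid's direction of motion in a second pass
(falling back to the previous frame's yaw when stationary).  Blobs whose
anisotropy √((μ₂₀−μ₀₂)² + 4μ₁₁²) is below 5% of μ₂₀+μ₀₂ are near-circular:
yaw is undefined, the previous value is carried and the frame flagged
low-confidence.  Blobs touching the image border or the barrier exclusion
region are marked invalid rather than contributing a biased centroid.

Gap decoding segments the bright (open) region inside a fixed ROI at a
threshold midway between panel and floor levels (default 130), takes the
largest component's area A_s and returns d_s = (A_s/A_max)·d_max clipped to
[0, d_max].  This is valid because the gap's vertical extent is constant —
area is proportional to horizontal width.  A_max is calibrated from a
fully-open frame with the same ROI and threshold, which cancels the
rasterised band geometry; on noiseless renders the decoded series tracks
the motion law with RMSE < 1% of d_max (the tested bound is 3%).

When no explicit background frame is available, the background is the
pixelwise median of ~20 frames sampled evenly across the sequence; the
moving insect occupies any given pixel in only a minority of them.

## Virtual mapping

A single overhead camera cannot recover height, so pixels are back-projected
onto the assumed flight plane at mid-tunnel height (z = 0.14 m).  The
mapping is the exact inverse of the projection on that plane (round-trip
re-projection error at machine precision); the systematic error for insects
flying off-plane under an oblique viewing ray is the height-loss limitation
of any planar single-camera rig, and is exercised explicitly in the tests.
Yaw converts between image and world conventions by negation (v down vs y
left).

The mapping-fidelity experiment reports two numbers: the literal
re-projection round trip (≈ 0 by construction, a consistency check) and the
pixel error between the originally detected track and the track re-detected
from a *re-render* of the virtual scene in which the insect model replays
the mapped world trajectory.  The second figure is the meaningful
actual-vs-virtual comparison: it carries the rasterisation and detection
error of the virtual pass (sub-pixel here, well inside the 15 px budget the
protocol allows).

## Geometric optic flow and gap parameters

Viewing directions sit on an azimuth × elevation grid at 5° spacing (the
ommatidial angle), poles excluded so the azimuthal basis is defined.  For
direction d (head frame, x forward, y left, z up), yaw rotation R, hit
distance r and surface velocity V_s from ray casting,

    flow(d) = −ω × d − (T_rel − (T_rel·d) d)/r,   T_rel = T − V_s,

projected on the local azimuth/elevation unit vectors gives (Vx, Vy) in
rad/s; Vx > 0 means environment motion toward increasing azimuth.  Rays
leaving through the open tunnel ends keep only the rotational term
(translational flow vanishes at infinite distance).  Wall, floor and
ceiling are static; each barrier panel edge carries ±v_c/2 laterally.  The
field is exactly linear in (T, ω) at fixed geometry, the rotational part is
distance-free, and pure translation along the heading has a focus of
expansion at the heading — all asserted in tests.

γ is the absolute wrapped difference of the atan2 bearings of the two gap
edges seen from the eye (order-invariant, quadrant-safe); γ̇ uses central
differences (exact for linear γ, one-sided at the ends, default
dt = 1/163 s); RREV = γ̇/γ is flagged undefined (NaN) below γ_eps = 1e−4 rad
rather than clipped, so zero-crossing analyses are not distorted.

## Simulated experiments and problem sizes

* **Speed sweep** — 12 speeds (1–12 m/s) × 20 trials × 3 repetitions, each
  trial a rendered crossing of a 16 × 6 mm high-contrast mock target over
  the 620 mm detector field with a random sub-frame start phase and an
  independent 2% per-frame detection miss probability (emulating real
  camera dropouts so accuracies are not trivially 100%).  Accuracy is the
  fraction of crossings firing exactly once.  The configuration reproduces
  the expected pattern: ≥ 98% up to 7 m/s, ≥ 95% at 8 m/s, collapse above
  ≈ 9.3 m/s where fewer than two detection frames exist.
* **Mapping experiment** — one 163 fps render (~165 frames) of a curved
  1 s flight with lateral scanning at mid-tunnel height.
* **Acquisition harness** — 100 passages at speeds uniform in 0.5–2 m/s
  with 2 cm lateral scanning and the default miss probability.
* **Trajectory statistics** — flight time (last − first timestamp),
  straightness (net displacement / path length) and lateral dispersion
  (RMS perpendicular residual about the principal line through the planar
  path; for a pure sinusoid of amplitude a this is a/√2).  "Straightness"
  and "dispersion" are not uniquely defined in the literature; these are
  the most standard readings and are rigid-motion invariant.  Group
  comparisons use paired two-sided t-tests (α = 0.05 by default,
  configurable), falling back to Welch's unpaired test with a warning when
  group sizes differ.

These sizes keep the full validation (test suite plus acceptance script)
within a few minutes on one CPU while leaving every statistical conclusion
comfortably away from its threshold.

## Known limitations

* Single insect, single camera, 2D: no identity tracking, no height, no 3D.
* The renderer's idealised photometry means real-footage performance
  (lighting, shadows, wing blur) is not bounded by these tests.
* The triangle-wave barrier law assumes ideal gearing (no backlash, no
  ramp-up).
* Luminance-based optic-flow estimation is out of scope: the flow here is
  geometric, computed from known geometry and motion.
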