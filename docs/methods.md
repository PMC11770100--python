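# Methods

## Cardiac model and assumptions

The ventricle of a laterally imaged zebrafish larva is modelled as a filled
ellipse whose long- and short-axis diameters D_L, D_S (µm) vary over the
cardiac cycle. All indices derive from the two diameters:

- Area = ¼·π·D_L·D_S (µm²) — the area of the fitted ellipse;
- Volume = ⅙·π·D_L·D_S² (µm³, reported in nL with 1 nL = 10⁶ µm³) — a
  prolate ellipsoid of revolution about the long axis; this assumes the
  out-of-plane ventricular diameter equals the in-plane short axis;
- FAC = 100·(EDA − ESA)/EDA (%), SV = EDV − ESV (nL/beat), CO = SV·HR
  (nL/min), where end-diastole (ED) and end-systole (ES) are the per-cycle
  area maximum and minimum.

ED/ES are defined on the area series rather than on each axis separately so
that LD and SD are always read at a common frame; with independently timed
axis extrema, Area(ED) could pair a maximal long axis with a non-maximal
short axis and FAC would be inflated. Cycles are delimited by successive
diastolic area maxima; the first and last (incomplete) portions of the
record are discarded, and per-cycle FAC and SV are averaged arithmetically
over the complete cycles. CO is mean SV × HR, which makes CO = SV·HR an
exact identity of every report.

## Heart-rate estimation

The intensity trace is the per-frame mean gray value of a rectangular ROI
(default: the whole frame, which for a centered heart integrates the area
signal and maximizes noise averaging). Processing steps:

1. subtract the trace mean (exact DC rejection);
2. zero-phase Butterworth band-pass, order 4, default 0.2–2 Hz, applied
   forward–backward with Gustafsson's edge handling. With pad-based
   edge handling the filter's slow poles (time constant ≈ 1/low ≈ 5 s) ring
   at the record boundaries and can bury the beats in a 10 s recording;
   Gustafsson's method chooses the edge initial conditions to minimize
   exactly that transient;
3. min–max normalization to [0, 1]; a flat trace raises an error (no
   cardiac signal);
4. peak detection with prominence ≥ 0.2 and separation ≥ 0.2 s (i.e. a
   300 beats/min ceiling), then HR = 60·(n−1)/(t_last − t_first).

The interval-based estimator is used instead of raw count/duration because
the latter is biased by the partial period at each end of the window — up to
±1 beat, i.e. ±6 beats/min on a 10 s record — while the interval form is
exact on periodic signals.

The 0.2–2 Hz default band tops out at 120 beats/min, below the resting rate
of many larvae; the band is therefore a config parameter, and `analyze`
checks the dominant raw-trace frequency (periodogram, before filtering)
against the high cutoff, warning and QC-flagging the report when the beat
sits at or above it. Validation runs that span 100–180 beats/min use a
0.5–5 Hz band (30–300 beats/min).

## Segmentation and ellipse fitting

Frames are smoothed with a Gaussian (σ = 1 px), thresholded with Otsu's
method (dark-object convention, manual override available), and the largest
connected component is taken as the ventricle. The returned edge is the
sub-pixel iso-intensity contour at the threshold level nearest that
component, which on smooth boundaries is accurate to a fraction of a pixel —
pixel-grid boundaries would limit axis accuracy to ~1 px.

Ellipse fitting uses the direct least-squares algebraic conic fit
(scikit-image's `EllipseModel`); on noise-free conic points it recovers the
axes to ~1e-14. D_L ≥ D_S is enforced by swapping axes (rotating the angle
by 90°); angles are degrees from +x toward +y (image coordinates, y down),
reported modulo 180°. A geometric (orthogonal-distance) fit was not needed:
at the contour noise levels the pipeline produces, the algebraic bias is far
below the quantization error already accepted.

Frames where segmentation or fitting fails are gap-flagged (NaN) and
linearly interpolated before cycle detection; the analysis errors out only
when no frame is usable. The M-mode matrix samples gray values bilinearly
along a fixed line (1 px spacing) in every frame, one row per frame.

## Vision chain

Presence detection: 3×3 uniform blur, binarize (Otsu or fixed threshold,
dark-object convention with a polarity flag), largest connected component,
present iff its area ≥ `min_area` (default 50 px²).

Eye segmentation: 3×3 median filter → binarize → erosion → dilation (disk of
radius 1, one iteration each, all configurable). The default threshold is
the lower cut of a three-class Otsu, which separates the eyes from both the
body and the background in a trimodal scene. Components pass gates on area
(5–400 px²) and circularity (4πA/P² ≥ 0.5); the two largest survivors are the
eyes. More than two candidates keep the two largest; a pair wider than a
configurable maximum inter-eye distance is rejected as implausible.

Orientation: the mean eye position and the body centroid are projected onto
the channel-axis unit vector (cos θ, sin θ). Eyes leading the body by more
than a dead-band ε (default 2 px) ⇒ head-forward; trailing ⇒ tail-forward;
otherwise (including zero eyes found) undetermined. The mapping from eye
features to a direction and all kernel sizes/thresholds are this package's
choices — the underlying morphological vocabulary is standard, its
parameterization here is not canonical. The rule is antisymmetric by
construction: mirroring the scene about the axis normal flips the call.

## Dosing model

The droplet (default 5.56 µL) is assumed drug-free before injection and
mixing is assumed complete and instantaneous; no evaporation or dispersion
corrections. V_inj = C_target·V/(S − C_target) then satisfies the forward
mixing equation identically. The Beer–Lambert calibration fits
A = slope·C + intercept by ordinary least squares with the intercept free
(a `through_origin` option gives the constrained fit, which the strict law
implies); R² = 1 − SS_res/SS_tot. Inversion C = (A − intercept)/slope warns
outside the fitted concentration range.

## Synthetic phantoms

The phantoms are the package's validation substrate and define its test
conditions.

**Heart phantom.** A filled dark ellipse (gray 60) on a light background
(gray 200) whose diameters follow a raised cosine between the systolic and
diastolic extremes, D(t) = D_s + (D_d − D_s)(1 + cos 2πft)/2 — smooth, one
extremum per half-cycle, starting at end-diastole. Defaults: 35 frames/s,
10 s, 200×200 px at 1 µm/px, 150 beats/min, diastole 150/100 µm, systole
100/70 µm (giving FAC = 53.3%, SV = 0.529 nL, CO = 79.3 nL/min — the same
order as real larval hearts). Edges are anti-aliased by a first-order
distance estimate so the half-intensity contour lies on the true ellipse;
additive Gaussian noise (sd in gray levels) is clipped to [0, 255]. Ground
truth records the exact per-frame axes and all derived indices, which
satisfy the five formulas to machine precision by construction.

**Larva phantom.** An elongated body ellipse (gray 130) along a channel
axis with two dark circular eyes (gray 40, radius 4 px) offset a signed
distance from the body centroid along the axis — positive offset =
head-forward — on a gray-220 background, plus optional noise.

**Calibration phantom.** A = slope·C + intercept + ε at caller-chosen
concentrations (the validation suite uses 5/20/50/80/110 µM standards).

What the phantoms do **not** emulate: blood-cell texture, the atrium,
pericardial structures, illumination gradients, motion blur, body pigment
patterns, or partial occlusion of the eyes. Passing the phantom suite
demonstrates the correctness of the measurement chain and its noise
robustness at the modelled contrast, not performance on arbitrary real
footage — on real data the segmentation threshold, ROI, band, and
morphology gates may all need tuning, which is why every one is exposed.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical phantoms and byte-identical batch reports
  (serialized outputs contain a config snapshot and package version, never
  timestamps).
- Validation problem sizes — 10 s × 35 fps videos, 200×200 px frames, 200
  orientation scenes, 1,000 dosing triples — are chosen so the full suite
  runs in a few minutes on one core while leaving every recovery margin
  wide (HR to ±0.4 beats/min against a ±3 target, axes to ~0.05 µm against
  a ±2 µm target).
- Cycle detection smooths the area series with a 0.06 s Gaussian before
  peak-finding (prominence 20% of the series range, separation 0.2 s), but
  reads the extrema from the unsmoothed series within each cycle.
- Per-cycle volume ordering (EDV ≥ ESV) is not algebraically guaranteed —
  area extrema order areas, not D_L·D_S² — so violating cycles are skipped
  with a QC flag rather than crashing the report.
- Group summaries report mean ± s.e.m. (sd with ddof = 1 over √n); the
  s.e.m. is undefined for n = 1 and serialized as null. No hypothesis
  testing is performed — the toolkit produces the descriptive summaries
  only.
- Batch failure policy is skip-and-log: one corrupt video does not abort a
  batch; the run errors only when nothing is analyzable.

## Known limitations

- Single-ellipse model: a ventricle that deviates strongly from an ellipse
  (or overlaps the atrium in projection) biases all geometric indices.
- The prolate-ellipsoid volume inherits the out-of-plane symmetry
  assumption; absolute SV/CO are model-dependent even when FAC is robust.
- Heart-rate estimation needs at least two detected beats (~2 s of signal)
  and assumes a quasi-periodic rhythm; arrhythmia classification is out of
  scope.
- The orientation rule needs at least one visible eye and a known channel
  axis; it does not estimate the axis itself.
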