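# Methods

## Signal and model

The observable is the per-frame eye aspect ratio (EAR) of the six eye-contour
landmarks of each eye,

EAR = (‖P2−P6‖ + ‖P3−P5‖) / (2‖P1−P4‖),

with P1/P4 the eye corners and P2,P3 / P6,P5 the upper/lower lid points.  The
numerator distances track lid aperture, the denominator the (nearly constant)
eye width, so the ratio is invariant under similarity transforms of the face
— translation, rotation in the image plane, and distance to the camera.  The
two per-eye ratios are averaged; a blink appears as a rapid dip of the average
EAR from an open baseline toward ~0.

**Classification.** A frame is CLOSED when its average EAR is at or below a
decision threshold, OPEN otherwise; frames with missing landmarks are UNKNOWN
and are excluded from calibration, metrics and run formation.  The decision
rule assigns the boundary case EAR = threshold to CLOSED (the convention is
exposed as a documented constant and covered by tests; the alternative choice
changes nothing at generic float inputs).

**Per-subject calibration (Modified EAR).** Baseline eye openness varies
between subjects, so a universal cut-off (0.2/0.3) is biased for small or
large eyes.  The calibrated threshold is the midpoint of two extreme ratios
assembled from per-term order statistics over the whole recording:
EAR_closed uses the minimal lid distances over the maximal width, EAR_open
the maximal lid distances over the minimal width.  Because every per-frame
numerator term is ≥ its minimum and the denominator ≤ its maximum,
EAR_closed lower-bounds and EAR_open upper-bounds every per-frame EAR
(bracketing), hence EAR_closed ≤ threshold ≤ EAR_open always holds.  Min/max
are exact order statistics; a percentile guard against landmark glitches is a
plausible extension but is off by default to keep the estimator as defined.
With two eyes, the three distance terms are averaged across eyes per frame
before taking extremes (calibrating each eye separately and averaging the
two thresholds is a near-equivalent alternative; for symmetric eyes they
coincide).  When a detector is built from an EAR trace alone, distance terms
are unavailable and auto-calibration uses the trace's EAR min/max midpoint —
identical whenever the corner width is constant, which holds exactly for the
synthetic geometry.

**Blink segmentation.** A blink event is a maximal run of CLOSED frames of
length ≥ `min_consecutive` (default 3 frames).  At 25–30 fps a physiological
blink of 100–400 ms spans roughly 3–12 frames, so 3 suppresses single-frame
noise without losing short blinks; the unit is frames, not seconds, since
multi-second closures are not blinks.  UNKNOWN frames and frame-index gaps
break a run; runs truncated by the trace boundary count if long enough.  Each
event reports start/middle/end; "middle" is the frame of minimum average EAR
within the run (ties → earliest), or the central frame when no trace is
available — both modes are exposed because the two conventions differ only on
asymmetric dips.

## Evaluation protocol

Frame-wise scoring is restricted to frames labelled on both sides (prediction
UNKNOWN or annotation not-visible frames are excluded; this is why "frames
processed" can fall below the raw frame count).  Positive class = closed.
Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R); zero
denominators yield 0 with a warning, matching common tooling.  Macro averages
are unweighted class means; weighted averages use class supports, whence
weighted-average recall equals accuracy exactly in the binary case.  The ROC
AUC is computed from the Mann–Whitney rank statistic of a continuous
closedness score — the negated EAR — with average ranks, so ties count ½ and
the value is invariant under strictly increasing score transforms; it is
undefined (error) for single-class truth.  Blink-level matching pairs
detected events with annotated intervals greedily in start order, a pair
matching on ≥ 1 frame of overlap; with both lists internally disjoint and
sorted this greedy matching attains the maximum, and tests verify it against
exhaustive matching.  The overlap rule is the simplest deterministic choice;
an IoU-based rule would be stricter but needs an arbitrary ratio.

Ground-truth frame labels from annotation files: closed when either eye's
fully-closed (FC) flag is set — the permissive OR reading, switchable to AND
("fully closed" means 90–100 % lid closure); unknown when both eyes carry the
not-visible (NV) flag; open otherwise.  Blink intervals are maximal runs of
records sharing a blink ID.

## Synthetic generator

`simulate_ear_trace` emulates what a landmark tracker yields on a video of a
blinking subject: a baseline at `ear_open_mean` with trapezoidal
close–hold–open dips to `ear_closed_mean` and additive i.i.d. Gaussian noise.
Defaults (chosen once, inside the physiological ranges): 30 fps, 60 s,
12 blinks/min, 200 ms per blink, EAR 0.32 open / 0.08 closed (bracketing the
conventional 0.2/0.3 cut-offs), noise sd 0.01, eye width 50 px.  The number
of events is fixed at round(rate·duration/60) and onsets are uniform with
rejection of overlaps (one open frame enforced between dips), keeping
exact-count recovery well-posed.

Ground-truth events use the **half-amplitude convention** standard in blink
kinematics: an event is the run of frames whose noise-free EAR is at or below
the midpoint of the open and closed levels.  The dip is sized so this run
spans exactly the configured blink duration in frames, with linear ramps of
about a third of the dip on each side; ramp samples sit at fractions
(i−½)/R of the descent so no sample ever falls exactly on the midpoint,
avoiding float ties at the decision boundary.  On a noise-free trace the
calibrated threshold *is* that midpoint, so re-detection reproduces the truth
boundaries exactly — this closure property is what the end-to-end tests
exploit.  Exported annotation files set both FC flags on exactly the
ground-truth closed frames and number blinks consecutively, so frame-level
and event-level truth agree by construction.

What the generator does **not** emulate: landmark jitter correlated in time,
head pose and perspective foreshortening, asymmetric or partial blinks,
illumination- or occlusion-induced dropouts (missing frames can be injected
at the file level), and per-frame eye-width variation.  Passing tests
therefore demonstrate the correctness of the computational pipeline and its
noise robustness at the configured level — not detection performance on real
video, which additionally depends on the upstream landmark detector.

## Numerical and degenerate-input choices

- Zero corner width raises a degenerate-geometry error; EAR never divides by zero silently.
- Calibration requires ≥ 1 valid frame and strictly positive widths; otherwise a calibration error.
- Noisy simulated EARs are clipped at 0 (an aspect ratio cannot be negative).
- AUC with n⁺ or n⁻ = 0 raises; evaluation reports AUC as null in that case rather than failing the whole report.
- All simulation randomness flows through one `numpy` generator seeded from the config.

## Problem sizes

Tests and the acceptance script use one-minute traces at 30 fps (1,800
frames) and 100-replicate noise sweeps; these sizes make every property
exercised (calibration, segmentation, metrics, round-trips) fully observable
while keeping the default suite fast.

## Known limitations

- The pluggable live-detector adapter is a contract only; no camera/Dlib code ships here.
- Per-eye asymmetric thresholds and rolling-window calibration are out of scope (the calibration window is the whole recording, one threshold per video).
- Blink taxonomy (reflex vs spontaneous) and drowsiness scores (PERCLOS) are not computed.
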