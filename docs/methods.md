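# Methods

## Scope and data model

`fieldtrack` analyses overhead video of a single animal in a circular
open-field arena. The central object is the `Trajectory`: strictly
increasing 0-based frame indices with centroid coordinates in image
convention (origin top-left, x = column, y = row, y increasing downward).
All geometry is computed in raw pixels; the spatial scale (mm/pixel) enters
only when results are reported. Tracker files on disk use 1-based frame
numbers; that convention is confined to the parser.

## Segmentation and tracking pipeline

Given an experiment clip and an empty-arena background clip (nominally
640×480 at 25 fps):

* **Spatial binning.** Each frame is block-averaged by an integer factor
  (default 2, giving 320×240). Non-divisible dimensions are an error that
  names the padding required rather than silently cropping.
* **Arena detection and alignment.** The arena floor is a bright disc on a
  dark surround. Each clip's temporal-median frame is thresholded midway
  between its extreme intensities; the largest bright component is accepted
  as the arena only if it fills ≥ 92 % of the circle fitted through its
  centroid and area (a square region fills ≈ 91 %, a pixelated disc ≈ 98 %,
  so this floor separates genuinely circular structure from blocky
  artefacts). The background is translated by the rounded integer difference
  of arena centres; alignment is integer x,y translation only — camera and
  arena do not rotate or rescale between the two clips.
* **Background subtraction.** The background model is the temporal median of
  the aligned background clip — robust to transient noise in a ~10 s clip,
  unlike any single frame. Each experiment frame is reduced to its absolute
  difference from the model.
* **Minimum thresholding.** One global threshold per video is derived from
  the 256-bin intensity histogram pooled over all frames: the histogram is
  repeatedly smoothed with a 3-bin running mean until at most two local
  maxima remain, and the threshold is the valley minimum between them. The
  histogram is padded with an empty bin at each end so a mode at intensity 0
  — always present in a subtracted video, where most pixels are exactly
  background — counts as a maximum. A histogram that never becomes bimodal
  (constant frames, or object contrast too low) is a hard error rather than
  an arbitrary threshold.
* **Anti-aliasing.** Morphological opening (binary erosion then dilation,
  3×3 structuring element, one iteration by default) removes speckle smaller
  than the element — droppings, compression artefacts — while leaving the
  animal-sized blob essentially unchanged.
* **Blob tracking.** Per frame, connected foreground components with area in
  [`min_area`, `max_area`] (defaults 50–5000 binned px², covering an adult
  mouse at 1–4 mm/px) are candidates; the largest is taken as the animal
  (ties break to the lowest centroid (x, y) lexicographically) and its
  centroid becomes the sample. Consecutive detections further apart than
  `max_step` (default 50 binned px) break the track, as do runs of more than
  5 empty frames; gaps of ≤ 5 frames are bridged by linear centroid
  interpolation (downstream differentiation needs a contiguous series), and
  the longest contiguous track wins. More than half the frames empty is a
  tracking failure.

## Movement statistics

All statistics are computed on the downsampled series: every k-th coordinate
(default k = 10, so 25 fps becomes an effective 2.5 samples/s), with any
frame-range restriction applied *before* downsampling (the range is a
user-facing selection on the raw recording; downsampling is a fixed analysis
default). At mouse speeds, 2.5 samples/s keeps genuine locomotion while
suppressing centroid jitter from body shape changes.

* **Distance** is the chord sum of Euclidean increments Δdᵢ; a step with
  Δdᵢ ≤ `stop_epsilon` is a stop, and the stop-time fraction is the stop
  count over the n samples. The default ε = 0 demands exact coordinate
  repetition, which occurs naturally on integer-pixel tracker output;
  sub-pixel centroids rarely repeat exactly, so ε is configurable.
* **Derivatives** use the three-point second-order central stencils with the
  series padded by replicating its first and last value, making endpoint
  derivatives one-sided; interior values are exact for polynomials of degree
  ≤ 2 and O(Δt²) otherwise.
* **Speed** is s·√(ẋ² + ẏ²) per sample. The mean and s.e.m. (sample s.d.
  with the m−1 denominator over √m) are over per-sample instantaneous
  speeds, including stop samples by default (`exclude_stops` gives the
  alternative); total-distance/elapsed-time is also reported, since the two
  estimates differ on stop-and-go paths.
* **Laterality.** Headings negate the y-displacement before `atan2`, so a
  positive turn angle is an anticlockwise heading change in world space —
  the animal's left. Turn angles are wrapped into the half-open interval
  (−π, π] so the backward boundary behaves deterministically: exactly ±π/2
  classifies backward (the rule assumes a forward-moving animal cannot turn
  90° in one step), exactly 0 is straight. Zero-length steps have no heading;
  they carry the previous heading forward and are excluded from
  classification counts. LRatio is the left over right step count (counts
  and time fractions share the denominator, so their ratios are equal); with
  no right step it is reported as +∞ with a flag rather than raising, since
  a perfectly circling animal is a legitimate observation.
* **Curvature radius** is the standard plane-curve osculating-circle radius
  from the same central differences. Denominators below 10⁻⁹ (straight
  segments) give R = +∞; the summary statistic is the mean over finite radii
  (median by config), with the infinite fraction reported separately. A
  fully straight path reports NaN with a flag.
* **ROI occupancy** is the fraction of samples inside each circular region,
  boundary inclusive, on the same downsampled series as every other
  statistic. Up to four ROIs; overlap is allowed and a sample may count
  toward several. The novelty-preference ratio divides the object-2 fraction
  by the object-1 fraction.

## Synthetic calibration

The `synthetic` module emulates a mechanical calibration rig: a mouse-sized
object on a rotor arm, swept around circles of known radius at constant
angular speed. Motion programs (circle, line, stop-and-go, confined random
walk) carry closed-form expectations; the renderer draws the arena disc
(floor 200, surround 30, blob 60 on the 8-bit scale, optional seeded
Gaussian noise) at 320×240 and the calibration harness runs the complete
render → preprocess → track → analyze chain, reporting
100·(1 − |observed − expected|/expected) per parameter.

Chosen conditions, fixed once: arena radius 110 px centred in the 320×240
frame (a 0.9 m arena at ≈ 2 mm/px after binning); three arm radii at 0.27,
0.55 and 0.80 of the arena radius (spanning tight turning to wall-following);
angular speed 0.5 rad/s, giving tangential speeds of 15–44 px/s ≈ 3–9 cm/s —
the range of ordinary adult-mouse locomotion; 800 s of motion rendered
directly at the effective 2.5 frames/s (~2000 frames per video, analysed
with downsample factor 1, so the analysis rate matches the standard
25 fps ÷ 10 configuration); blob radius 8 px; noise-free rendering for the
deterministic calibration, with seeded noise available. A clockwise
repetition of the middle radius checks both turn signs. The expected
distance for a circle is the chord sum (n−1)·2r·sin(|ω|Δt/2), not the arc
length: the tracker measures a polyline, and the comparison should be chord
against chord.

What the synthetic fixtures do not emulate: deformable body shape (the blob
is rigid, so centroid jitter from posture is absent), lighting gradients and
shadows, camera distortion, and occlusion. Passing calibration therefore
demonstrates the correctness of the algorithm chain and its noise floor, not
robustness to every artefact of a real recording; the area-gate, opening
filter and max-step linking are the designed defences for those.

## Numerical choices and degenerate inputs

* Angle wrapping is the closed-form π − mod(π − a, 2π), exact at the ±π
  boundary (−π maps to +π).
* Differentiation requires ≥ 3 samples; downsampling that leaves fewer is an
  explicit error naming the minimum.
* Curvature denominator floor 10⁻⁹ (px/s·px/s² scale) distinguishes genuine
  straightness from floating-point residue.
* Ties between equal-area blobs, exact-boundary ROI membership and the
  Δθ = ±π/2 classification are all resolved by fixed documented conventions
  so repeated runs are byte-identical.
* CSV output uses "." decimals and UTF-8 regardless of locale; all parsers
  accept every file the writers emit, bit-faithfully.

## Known limitations

Single-animal tracking only; no head/tail discrimination, so "left" and
"right" refer to path geometry, not body posture; backward motion is counted
but not further analysed (the classification rule assumes predominantly
forward motion); no trajectory smoothing beyond downsampling; circular ROIs
only; video input is limited to codecs imageio can decode, with numbered-PNG
frame sequences as the always-available path.
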