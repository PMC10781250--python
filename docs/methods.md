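# Methods

## Data model

A motion sequence is an ordered series of frames, each carrying the 3-D
position (normalized image coordinates: x right, y down, both nominally in
[0, 1]; z a unitless relative depth) and a visibility confidence in [0, 1]
for each of up to 33 body landmarks, following the standard full-body
layout of mobile pose-estimation models (nose = 0, shoulders = 11/12,
hips = 23/24, …). Timestamps strictly increase; when a source provides
none, `t = frame_index / fps`. Frames with inconsistent landmark sets are
rejected at load time with the offending frame and indices named — never
silently padded. Serialization uses a fixed-field JSON schema and a wide
CSV dialect (`t, kp00_x … kp32_v`, metadata in `#`-comment headers); both
round-trip losslessly because floats are written at full precision.

Three coordinate conventions are supported: `raw` (image origin),
`hip_centered` (per-frame hip-midpoint subtracted) and
`hip_centered_scaled` (additionally divided by the per-frame torso length).
Hip centering is the scoring default: with image-origin vectors, cosine
similarity mostly measures where the person stands in the frame, not how
they move.

## Cosine scoring

Per frame, each landmark contributes the rescaled cosine similarity
`((x·y)/(‖x‖‖y‖) + 1)/2` between reference and trial position vectors; the
frame mean over included landmarks is compared against the correctness
threshold (default 0.90, strict inequality, on the rescaled scale — a raw
scale option exists). The exercise score is the percentage of correct
frames. Landmarks with zero-length vectors (possible after hip centering)
or below the visibility cutoff are excluded from the mean and counted.

Length mismatch: the reference is linearly resampled to the trial's frame
count and frames pair index-by-index. Two structural consequences, both
verified by the test suite and worth stating plainly:

* a **pure uniform speed change is exactly compensated** by the resampling
  (the resampled reference and the re-timed trial sample identical
  phases), so the cosine score cannot detect it — only DTW can;
* the per-frame mean is **floored by static landmarks**. In a localized
  shoulder exercise most of the 33 landmarks barely move, so the full-body
  frame mean rarely crosses the 0.90 cutoff. Scoring is therefore applied
  segment-wise in the study pipeline (the exercise's target segment is
  what discriminates), mirroring how the validation results are reported
  per head/trunk/shoulder exercise.

## Dynamic time warping

Exact solver: full dynamic programming with the symmetric step pattern
{(1,0), (0,1), (1,1)}, unit weights, no window; local cost is the
Euclidean distance between concatenated landmark coordinates of the paired
frames, after the same normalization convention as cosine scoring.
The recursion is evaluated along anti-diagonals with vectorized updates;
the optimal path is recovered by backtracking (diagonal preferred on
ties). Exactness is checked against brute-force enumeration of all
monotone warping paths on small instances.

Approximate solver: FastDTW-style multiresolution refinement — sequences
are halved recursively (pairwise averaging), the coarse path is projected
up and dilated by the radius (default 1), and the DP is re-solved inside
that window. Because the window restricts the feasible path set, the
approximate distance is always ≥ the exact distance, and a radius at least
the sequence length reproduces the exact solver bit-for-bit. The windowed
DP uses a dense masked matrix: simple and exact, at the cost of the
asymptotic memory advantage (irrelevant at the sequence lengths used
here).

Batch normalization maps raw distances to percentages by the affine rule
`clamp(100·(d − mean)/(max − mean), 0, 100)`: 0 % is anchored at the batch
mean distance, 100 % at the batch maximum. A conventional z-score is
exposed alongside for transparency; the two descriptions are not mutually
consistent (z = 1 is the maximum only when max = mean + 1 sd), and the
printed 0 %/100 % anchors are what the implementation reproduces.
Distances below the mean clamp to 0 because the reported minimum of the
scale is 0 %. Normalization batches are all trials of one
(exercise, method) group, which keeps per-exercise comparisons meaningful.

`warp_cost_bound` gives an analytic upper bound on the DTW distance of any
trial whose frames lie on the reference trajectory (idle lead-in, uniform
re-timing): the monotone merge-by-time alignment pairs frames at most one
local step apart, so its cost is at most
`(n + m) · max_step · max(1, (n−1)/(m−1))`. The timing-robustness tests
assert the DTW distance of such trials stays under this bound while the
frame-paired cosine score drops below 100 % — the rationale for running
both methods.

## Joint-angle comparator

Angles are computed per frame between two lines through anatomical points
(a point is a landmark or a midpoint of landmarks; one line may be the
fixed vertical reference, the −y unit vector). Lines are undirected by
default (`arccos` of the absolute normalized dot product, range [0, 90]);
joint angles with a shared vertex (elbow flexion) use the directed option
(range [0, 180]). Default pairs: trunk line vs vertical; upper arm vs
trunk line; nose–ear line vs trunk line; arm line vs head line.

The angular-agreement score `100·(1 − mean|Δangle|/180)` (series resampled
onto a common normalized time axis, clamped to [0, 100]) condenses two
angle traces to the 0–100 scale of the other methods. It is an explicit
stand-in: how a marker-based lab system's angle traces were historically
condensed to summary scores is not publicly defined, so no reconstruction
is attempted.

## Synthetic exercises

Postures are built from a neutral 33-landmark frontal layout with fixed
segment lengths (upper arm 0.15, forearm 0.14 image units — proportions
that let the hand hang at hip level and reach the opposite hip, as the
standing exercise's start posture requires). Stages blend with the
minimum-jerk profile `6u⁵ − 15u⁴ + 10u³`, smooth with zero end velocity,
so keyframe geometry is met essentially exactly at sampled frames:

* **seated_rotation** — arm abducted 90° to the trunk, elbow flexed 90°;
  forearm externally rotates from horizontal-forward to vertical while the
  trunk twists 15° (pelvis and legs follow with half the twist, keeping
  the body rigid); the end position holds for 3 s; reversal returns to the
  start. Default 240 frames at 30 fps (≈ 8 s: 2.5 s up, 3 s hold, 2.5 s
  down).
* **standing_diagonal** — hand closed beside the opposite hip, elbow
  extended; the arm slerps up across the body while the hand opens,
  peaking at mid-trial with the arm line at exactly 45° to the head line
  (constructed in closed form), then returns.

Perturbations (applied in this order, one seeded generator): range-of-
motion scaling about the per-frame hip midpoint; uniform speed change
(timestamps rescale, frame count adjusts at constant fps); idle lead-in
replicating the start posture; i.i.d. Gaussian coordinate noise;
visibility dropout. Neutral parameters are the identity. Note that
hip-centered cosine similarity is *invariant* to the amplitude scaling
(it preserves vector directions), so amplitude errors are visible to DTW
and the angle comparator but not to the cosine score.

Quality classes are a fixed function of the perturbation magnitudes
(good: noise sd ≤ 0.005 and amplitude in [0.9, 1.1]; poor: noise sd ≥ 0.03
or amplitude ≤ 0.6; degraded otherwise) and exist as ground truth for
separation tests. The default cohort prototypes are good = (0.003, 1.0),
degraded = (0.015, 0.8) and poor = (0.12, 0.55): "poor" models gross
execution error — deviations around 12 % of the image scale with a heavily
reduced range of motion — not sensor jitter, because the cosine frame mean
needs direction changes of tens of degrees before a frame fails the 0.90
cutoff. The timing-robustness condition draws idle lead-ins uniformly from
2–5 s (the time to assume the start posture after triggering recording on
a phone, for an ≈ 8 s exercise) and speed factors from 0.7–1.4.

What the generator does **not** emulate: correlated (smooth) tracking
error, limb occlusion geometry, camera viewpoint changes, perspective
distortion, or biomechanically validated joint dynamics. Passing tests
therefore demonstrate the scoring pipeline's mathematical behavior under
controlled deviations, not clinical validity on real recordings.

## Statistics

Descriptives use the sample (n−1) standard deviation, bias-corrected
Fisher skewness and **excess** kurtosis (normal → 0; a raw-kurtosis option
exists). One-way ANOVA is computed from definitional sums of squares with
p from the F(k−1, N−k) distribution; Tukey HSD uses the studentized-range
distribution with the Tukey–Kramer correction when unbalanced (delegated
to scipy, cross-checked against statsmodels in tests). Significance is
flagged at 0.05. Subjects contribute to every method, but the analysis
deliberately uses plain one-way ANOVA rather than a repeated-measures
model, reproducing the validation study's design; the report carries a
note to that effect.

In the study pipeline the DTW trial-table score is reported as
`100 − normalized_percent` so that, like the other two methods, higher
means closer to the reference.

## Numerical choices and edge cases

* Cosine of zero-length vectors is undefined: excluded per landmark inside
  frame scoring, a hard error for the scalar `cosine_similarity`.
* Batch normalization requires max > mean; a constant batch is a
  degenerate-batch error, not a silent 0.
* DP backtracking prefers the diagonal step on ties, making paths
  deterministic.
* `arccos` loses ~√ε precision at its endpoints; angle assertions near 0°
  or 180° use tolerances of 1e-5 degrees rather than 1e-9.
* Resampling to the current length is the identity by construction, and
  endpoints are preserved exactly.
* Problem sizes: reference sequences default to 240 frames at 30 fps;
  test cohorts use 15–30 subjects and 20 seeds, enough for the rank-based
  and calibration statistics they feed.

## Known limitations

* The cosine method's insensitivity (static-landmark flooring, speed
  compensation, amplitude invariance) is inherent to the published scoring
  rule, not an implementation artifact; the package documents and
  demonstrates it rather than repairing it.
* The angle-agreement score is a stand-in summary, not a reconstruction of
  any proprietary lab metric.
* The seated exercise's target-segment postures differ too little between
  phases for an idle lead-in alone to push cosine frames below the 0.90
  cutoff; the timing-robustness demonstration uses the standing diagonal,
  whose arm sweep is large.
* No video decoding or pose estimation is bundled; the adapter's reference
  backend activates only when the optional packages are installed.
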