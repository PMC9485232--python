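# Methods

## Geometry and the parallax scale

Both cameras are modelled as pinholes sharing intrinsics: focal length
`f` in pixels, principal point at the sensor centre, zero skew, and an
optional two-coefficient Brown radial distortion acting on normalized
coordinates (`x_d = x_u (1 + k1 r² + k2 r⁴)`); undistortion inverts this
by fixed-point iteration to better than 1e-6 px for |k1| ≤ 0.3 within
the unit radius. Camera *b* sits `B` = 0.08 m below camera *a*, so a
point at depth `z` shows a vertical disparity `d = f·B/z` and the metric
size of one pixel at that depth is `z/f` m — equivalently
`s = B·10⁶/d` micron/pixel, independent of `f`. That hyperbola is the
analytic oracle against which the empirical calibration is checked.

The default rig uses square pixels with `f = 3218.7 px` derived from the
54° horizontal field of view of the 3280-px-wide sensor. Deriving the
vertical focal length separately from the nominal 41° vertical FOV would
give 3295 px — a 2.4% pixel anisotropy that is an artefact of rounded
datasheet FOVs, not of the sensor, and that would decouple horizontal
size measurements from vertical disparities. With square pixels the
parallax relation is exact for landmarks in any orientation.
`CameraIntrinsics.from_fov` still supports per-axis derivation for rigs
where the anisotropy is real.

Water refraction is not ray-traced. As in the field procedure, it is
absorbed empirically by calibrating in the operating medium; the rig's
`medium_index` knob (multiplying `f`, ≈1.33 for a flat port in water) is
a synthetic-data convenience for emulating such sessions, not a physical
model.

## Calibration model

Each chessboard landmark pair yields one observation: its translation
(mean stereo disparity of the two endpoints, Euclidean norm — dominated
by the vertical component on this rig, with a vertical-only variant
available) and its scale (known physical separation, an integer number
of 27-mm squares, divided by the pixel separation in the upper frame;
averaging both frames is a config option). `ScaleCalibrator` fits
scale on polynomial features of translation — degree 3 by default, ridge
penalty `alpha` on standardized features with `alpha = 0` (the default)
reproducing the ordinary least-squares cubic. The fitted curve is
checked for strict positivity and reported with its training R², the
observation count, the residual standard deviation (from which
approximate normal-theory prediction bands are drawn; the exact band
construction used in the field study is unspecified, so ours is
documented as approximate), and a validity range whose lower edge is the
140-px threshold. Queries outside the range extrapolate with a warning
rather than fail, because field translations can slightly exceed the
calibrated span. R² with a constant response is reported as undefined
(`None`), never silently as 0.

**A deliberate limitation:** a cubic polynomial cannot represent the
hyperbola `B·10⁶/d` to better than a few percent over a wide disparity
span — over 140–600 px (a 4.3× range) the best-case relative error is
≈3% and the least-squares fit reaches ≈6–7% at the far (small-scale)
end, concentrated at the closest targets. Over a moderate span such as
140–320 px the cubic is accurate to well under 1%, which is the regime
the sub-percent recovery tests use. In jittered sessions the lack of fit
is small against the landmark noise (training R² ≈ 0.996 at the default
2-px jitter) and the end-to-end silhouette error stays near 2–3% MAPE;
users wanting wide-span accuracy should raise `degree` (degree 5 is
≈1% over 140–600 px), which the estimator supports directly.

## Length and weight

A fish's pixel length is the snout-to-caudal-base Euclidean distance in
the upper frame; its translation is the mean of the two landmarks'
disparities. Fish with translation below 140 px (inclusive threshold:
exactly 140 passes) are discarded as too distant — the threshold
partitions any batch exactly and the QC reason is recorded per fish.
Standard length in cm is `pixel_length × scale / 10⁴` with scale in
micron/pixel. No pose correction is applied: a fish yawed by θ projects
a body segment foreshortened by cos θ, so unposed estimates are biased
low, never high, under zero noise — this is documented (and reproduced
by the synthetic yaw knob, which visibly inflates the dispersion of
estimated lengths) rather than corrected.

Validation against targets of known length reports two statistics
together: mean absolute error in cm and mean absolute percentage error
(% of body length), since the method's accuracy is quoted under both
conventions.

Weight uses the allometric relationship `W = a·SLᵇ`, fit by OLS of
log W on log SL with `a = exp(intercept)`; R² is reported on the log
scale, the scale of the fit. No back-transform bias correction is
applied by default; `bias_correction=True` multiplies predictions by the
log-normal smearing factor `exp(σ²/2)`. Reference coefficients for
farmed seabream, `a = 0.1342`, `b = 2.5465`, are used as synthetic
defaults. (Published accounts of the underlying field sample give its
size variously as 190, 198 and 200 fish; the synthetic default is
n = 190 and the discrepancy is noted here rather than resolved.)

## Distribution comparison

The sampled-vs-estimated comparison runs a fixed, auditable cascade:
Shapiro–Wilk per group, Levene across groups (median-centred
Brown–Forsythe by default, mean-centred configurable), then a Welch test
if Levene rejects homogeneity at α = 0.05 and a pooled-variance test
otherwise, with the branch recorded. The two-group statistic is reported
in its F form (t²), the convention for Welch one-way comparisons.
Percentage mean difference is `|sampled − estimated| / estimated × 100`,
i.e. relative to the image-estimated mean — the convention pinned down
by the reference weight pair (21/585 = 3.59% rounds to the reported
3.6%, whereas /606 would give 3.5%). Q-q pairs evaluate both groups'
type-7 quantiles at the plotting positions `(i−1)/(n−1)` of the smaller
group; histograms use half-open integer-edged 1-cm bins `[k, k+1)`.
Constant groups mark the tests not-applicable instead of erroring.

## Synthetic data: what it emulates, and what it does not

Generators draw all randomness from a single integer seed
(`numpy.random.default_rng`) and emit paired annotation/truth tables so
downstream statistics can be scored exactly.

- **Chessboard sessions** (default 52 poses × 4 pairs = 208
  observations): fronto-parallel boards with pose depths sampled
  uniformly in *disparity* over the configured band — a calibration
  session's purpose is even coverage of the working translation range,
  and uniform-in-distance sampling would crowd the far field and leave
  the near field uncalibrated. Landmark pairs span 3–7 squares
  horizontally; each projected corner is jittered by isotropic Gaussian
  noise (`landmark_jitter_sd`, default 2 px). Poses are resampled until
  the widest pair fits in frame.
- **Silhouette batches** (default 17 images × 4 lengths of 22.0, 24.2,
  29.0 and 33.6 cm): fronto-parallel at linearly increasing distances
  across the configured range; silhouettes whose true disparity falls
  below 140 px are kept but flagged, so they exercise the QC path.
- **Populations**: SL ~ Normal(27.1, 1.6²) cm truncated at >5 cm,
  n = 190 by default; weights `a·SLᵇ` times unit-mean log-normal noise
  with CV `weight_noise_cv` (default 0.05 — a modest individual
  condition spread).
- **Fish scenes**: each fish gets a uniform depth, a Normal(0, yaw_sd)
  yaw (foreshortening the projected segment by cos yaw), a random
  lateral position, and jittered landmarks. The `field_scene_config`
  preset (depths 0.3–3.6 m, 25° yaw sd) loses roughly half its fish to
  the 140-px filter, mirroring realistic cage acquisition; the default
  validation geometry spans the calibrated disparity band instead.

The 2-px jitter stands in for the landmark CNN's localisation error,
whose pixel-scale magnitude is not published; it is a free knob, chosen
as a plausible figure for a trained keypoint model at this resolution,
and the headline synthetic error rates are conditional on it. Fish are
line segments (two landmarks), not rendered bodies — detection and
landmark CNNs are out of scope, so no other pixel carries information.
Consequently, passing tests demonstrate the correctness of the
geometry, calibration, filtering and statistics, and the error budget of
jittered landmarks; they say nothing about detector recall, landmark
error on real imagery, occlusion, turbidity, fish curvature, or
refraction beyond its empirical absorption into calibration.

## Numerical choices and degenerate inputs

Distortion inversion: fixed-point iteration, tolerance 1e-12 on
normalized coordinates, 100-iteration cap, explicit error on
non-convergence or non-positive radial factor. Calibration fitting
requires more observations than polynomial parameters and non-constant
translations (rank error otherwise). Zero pixel separations and
incomplete stereo correspondences are skipped with logged warnings, not
errors. The threshold comparison is inclusive (≥140). Degenerate fish
landmarks (zero pixel length) fail QC with a reason rather than raising.
Seeds derived from a master seed stay below 2³¹.

## Problem sizes

Default test and validation runs use the study-scale geometry — 208
calibration observations, 68 silhouette measurements, populations of
tens to 190 fish — which keeps the whole suite in a few seconds while
matching the sample sizes the validation analogues are defined at.
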