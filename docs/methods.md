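# Methods

## Problem

Deep-learning spine-alignment tools are usually trained on radiographs from a
single hospital. When deployed elsewhere they meet systematically different
pixel-intensity distributions — different detectors, exposure protocols and
post-processing shift brightness, contrast and gamma — and their accuracy
degrades. `spineharm` implements a lightweight remedy: a real-time,
unsupervised, per-image intensity transformation that aligns each image's
empirical intensity distribution to a reference distribution, plus the
geometric (Cobb angle) and statistical (agreement, classification) machinery
needed to quantify spinal alignment and evaluate such a system, and a
synthetic multicenter benchmark to exercise everything without patient data.

## Intensity profiles

An image with bit depth *b* is summarized by a profile over *L* equal-width
intensity bins (default *L* = 256, regardless of bit depth; 16-bit images are
binned, which keeps transfer maps compact):

* histogram *h(k)*, normalized to sum 1, and its CDF *F(k)*;
* **brightness** = mean(pixel / (2^b − 1)) × 255 — the mean intensity on the
  conventional 0–255 display scale;
* **spread** = population SD of pixel / (2^b − 1) — a contrast surrogate on
  the normalized [0, 1] scale.

The two descriptors deliberately live on different scales (0–255 vs [0, 1]);
both are documented on the type to avoid unit confusion. The population
(rather than sample) SD is used because an image is the complete population
of its own pixels. The exact normalization behind published spread figures
for real cohorts is rarely stated; the [0, 1]-scale population-SD definition
above is this package's documented convention, and cross-study comparisons of
absolute spread values should account for it.

Cohorts are pooled by pixel-count-weighted averaging of histograms;
brightness and spread of a pooled profile are recomputed from the pooled
histogram with bin centers (k + 0.5)/L as representative values, so pooled
and per-image descriptors agree to within one bin width.

Heterogeneity between two profiles is reported as the pair
(|Δbrightness|, |Δspread|) — a pseudometric used to quantify inter-center
differences before and after harmonization.

## The transfer map

Given source CDF F^S and reference CDF F^T over the same *L* levels, each
occupied source level *s* (h^S(s) > 0) is mapped to

    map[s] = argmin_t | F^S(s) − F^T(t) |

with ties broken to the smallest *t* (a deterministic, reproducible choice).
Unoccupied levels are filled by linear interpolation between the nearest
occupied neighbours (held flat beyond the ends) so the lookup table is total
and robust to unseen levels at apply time, and a cumulative maximum enforces
monotonicity. Because F^S is non-decreasing and the tie-break is consistent,
the argmin itself is already monotone on occupied levels; the cumulative
maximum is a guard, not a correction.

Whether the underlying optimization should be read as an exact CDF match or
a global objective beyond the per-level argmin is an open design point; the
per-level argmin with monotone repair is the documented reading here, and the
brute-force argmin over all level pairs serves as an independent test oracle.

Applying the map is a pure per-pixel table lookup followed by rescaling the
level index to the image's bit depth. Consequences, each verified by tests:

* **No spatial distortion** — geometry is untouched; only intensities move.
* **Rank preservation** — a monotone lookup never inverts the order of two
  pixel values.
* **Alignment bound** — the output CDF matches the reference CDF to within
  the largest single-bin mass of the source histogram (the discretization
  limit of any histogram-matching scheme).
* **Idempotence up to quantization** — a second pass against the same
  reference changes no pixel by more than one level.
* **Complexity** — one histogram pass plus a lookup: O(n log n) in pixel
  count n (the log factor bounds the sort-free binning bookkeeping; in
  practice the histogram pass dominates and scales linearly).

The reference may be a single image's profile or a pooled center profile. A
packaged default reference (the pooled profile of the synthetic internal
training cohort, `data/default_reference.json`, version 1) supports
calibration-free operation; any profile can be supplied instead.

## Training augmentation

The augmentation protocol mirrors multicenter fine-tuning: each training
image is transformed `transforms_per_image` times, each time against a single
reference image drawn uniformly at random from a uniformly chosen center
pool (single-image references, not pooled ones, to preserve transformation
diversity); originals are mixed in unweighted when requested, and the output
order is a seeded shuffle. Per-draw randomness is derived from
(seed, image index, copy index), so extending the image list does not perturb
earlier draws, and identical seeds give bit-identical outputs.

## Cobb geometry

Endplate slopes come straight from the 72-landmark scheme: slope =
atan2(y_right − y_left, x_right − x_left) in the y-down raster convention.
An endplate is treated as an **undirected line**, so slopes are folded into
[−90°, 90°) modulo 180°; this keeps slopes well defined under arbitrary
rotations of the landmark set, and rotation covariance (all slopes shift by
the rotation angle, Cobb angles unchanged) then holds exactly in mod-180
arithmetic. The Cobb angle of a vertebra pair is the acute angle between the
upper vertebra's superior endplate line and the lower vertebra's inferior
endplate line — the classical construction — and therefore lies in [0°, 90°].

Curve detection is exhaustive: the primary curve is the maximal-Cobb pair
over all 153 ordered vertebra pairs; the cranial and caudal segments
*strictly outside* the primary curve (excluding its end vertebrae) are then
searched recursively for additional curves of at least 10°, the conventional
radiographic floor for calling a scoliotic curve. The apex of a curve is the
vertebra whose 4-corner centroid deviates most, perpendicular to the chord
joining the end-vertebra centroids — deterministic and resolution
independent. Curves are reported cranial→caudal.

Classification rules:

* **Curve type** — apex at T1–T11: thoracic; apex at T12–L5:
  thoracolumbar/lumbar. C7 (never assigned by the clinical rule) maps to
  thoracic as the conservative cranial extension.
* **Severity** — [0°, 20°] normal-mild, (20°, 40°] moderate, (40°, ∞)
  severe. Published descriptions of this grading are ambiguous exactly at
  20° and in the 40–41° gap; the closed/half-open partition above grades
  every angle exactly once and resolves 40° < x as severe. Users comparing
  against other implementations should check the boundary convention.

Both `find_curves` per-curve angles and the per-patient maximum
(`max_cobb`) are exposed.

## Evaluation statistics

For paired predicted/ground-truth angles: MAE and the sample SD (ddof 1) of
absolute errors; quartiles/IQR of the absolute errors by linear interpolation
(the "type 7" rule), with signed-error quartiles available via
`quartiles_of="signed"`; R² from OLS of ground truth on predictions
(predictions on the x-axis); Bland–Altman bias with 95% limits of agreement
bias ± 1.96 × SD(differences) (sample SD). The report's `t_stat`/`p_value`
are the one-sample paired t of the signed differences against zero (the bias
test); `paired_error_test` provides the two-model comparison (classical
paired t on the difference of absolute errors, two-sided, n − 1 df).

Classification metrics are one-vs-rest per class — sensitivity TP/(TP+FN),
specificity TN/(TN+FP), precision TP/(TP+FP), NPV TN/(TN+FN), accuracy
(TP+TN)/n — each with a 95% Wilson score interval (Clopper–Pearson
selectable; Wilson is the default because score-type intervals are the
common choice for such report tables). Metrics with empty denominators are
reported as undefined-with-reason, never silent NaN; macro averages are
unweighted means over the classes where the metric is defined.

## Synthetic benchmark

`generate_phantom` renders 18 vertebral bodies as bright rotated rectangles
over a smooth soft-tissue gradient with mild low-frequency texture, peak
intensity ≤ 235 (headroom for additive brightness distortions without
clipping). Realism is deliberately minimal: the harmonization method sees
only intensity distributions and the geometry needs only valid landmarks, so
photorealism would add no test power. Each requested curve prescribes
per-vertebra endplate tilts directly — a half-sine ramp from +Cobb/2 at the
upper end vertebra through 0 at the apex to −Cobb/2 at the lower end
vertebra (extent: apex ± 3 vertebrae) — and vertebra centers integrate the
tilts into a smooth midline. The emitted landmarks are the exact float
corners of the rendered rectangles, so measured Cobb angles equal targets to
machine precision and apexes are recovered exactly; curve extents must not
overlap (enforced), and adjacent curves must alternate direction.

`apply_center_profile` distorts normalized intensities x by
clamp(contrast × (x^gamma − 0.5) + 0.5 + offset/255 + ε), ε ~ N(0,
(noise_sd/255)²), seeded per (profile, image), then requantizes. Without
noise the distortion is monotone, so it composes cleanly with the
rank-preservation properties of the transform.

The default benchmark has the shape of a multicenter validation study: one
"internal" reference center (identity distortion + mild noise) and five
"external" centers with distinct gamma/offset/contrast fingerprints (gamma
0.85–1.25, offsets +4 to +18 on the 0–255 scale, contrast 0.85–1.2, noise SD
2–4). These defaults put the pooled internal-vs-external brightness
difference in the high single digits on the 0–255 scale — the order observed
between real hospital cohorts — so the harmonization step has realistic work
to do. What the phantoms do **not** model: scanner physics, scatter,
stitching artifacts, anatomical variation beyond curve geometry, or
cross-modality differences; passing tests therefore demonstrate the
correctness of the algorithms under controlled distribution shift, not
clinical performance on real radiographs.

## Numerical choices and degenerate inputs

* Level binning is exact integer arithmetic: level = ⌊pixel·L / 2^b⌋ (the
  identity when L = 2^b); level → intensity uses round(level·(2^b−1)/(L−1)).
* Interpolated (unoccupied-level) map entries are rounded half-up before the
  cumulative maximum; occupied entries keep their exact argmin values.
* Empty images, empty reference pools, mismatched `n_levels`, zero-variance
  predictors, all-identical paired differences, coincident endplate corners,
  and infeasible phantom specs all raise typed errors rather than producing
  silent NaNs.
* Landmark CSVs are written with `%.17g` and parsed with pandas'
  round-trip float parser, so write→read is bit-exact.
* The sup-above-inf landmark orientation check allows 2 px of slack to admit
  near-degenerate endplates at low resolution.

## Problem sizes used in the checks

The bundled verification runs use: 100 small random instances for the
transfer-map oracle; 50 random 128×128 image pairs for the alignment,
monotonicity and idempotence properties; the 6-center × 30-image benchmark
for heterogeneity reduction; 50 random phantoms for Cobb recovery; and 10⁵
Gaussian differences for limits-of-agreement coverage. These sizes give
stable statistics while keeping a full run in well under a minute on one
core.

## Known limitations

* Harmonization is within-modality only; it does not address resolution,
  class imbalance, or content-level quality problems.
* The severity and curve-type boundary conventions are documented choices at
  clinically ambiguous edges (see above).
* Brightness/spread are global descriptors; no per-region (vertebra-masked)
  profiling is provided.
* The landmark detector itself (the deep-learning component of a full
  pipeline) is out of scope: geometry starts from given landmarks.
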