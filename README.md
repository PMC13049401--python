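# spineharm

Intensity-distribution harmonization and Cobb-angle analysis for multicenter
whole-spine radiographs.

Automated assessment of adolescent idiopathic scoliosis (AIS) hinges on the
Cobb angle (CA) measured from posteroanterior whole-spine radiographs. Models
trained at one hospital degrade at others because detectors, exposure
protocols and post-processing shift each center's pixel-intensity
distribution. `spineharm` provides, for researchers and engineers building or
evaluating such pipelines:

* **Harmonization** — a real-time, unsupervised transformation that aligns a
  source image's intensity CDF to a reference. For source CDF *F<sup>S</sup>*
  and reference CDF *F<sup>T</sup>*, each occupied intensity level *s* maps to

  &nbsp;&nbsp;&nbsp;&nbsp;map(s) = argmin<sub>t</sub> |F<sup>S</sup>(s) − F<sup>T</sup>(t)|

  with a monotone lookup table (no spatial resampling, pixel rank order
  preserved), O(n log n) in the pixel count, plus the multi-reference
  training-augmentation protocol built on it.
* **Geometry** — endplate slopes, Cobb angles, exhaustive curve detection
  with apex localization, curve-type (thoracic vs thoracolumbar/lumbar) and
  severity (normal-mild / moderate / severe) grading from the standard
  72-landmark scheme (18 vertebrae C7–L5 × 4 endplate corners).
* **Evaluation** — residual statistics, R², Bland–Altman 95% limits of
  agreement, paired t tests, and confusion-matrix metrics (sensitivity,
  specificity, precision, NPV, accuracy) with Wilson 95% CIs and macro
  averages.
* **Synthetic benchmark** — phantom spines with exactly known landmark
  ground truth and per-center intensity distortions (gamma, brightness,
  contrast, noise), so the whole pipeline is testable without patient data.

Inputs: 8/16-bit PNG/TIFF or monochrome DICOM images; landmark CSV
(`vertebra,corner,x,y`) or JSON; angle tables as CSV. See
[`docs/methods.md`](docs/methods.md) for the model, conventions and
limitations.

## Worked example

```python
from spineharm import (SpinePhantomSpec, CurveSpec, CenterProfile,
                       generate_phantom, apply_center_profile, compute_profile,
                       harmonize, find_curves, profile_distance)

# a phantom "patient" with a 32-degree right thoracic curve, imaged twice
spec = SpinePhantomSpec(curves=[CurveSpec("T8", 32.0, "right")], seed=7)
internal, landmarks = generate_phantom(spec)
external = apply_center_profile(
    internal, CenterProfile("EXT", gamma=0.85, brightness_offset=14.0,
                            contrast_scale=1.15, noise_sd=3.0, seed=102))

ref = compute_profile(internal)                 # reference distribution
b_ext, s_ext = profile_distance(compute_profile(external), ref)
harmonized = harmonize(external, ref)           # fit + apply the transfer map
b_h, s_h = profile_distance(compute_profile(harmonized), ref)
print(f"brightness gap to reference: {b_ext:.2f} -> {b_h:.2f}")
print(f"spread gap to reference:     {s_ext:.4f} -> {s_h:.4f}")

for c in find_curves(landmarks):
    print(f"{c.upper_end_vertebra}-{c.lower_end_vertebra} (apex {c.apex_vertebra}): "
          f"{c.cobb_deg:.1f} deg, {c.curve_type}, {c.severity}")
```

Output:

```
brightness gap to reference: 22.94 -> 0.09
spread gap to reference:     0.0159 -> 0.0000
T5-T11 (apex T8): 32.0 deg, thoracic, moderate
```

The external center's acquisition chain shifted mean brightness by ~23 units
on the 0–255 scale and changed contrast; one harmonization pass closes both
gaps to the discretization limit. The landmark geometry recovers the
constructed 32° curve exactly, grades it moderate (20°–40°], and types it
thoracic (apex T8 lies in T1–T11).

The same operations are available from the shell:

```bash
spineharm synth --out-dir bench/ --n-per-center 30 --seed 7
spineharm profile bench/INT_*.png --pool --json internal.json
spineharm transform --reference ref.png input.png harmonized.png
spineharm cobb --landmarks bench/INT_000_landmarks.csv
spineharm evaluate --pred pred.csv --gt gt.csv --json report.json
```

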