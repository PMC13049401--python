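"""Synthetic multicenter spine-radiograph benchmark.

Generates phantom posteroanterior whole-spine images with exactly known
endplate-landmark ground truth, and per-center intensity distortions
(gamma, brightness offset, contrast scaling, additive Gaussian noise) that
emulate the inter-center heterogeneity of real multicenter radiograph
cohorts. Harmonization, geometry and evaluation are all testable against
these phantoms with no external data.

Phantom realism is deliberately minimal — bright rotated rectangles for the
18 vertebral bodies over a smooth soft-tissue gradient — because the
harmonization method operates on intensity distributions and the geometry
needs only valid landmarks; photorealism would add no test power.

Each requested curve prescribes per-vertebra endplate tilts directly: the
tilt ramps (half-sine) from +Cobb/2 at the upper end vertebra through zero
at the apex to -Cobb/2 at the lower end vertebra, so the Cobb angle measured
from the emitted landmarks equals the target up to floating-point precision,
and the apex is the extremum of the lateral midline deviation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon

from .errors import GenerationError, ValidationError
from .imgio import (
    CORNERS,
    VERTEBRAE,
    GrayImage,
    LandmarkSet,
    vertebra_index,
    write_image,
    write_landmarks,
)

MANIFEST_COLUMNS = ("image", "landmarks", "center_id", "curve_index", "apex", "gt_cobb")


@dataclass
class CurveSpec:
    """One requested scoliotic curve of a phantom."""

    apex: str
    cobb_deg: float
    direction: str  # "left" or "right" convexity

    def __post_init__(self) -> None:
        vertebra_index(self.apex)
        if not 0.0 <= self.cobb_deg <= 90.0:
            raise ValidationError(f"target Cobb outside [0, 90]: {self.cobb_deg}")
        if self.direction not in ("left", "right"):
            raise ValidationError(f"direction must be 'left' or 'right', got "
                                  f"{self.direction!r}")


@dataclass
class SpinePhantomSpec:
    """Geometry of one phantom: image size, requested curves, vertebra size."""

    image_shape: tuple[int, int] = (448, 224)  # (height, width) pixels
    curves: list[CurveSpec] = field(default_factory=list)
    vertebra_width: float = 26.0
    vertebra_height: float = 12.0
    half_span: int = 3  # vertebrae between apex and each end vertebra
    seed: int = 0

    def __post_init__(self) -> None:
        idxs = [vertebra_index(c.apex) for c in self.curves]
        if any(b <= a for a, b in zip(idxs, idxs[1:])):
            raise ValidationError("curve apexes must be strictly ordered cranial→caudal")
        dirs = [c.direction for c in self.curves]
        if any(a == b for a, b in zip(dirs, dirs[1:])):
            raise ValidationError("adjacent curves must alternate direction")
        if self.half_span < 1:
            raise ValidationError("half_span must be >= 1")


def _vertebra_tilts(spec: SpinePhantomSpec) -> np.ndarray:
    """Per-vertebra endplate tilt angles (degrees) realizing the target curves."""
    n = len(VERTEBRAE)
    tilts = np.zeros(n)
    prev_lower = -1
    for c in spec.curves:
        a = vertebra_index(c.apex)
        u = a - spec.half_span
        l = a + spec.half_span
        if u < 0 or l > n - 1:
            raise GenerationError(
                f"curve at {c.apex} with half_span {spec.half_span} runs off the spine"
            )
        if u <= prev_lower:
            raise GenerationError(
                f"curve at {c.apex} overlaps the previous curve's extent"
            )
        prev_lower = l
        sign = 1.0 if c.direction == "right" else -1.0
        half = c.cobb_deg / 2.0
        for v in range(u, l + 1):
            if v <= a:
                frac = (a - v) / (a - u)
            else:
                frac = -(v - a) / (l - a)
            tilts[v] = sign * half * np.sin(np.pi / 2.0 * frac)
    return tilts


def _layout(spec: SpinePhantomSpec,
            tilts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vertebra center coordinates: y on a fixed grid, x integrating the tilts."""
    h, w = spec.image_shape
    margin = 0.08 * h
    ys = margin + np.arange(len(VERTEBRAE)) * (h - 2 * margin) / (len(VERTEBRAE) - 1)
    dy = ys[1] - ys[0]
    xs = np.zeros(len(VERTEBRAE))
    for v in range(len(VERTEBRAE) - 1):
        mid = np.radians((tilts[v] + tilts[v + 1]) / 2.0)
        xs[v + 1] = xs[v] + dy * np.tan(mid)
    xs = xs - xs.mean() + w / 2.0
    radius = float(np.hypot(spec.vertebra_width, spec.vertebra_height)) / 2.0
    if xs.min() < radius + 2 or xs.max() > w - 1 - radius - 2:
        raise GenerationError(
            "requested curves push vertebrae outside the image; enlarge the image "
            "or reduce the target angles"
        )
    return xs, ys


def _corners(cx: float, cy: float, tilt_deg: float,
             width: float, height: float) -> dict[str, tuple[float, float]]:
    """The four endplate corners of a vertebral body rotated by its tilt."""
    t = np.radians(tilt_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    offsets = {
        "sup_left": (-width / 2.0, -height / 2.0),
        "sup_right": (width / 2.0, -height / 2.0),
        "inf_left": (-width / 2.0, height / 2.0),
        "inf_right": (width / 2.0, height / 2.0),
    }
    out = {}
    for name, off in offsets.items():
        d = rot @ np.asarray(off)
        out[name] = (cx + float(d[0]), cy + float(d[1]))
    return out


def generate_phantom(spec: SpinePhantomSpec,
                     source_id: str | None = None) -> tuple[GrayImage, LandmarkSet]:
    """Render a phantom radiograph and its exact landmark ground truth.

    The emitted landmarks are the exact (floating-point) corner positions of
    the rendered vertebral rectangles, so measured endplate slopes equal the
    prescribed tilts to machine precision. The image is 8-bit with peak
    intensity kept at or below 235, leaving headroom for additive brightness
    distortions without clipping. Same seed → bit-identical output.
    """
    tilts = _vertebra_tilts(spec)
    xs, ys = _layout(spec, tilts)
    h, w = spec.image_shape
    sid = source_id if source_id is not None else f"phantom-{spec.seed}"

    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = 48.0 + 58.0 * yy / (h - 1) - 18.0 * ((xx - w / 2.0) / (w / 2.0)) ** 2
    img += gaussian_filter(rng.standard_normal((h, w)), 9.0) * 22.0  # soft-tissue texture

    points: dict[tuple[str, str], tuple[float, float]] = {}
    for v, label in enumerate(VERTEBRAE):
        corners = _corners(xs[v], ys[v], tilts[v], spec.vertebra_width,
                           spec.vertebra_height)
        for c in CORNERS:
            points[(label, c)] = corners[c]
        poly = np.array([corners["sup_left"], corners["sup_right"],
                         corners["inf_right"], corners["inf_left"]])
        rr, cc = polygon(poly[:, 1], poly[:, 0], shape=(h, w))
        img[rr, cc] = 170.0 + float(rng.uniform(-8.0, 8.0))

    img = gaussian_filter(img, 1.2)
    img = np.clip(np.rint(img), 0, 235).astype(np.uint8)
    gray = GrayImage(pixels=img, bit_depth=8, source_id=sid)
    lm = LandmarkSet(image_id=sid, points=points)
    lm.validate(image=gray)
    return gray, lm


@dataclass
class CenterProfile:
    """Intensity distortion fingerprint of one imaging center."""

    center_id: str
    gamma: float = 1.0
    brightness_offset: float = 0.0  # on the 0-255 scale
    contrast_scale: float = 1.0
    noise_sd: float = 0.0  # on the 0-255 scale
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.25 <= self.gamma <= 4.0:
            raise ValidationError(f"gamma outside [0.25, 4]: {self.gamma}")
        if not 0.25 <= self.contrast_scale <= 4.0:
            raise ValidationError(f"contrast_scale outside [0.25, 4]: "
                                  f"{self.contrast_scale}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0: {self.noise_sd}")


def apply_center_profile(img: GrayImage, cp: CenterProfile) -> GrayImage:
    """Distort an image the way one center's acquisition chain would.

    On normalized intensities x in [0, 1]:
    ``clamp(contrast * (x**gamma - 0.5) + 0.5 + offset/255 + eps)`` with
    ``eps ~ N(0, (noise_sd/255)^2)``, then requantized to the bit depth.
    Noise is seeded from the profile seed and the image's source tag, so a
    given (profile, image) pair is reproducible. With the identity profile
    (gamma 1, contrast 1, offset 0, noise 0) the output equals the input.
    """
    x = img.pixels.astype(np.float64) / img.max_value
    y = cp.contrast_scale * (x**cp.gamma - 0.5) + 0.5 + cp.brightness_offset / 255.0
    if cp.noise_sd > 0:
        rng = np.random.default_rng([cp.seed, zlib.crc32(img.source_id.encode())])
        y = y + rng.normal(0.0, cp.noise_sd / 255.0, size=y.shape)
    y = np.clip(y, 0.0, 1.0)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    out = np.rint(y * img.max_value).astype(dtype)
    return GrayImage(pixels=out, bit_depth=img.bit_depth, source_id=img.source_id)


def default_center_profiles() -> list[CenterProfile]:
    """The packaged 6-center benchmark: 1 "internal" reference center plus 5
    "external" centers with distinct gamma/offset/contrast fingerprints, the
    shape of a multicenter validation design."""
    return [
        CenterProfile("INT", gamma=1.0, brightness_offset=0.0, contrast_scale=1.0,
                      noise_sd=2.0, seed=101),
        CenterProfile("EXT1", gamma=0.85, brightness_offset=14.0, contrast_scale=1.15,
                      noise_sd=3.0, seed=102),
        CenterProfile("EXT2", gamma=1.25, brightness_offset=4.0, contrast_scale=0.85,
                      noise_sd=4.0, seed=103),
        CenterProfile("EXT3", gamma=0.9, brightness_offset=18.0, contrast_scale=1.05,
                      noise_sd=2.5, seed=104),
        CenterProfile("EXT4", gamma=1.15, brightness_offset=6.0, contrast_scale=0.9,
                      noise_sd=3.5, seed=105),
        CenterProfile("EXT5", gamma=1.1, brightness_offset=10.0, contrast_scale=1.2,
                      noise_sd=3.0, seed=106),
    ]


def default_spec_sampler(rng: np.random.Generator) -> SpinePhantomSpec:
    """Sample a realistic phantom spec: one curve (55%) or an alternating
    double curve (45%), apexes spanning the thoracic and thoracolumbar/lumbar
    regions, primary Cobb 12–48 degrees."""
    first_dir = "right" if rng.random() < 0.5 else "left"
    other = "left" if first_dir == "right" else "right"
    if rng.random() < 0.55:
        apex = int(rng.integers(4, 14))  # T4 .. L1
        curves = [CurveSpec(VERTEBRAE[apex], float(rng.uniform(12.0, 48.0)), first_dir)]
    else:
        gap = int(rng.integers(7, 9))
        apex1 = int(rng.integers(4, min(8, 15 - gap)))
        apex2 = apex1 + gap
        cobb1 = float(rng.uniform(20.0, 48.0))
        cobb2 = float(rng.uniform(11.0, min(cobb1 - 3.0, 30.0)))
        curves = [CurveSpec(VERTEBRAE[apex1], cobb1, first_dir),
                  CurveSpec(VERTEBRAE[apex2], cobb2, other)]
    return SpinePhantomSpec(curves=curves, seed=int(rng.integers(2**31)))


def make_multicenter_benchmark(
    out_dir: str | Path,
    n_per_center: int = 30,
    centers: list[CenterProfile] | None = None,
    seed: int = 0,
    spec_sampler=None,
) -> pd.DataFrame:
    """Write a reproducible multicenter benchmark to ``out_dir``.

    For each center and each of ``n_per_center`` patients, a phantom is
    sampled, distorted with the center's profile, and written as PNG with a
    landmark CSV; ``manifest.csv`` lists one row per ground-truth curve with
    columns ``image,landmarks,center_id,curve_index,apex,gt_cobb``. The
    whole tree is a pure function of ``seed``.
    """
    if n_per_center < 1:
        raise ValidationError(f"n_per_center must be >= 1, got {n_per_center}")
    centers = centers if centers is not None else default_center_profiles()
    if not centers:
        raise ValidationError("centers must be non-empty")
    sampler = spec_sampler if spec_sampler is not None else default_spec_sampler
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, cp in enumerate(centers):
        for k in range(n_per_center):
            rng = np.random.default_rng([seed, ci, k])
            spec = sampler(rng)
            sid = f"{cp.center_id}_{k:03d}"
            img, lm = generate_phantom(spec, source_id=sid)
            distorted = apply_center_profile(img, cp)
            img_path = out_dir / f"{sid}.png"
            lm_path = out_dir / f"{sid}_landmarks.csv"
            write_image(distorted, img_path)
            write_landmarks(lm, lm_path)
            if spec.curves:
                for qi, c in enumerate(spec.curves):
                    rows.append({"image": img_path.name, "landmarks": lm_path.name,
                                 "center_id": cp.center_id, "curve_index": qi,
                                 "apex": c.apex, "gt_cobb": c.cobb_deg})
            else:
                rows.append({"image": img_path.name, "landmarks": lm_path.name,
                             "center_id": cp.center_id, "curve_index": -1,
                             "apex": "", "gt_cobb": 0.0})
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest.to_csv(out_dir / "manifest.csv", index=False, float_format="%.10g")
    return manifest
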