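"""Statistical intensity profiles of radiographs.

An :class:`IntensityProfile` holds the empirical histogram and CDF of one
image (or a pooled cohort) over ``n_levels`` equal-width intensity bins,
together with two scalar heterogeneity descriptors:

* **brightness** — mean pixel intensity expressed on a 0–255 scale,
  ``mean(pixel / (2**bit_depth - 1)) * 255``;
* **spread** — population standard deviation of pixel intensities on the
  normalized [0, 1] scale, a contrast surrogate.

The mixed scales (0–255 for brightness, [0, 1] for spread) are deliberate and
stated on the type so the two are never confused.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, IncompatibilityError, ValidationError
from .imgio import GrayImage

DEFAULT_N_LEVELS = 256


def quantize_levels(pixels: np.ndarray, bit_depth: int, n_levels: int) -> np.ndarray:
    """Bin integer pixel values into ``n_levels`` equal-width levels.

    ``level = floor(pixel * n_levels / 2**bit_depth)``; exact integer
    arithmetic, and the identity map when ``n_levels == 2**bit_depth``.
    """
    return (pixels.astype(np.int64) * n_levels) // (1 << bit_depth)


def level_to_intensity(levels: np.ndarray, bit_depth: int, n_levels: int) -> np.ndarray:
    """Representative integer intensity of each level at the given bit depth."""
    max_value = (1 << bit_depth) - 1
    if n_levels == 1:
        return np.full_like(np.asarray(levels), max_value // 2)
    return np.rint(np.asarray(levels) * (max_value / (n_levels - 1))).astype(np.int64)


@dataclass
class IntensityProfile:
    """Histogram + CDF + brightness + spread of an image or pooled cohort.

    Invariants (checked on construction): ``hist`` sums to 1, ``cdf`` is its
    cumulative sum (non-decreasing, ending at 1), ``0 <= brightness <= 255``,
    ``0 <= spread <= 0.5``.
    """

    n_levels: int
    hist: np.ndarray
    brightness: float
    spread: float
    n_pixels: int
    profile_id: str = ""
    cdf: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.hist = np.asarray(self.hist, dtype=float)
        if self.n_levels < 2:
            raise ValidationError(f"n_levels must be >= 2, got {self.n_levels}")
        if self.hist.shape != (self.n_levels,):
            raise ValidationError(
                f"hist must have shape ({self.n_levels},), got {self.hist.shape}"
            )
        if self.n_pixels > 0 and abs(self.hist.sum() - 1.0) > 1e-9:
            raise ValidationError(f"hist must sum to 1, got {self.hist.sum()!r}")
        if (self.hist < 0).any():
            raise ValidationError("hist must be non-negative")
        if not 0.0 <= self.brightness <= 255.0:
            raise ValidationError(f"brightness out of [0, 255]: {self.brightness}")
        if not 0.0 <= self.spread <= 0.5 + 1e-12:
            raise ValidationError(f"spread out of [0, 0.5]: {self.spread}")
        if self.cdf is None:
            self.cdf = np.cumsum(self.hist)
        else:
            self.cdf = np.asarray(self.cdf, dtype=float)
            if np.abs(self.cdf - np.cumsum(self.hist)).max() > 1e-12:
                raise ValidationError("cdf is not the cumulative sum of hist")

    def to_dict(self) -> dict:
        return {
            "n_levels": int(self.n_levels),
            "hist": self.hist.tolist(),
            "brightness": float(self.brightness),
            "spread": float(self.spread),
            "n_pixels": int(self.n_pixels),
            "profile_id": self.profile_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IntensityProfile":
        return cls(
            n_levels=int(d["n_levels"]),
            hist=np.asarray(d["hist"], dtype=float),
            brightness=float(d["brightness"]),
            spread=float(d["spread"]),
            n_pixels=int(d["n_pixels"]),
            profile_id=str(d.get("profile_id", "")),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load_json(cls, path: str | Path) -> "IntensityProfile":
        return cls.from_dict(json.loads(Path(path).read_text()))


def compute_profile(img: GrayImage, n_levels: int = DEFAULT_N_LEVELS) -> IntensityProfile:
    """Empirical intensity profile of one image.

    Pixels are binned into ``n_levels`` equal-width bins over the image's
    representable range; brightness and spread are computed from the raw
    (un-binned) pixel values.
    """
    if n_levels < 2:
        raise ValidationError(f"n_levels must be >= 2, got {n_levels}")
    pixels = img.pixels
    if pixels.size == 0:
        raise DegenerateInputError("cannot profile an empty image")
    levels = quantize_levels(pixels.ravel(), img.bit_depth, n_levels)
    counts = np.bincount(levels, minlength=n_levels).astype(float)
    n = pixels.size
    normalized = pixels.astype(np.float64).ravel() / img.max_value
    return IntensityProfile(
        n_levels=n_levels,
        hist=counts / n,
        brightness=float(normalized.mean() * 255.0),
        spread=float(normalized.std()),  # population SD: the image IS its population
        n_pixels=n,
        profile_id=img.source_id,
    )


def pool_profiles(profiles: Sequence[IntensityProfile],
                  profile_id: str = "pooled") -> IntensityProfile:
    """Pixel-count-weighted pooled profile of a cohort.

    Brightness and spread are recomputed from the pooled histogram, using
    bin centers ``(k + 0.5) / n_levels`` as representative normalized
    intensities (so they agree with per-image values to within one bin width).
    """
    if not profiles:
        raise DegenerateInputError("cannot pool an empty list of profiles")
    n_levels = profiles[0].n_levels
    for p in profiles[1:]:
        if p.n_levels != n_levels:
            raise IncompatibilityError(
                f"profiles have mismatched n_levels: {n_levels} vs {p.n_levels}"
            )
    weights = np.array([p.n_pixels for p in profiles], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise DegenerateInputError("pooled profile would cover zero pixels")
    hist = np.zeros(n_levels)
    for w, p in zip(weights, profiles):
        hist += w * p.hist
    hist /= total
    centers = (np.arange(n_levels) + 0.5) / n_levels
    mean_norm = float((hist * centers).sum())
    var_norm = float((hist * centers**2).sum()) - mean_norm**2
    return IntensityProfile(
        n_levels=n_levels,
        hist=hist,
        brightness=mean_norm * 255.0,
        spread=float(np.sqrt(max(var_norm, 0.0))),
        n_pixels=int(total),
        profile_id=profile_id,
    )


def profile_distance(a: IntensityProfile, b: IntensityProfile) -> tuple[float, float]:
    """(brightness difference on the 0–255 scale, spread difference on [0, 1]).

    Both are absolute differences of the scalar descriptors; together they
    quantify inter-center heterogeneity before and after harmonization.
    """
    if a.n_levels != b.n_levels:
        raise IncompatibilityError(
            f"profiles have mismatched n_levels: {a.n_levels} vs {b.n_levels}"
        )
    return abs(a.brightness - b.brightness), abs(a.spread - b.spread)
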