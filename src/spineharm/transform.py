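"""Intensity-distribution harmonization by monotone CDF matching.

The core method: given the empirical CDFs :math:`F^S` of a source image and
:math:`F^T` of a reference, every occupied source level *s* is mapped to the
reference level *t* minimizing :math:`|F^S(s) - F^T(t)|` (ties broken to the
smallest *t*), unoccupied levels are filled by linear interpolation, and the
lookup table is made monotone by a cumulative maximum. Applying the map is a
pure per-pixel table lookup, so no spatial resampling occurs, pixel rank
order is preserved, and the whole pipeline is O(n log n) in the pixel count
(histogram accumulation dominates).

After harmonization the output CDF matches the reference CDF to within the
largest single-bin mass of the source histogram (the discretization bound).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateInputError,
    IncompatibilityError,
    PlanValidationError,
    ValidationError,
)
from .imgio import GrayImage
from .profile import (
    DEFAULT_N_LEVELS,
    IntensityProfile,
    compute_profile,
    level_to_intensity,
    quantize_levels,
)


@dataclass
class TransferMap:
    """A monotone intensity lookup table from source levels to reference levels."""

    n_levels: int
    map: np.ndarray
    source_profile_id: str = ""
    reference_profile_id: str = ""

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=np.int64)
        if self.map.shape != (self.n_levels,):
            raise ValidationError(
                f"map must have shape ({self.n_levels},), got {self.map.shape}"
            )
        if (np.diff(self.map) < 0).any():
            raise ValidationError("transfer map must be non-decreasing")
        if self.map.min() < 0 or self.map.max() > self.n_levels - 1:
            raise ValidationError(f"map values outside [0, {self.n_levels - 1}]")

    def to_dict(self) -> dict:
        return {"n_levels": int(self.n_levels), "map": self.map.tolist(),
                "source_profile_id": self.source_profile_id,
                "reference_profile_id": self.reference_profile_id}

    @classmethod
    def from_dict(cls, d: dict) -> "TransferMap":
        return cls(n_levels=int(d["n_levels"]), map=np.asarray(d["map"]),
                   source_profile_id=str(d.get("source_profile_id", "")),
                   reference_profile_id=str(d.get("reference_profile_id", "")))


def fit_transfer_map(source: IntensityProfile,
                     reference: IntensityProfile) -> TransferMap:
    """Fit the monotone CDF-matching lookup table.

    For every source level *s* with positive histogram mass,
    ``map[s] = argmin_t |F_S(s) - F_T(t)|`` with ties to the smallest *t*;
    unoccupied levels are linearly interpolated between their occupied
    neighbours (held flat beyond the ends), and a cumulative maximum
    guarantees monotonicity of the final table.
    """
    if source.n_levels != reference.n_levels:
        raise IncompatibilityError(
            f"profiles have mismatched n_levels: {source.n_levels} vs {reference.n_levels}"
        )
    if source.n_pixels == 0 or reference.n_pixels == 0:
        raise DegenerateInputError("cannot fit a transfer map from an empty image")
    n = source.n_levels
    occupied = np.flatnonzero(source.hist > 0)
    # |F_S(s) - F_T(t)| over all occupied s and all t; argmin returns the
    # smallest t on ties, which is the documented tie-break.
    diff = np.abs(source.cdf[occupied, None] - reference.cdf[None, :])
    mapped = diff.argmin(axis=1)
    full = np.interp(np.arange(n), occupied, mapped)
    full = np.floor(full + 0.5).astype(np.int64)
    full[occupied] = mapped  # keep optimal values exact where data exist
    full = np.maximum.accumulate(full)
    return TransferMap(
        n_levels=n,
        map=np.clip(full, 0, n - 1),
        source_profile_id=source.profile_id,
        reference_profile_id=reference.profile_id,
    )


def apply_transfer_map(img: GrayImage, tm: TransferMap) -> GrayImage:
    """Apply a fitted map to every pixel (dimensions and rank order preserved)."""
    if tm.n_levels > (1 << img.bit_depth):
        raise IncompatibilityError(
            f"map has {tm.n_levels} levels but the image bit depth {img.bit_depth} "
            f"supports at most {1 << img.bit_depth}"
        )
    levels = quantize_levels(img.pixels, img.bit_depth, tm.n_levels)
    out_levels = tm.map[levels]
    out = level_to_intensity(out_levels, img.bit_depth, tm.n_levels)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    return GrayImage(pixels=out.astype(dtype), bit_depth=img.bit_depth,
                     source_id=img.source_id)


def harmonize(img: GrayImage, reference: IntensityProfile) -> GrayImage:
    """Align one image's intensity distribution to a reference profile.

    Composition of profile → fit → apply. Real-time: one histogram pass plus
    a per-pixel lookup.
    """
    source = compute_profile(img, n_levels=reference.n_levels)
    tm = fit_transfer_map(source, reference)
    return apply_transfer_map(img, tm)


def default_reference_profile() -> IntensityProfile:
    """The packaged default reference: pooled profile of the synthetic
    training cohort, used for calibration-free operation. Any
    :class:`IntensityProfile` may be supplied instead."""
    with resources.files("spineharm.data").joinpath(
            "default_reference.json").open() as fh:
        import json

        return IntensityProfile.from_dict(json.load(fh))


@dataclass
class Provenance:
    """Where an augmented image came from."""

    source_id: str
    center_id: str | None = None
    reference_id: str | None = None

    @property
    def is_transformed(self) -> bool:
        return self.reference_id is not None


@dataclass
class AugmentationPlan:
    """Multi-reference training augmentation protocol.

    Each source image is transformed ``transforms_per_image`` times, each
    time against a single reference image drawn uniformly at random from a
    uniformly chosen center pool; originals are mixed in unweighted when
    ``include_originals`` is set, and the output order is a seeded shuffle.
    """

    references: list[tuple[str, list[GrayImage]]]
    transforms_per_image: int = 1
    include_originals: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transforms_per_image < 1:
            raise PlanValidationError(
                f"transforms_per_image must be >= 1, got {self.transforms_per_image}"
            )
        if not self.references:
            raise PlanValidationError("plan must list at least one center pool")
        for center_id, pool in self.references:
            if not pool:
                raise PlanValidationError(f"center {center_id!r} has an empty pool")


def _stable_tag(s: str) -> int:
    return zlib.crc32(s.encode("utf-8"))


def build_augmented_set(
    images: Sequence[GrayImage],
    plan: AugmentationPlan,
    n_levels: int = DEFAULT_N_LEVELS,
) -> list[tuple[GrayImage, Provenance]]:
    """Produce the augmented training set prescribed by ``plan``.

    Randomness is derived per (image index, copy index) from the plan seed,
    so adding images does not perturb earlier draws, and identical seeds give
    bit-identical output sequences.
    """
    if not images:
        raise DegenerateInputError("no images to augment")
    # Cache reference profiles: pools are typically small and shared.
    profile_cache: dict[tuple[int, int], IntensityProfile] = {}

    def ref_profile(ci: int, ri: int) -> IntensityProfile:
        key = (ci, ri)
        if key not in profile_cache:
            profile_cache[key] = compute_profile(plan.references[ci][1][ri],
                                                 n_levels=n_levels)
        return profile_cache[key]

    outputs: list[tuple[GrayImage, Provenance]] = []
    for i, img in enumerate(images):
        for j in range(plan.transforms_per_image):
            rng = np.random.default_rng([plan.seed, i, j])
            ci = int(rng.integers(len(plan.references)))
            center_id, pool = plan.references[ci]
            ri = int(rng.integers(len(pool)))
            out = harmonize(img, ref_profile(ci, ri))
            ref_id = pool[ri].source_id or f"{center_id}[{ri}]"
            outputs.append((out, Provenance(img.source_id, center_id, ref_id)))
        if plan.include_originals:
            outputs.append((img, Provenance(img.source_id)))
    shuffle_rng = np.random.default_rng([plan.seed, _stable_tag("shuffle")])
    order = shuffle_rng.permutation(len(outputs))
    return [outputs[k] for k in order]
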