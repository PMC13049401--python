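"""Shared fixtures and helpers for the spineharm test suite."""

from __future__ import annotations

import numpy as np
import pytest

from spineharm.imgio import CORNERS, VERTEBRAE, GrayImage, LandmarkSet
from spineharm.profile import IntensityProfile, compute_profile


def gray(values, bit_depth=8, source_id="test") -> GrayImage:
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return GrayImage(pixels=np.asarray(values, dtype=dtype), bit_depth=bit_depth,
                     source_id=source_id)


def landmarks_from_tilts(tilts, image_id="lm", width=24.0, height=10.0,
                         dy=24.0, x0=100.0, y0=40.0) -> LandmarkSet:
    """Build a landmark set with each vertebra's endplates tilted by the given
    angle (degrees); tilts may be a scalar or one value per vertebra."""
    tilts = np.broadcast_to(np.asarray(tilts, dtype=float), (len(VERTEBRAE),))
    points = {}
    for i, v in enumerate(VERTEBRAE):
        cx, cy = x0, y0 + i * dy
        t = np.radians(tilts[i])
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        offsets = {
            "sup_left": (-width / 2, -height / 2),
            "sup_right": (width / 2, -height / 2),
            "inf_left": (-width / 2, height / 2),
            "inf_right": (width / 2, height / 2),
        }
        for c in CORNERS:
            d = rot @ np.asarray(offsets[c])
            points[(v, c)] = (cx + float(d[0]), cy + float(d[1]))
    return LandmarkSet(image_id=image_id, points=points)


def transform_landmarks(lm: LandmarkSet, fn) -> LandmarkSet:
    """Apply a coordinate map (x, y) -> (x', y') to every landmark."""
    return LandmarkSet(
        image_id=lm.image_id,
        points={k: fn(*xy) for k, xy in lm.points.items()},
    )


def mirror_landmarks(lm: LandmarkSet) -> LandmarkSet:
    """Anatomical x-mirror: reflect coordinates and swap left/right labels."""
    xs = [xy[0] for xy in lm.points.values()]
    w = max(xs)
    swap = {"sup_left": "sup_right", "sup_right": "sup_left",
            "inf_left": "inf_right", "inf_right": "inf_left"}
    return LandmarkSet(
        image_id=lm.image_id,
        points={(v, swap[c]): (w - x, y) for (v, c), (x, y) in lm.points.items()},
    )


def random_small_profile(rng: np.random.Generator, n_levels: int,
                         max_distinct: int = 8) -> IntensityProfile:
    """Profile of a small random 8-bit image with few distinct values."""
    k = int(rng.integers(1, max_distinct + 1))
    values = rng.choice(256, size=k, replace=False)
    counts = rng.integers(1, 20, size=k)
    pixels = np.repeat(values, counts)
    rng.shuffle(pixels)
    return compute_profile(gray(pixels.reshape(1, -1)), n_levels=n_levels)


def random_image(rng: np.random.Generator, shape=(128, 128), smooth=True) -> GrayImage:
    """A random 8-bit image with a reasonably diffuse histogram."""
    from scipy.ndimage import gaussian_filter

    arr = rng.normal(128, 45, size=shape)
    if smooth:
        arr = gaussian_filter(arr, 1.5) + rng.normal(0, 6, size=shape)
    return gray(np.clip(np.rint(arr), 0, 255))


def brute_force_transfer_map(source: IntensityProfile,
                             reference: IntensityProfile) -> dict[int, int]:
    """Independent oracle: exhaustive argmin over all (source, reference) level
    pairs, ties broken to the smallest reference level. Plain loops, no numpy
    vectorized argmin, so it shares no code path with the implementation."""
    out = {}
    for s in range(source.n_levels):
        if source.hist[s] <= 0:
            continue
        best_t, best_d = 0, None
        for t in range(reference.n_levels):
            d = abs(float(source.cdf[s]) - float(reference.cdf[t]))
            if best_d is None or d < best_d:
                best_t, best_d = t, d
        out[s] = best_t
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
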