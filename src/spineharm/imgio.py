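"""Radiograph and landmark I/O.

Reads grayscale posteroanterior whole-spine radiographs (8/16-bit PNG, TIFF,
or monochrome DICOM) into :class:`GrayImage`, and endplate-landmark
annotations (CSV or JSON, 72 points: 18 vertebrae C7–L5 x 4 corners) into
:class:`LandmarkSet`.

Coordinate convention: x rightward, y downward, origin at the top-left pixel
center, 0-based. DICOM MONOCHROME1 images are inverted on read so that a
higher stored value is always brighter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pydicom

from .errors import SchemaError, UnsupportedFormatError, ValidationError

#: Canonical cranio-caudal vertebra order of the 18 annotated levels.
VERTEBRAE: tuple[str, ...] = ("C7",) + tuple(f"T{i}" for i in range(1, 13)) + tuple(
    f"L{i}" for i in range(1, 6)
)

#: The four named endplate corners of each vertebral body.
CORNERS: tuple[str, ...] = ("sup_left", "sup_right", "inf_left", "inf_right")

#: Vertical slack (pixels) allowed when checking that a superior endplate sits
#: above the inferior one; admits near-degenerate endplates at low resolution.
ORIENTATION_TOLERANCE_PX = 2.0

_VERTEBRA_INDEX = {v: i for i, v in enumerate(VERTEBRAE)}

_LANDMARK_CSV_COLUMNS = ("vertebra", "corner", "x", "y")


def vertebra_index(label: str) -> int:
    """Position of ``label`` in the C7→L5 order; raises on unknown labels."""
    try:
        return _VERTEBRA_INDEX[label]
    except KeyError:
        raise ValidationError(f"unknown vertebra label {label!r}") from None


@dataclass
class GrayImage:
    """A 2D grayscale raster with its bit depth and a provenance tag.

    Parameters
    ----------
    pixels
        2D array of non-negative integers in ``[0, 2**bit_depth - 1]``.
    bit_depth
        8 or 16.
    source_id
        Opaque center/patient tag carried through transformations.
    """

    pixels: np.ndarray
    bit_depth: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.ndim != 2:
            raise ValidationError(f"pixels must be 2D, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValidationError(f"image must be at least 1x1, got {self.pixels.shape}")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValidationError(f"pixels must be integer-typed, got {self.pixels.dtype}")
        if self.pixels.min() < 0 or int(self.pixels.max()) > self.max_value:
            raise ValidationError(
                f"pixel values outside [0, {self.max_value}] for bit_depth {self.bit_depth}"
            )

    @property
    def max_value(self) -> int:
        """Largest representable intensity, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class LandmarkSet:
    """72 endplate corner points: 18 vertebrae (C7–L5) x 4 named corners.

    ``points`` maps ``(vertebra, corner)`` to ``(x, y)`` pixel coordinates.
    Schema completeness and coordinate validity are checked on construction;
    the anatomical orientation check (superior endplate above inferior) and
    image-bounds check live in :meth:`validate` because rotated or detached
    landmark sets are legitimate intermediates in geometric computations.
    """

    image_id: str
    points: dict[tuple[str, str], tuple[float, float]] = field(repr=False)

    def __post_init__(self) -> None:
        expected = {(v, c) for v in VERTEBRAE for c in CORNERS}
        got = set(self.points)
        unknown = sorted(f"{v}/{c}" for v, c in got - expected)
        if unknown:
            raise SchemaError(f"unknown (vertebra, corner) pairs: {', '.join(unknown)}")
        missing = sorted(
            (f"{v}/{c}" for v, c in expected - got),
            key=lambda s: (_VERTEBRA_INDEX[s.split("/")[0]], s),
        )
        if missing:
            raise SchemaError(f"missing landmarks: {', '.join(missing)}")
        for (v, c), (x, y) in self.points.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValidationError(f"non-finite coordinate at {v}/{c}")
            if x < 0 or y < 0:
                raise ValidationError(f"negative coordinate at {v}/{c}: ({x}, {y})")

    def get(self, vertebra: str, corner: str) -> tuple[float, float]:
        return self.points[(vertebra, corner)]

    def corners_of(self, vertebra: str) -> np.ndarray:
        """4x2 array of (x, y) for one vertebra in canonical corner order."""
        return np.array([self.points[(vertebra, c)] for c in CORNERS], dtype=float)

    def centroid(self, vertebra: str) -> np.ndarray:
        """Mean of the four corner points of one vertebra."""
        return self.corners_of(vertebra).mean(axis=0)

    def validate(self, image: GrayImage | None = None,
                 orientation_tolerance: float = ORIENTATION_TOLERANCE_PX) -> None:
        """Check anatomical orientation and (optionally) image bounds.

        Raises :class:`ValidationError` if a superior corner lies more than
        ``orientation_tolerance`` pixels below the matching inferior corner,
        or if any point falls outside the attached image.
        """
        for v in VERTEBRAE:
            for side in ("left", "right"):
                sup_y = self.points[(v, f"sup_{side}")][1]
                inf_y = self.points[(v, f"inf_{side}")][1]
                if sup_y > inf_y + orientation_tolerance:
                    raise ValidationError(
                        f"superior endplate below inferior at {v} ({side} side): "
                        f"sup y={sup_y:.2f} > inf y={inf_y:.2f} + {orientation_tolerance}"
                    )
        if image is not None:
            h, w = image.shape
            for (v, c), (x, y) in self.points.items():
                if x > w - 1 or y > h - 1:
                    raise ValidationError(
                        f"landmark {v}/{c} at ({x}, {y}) outside image {w}x{h}"
                    )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"vertebra": v, "corner": c, "x": self.points[(v, c)][0],
             "y": self.points[(v, c)][1]}
            for v in VERTEBRAE
            for c in CORNERS
        ]
        return pd.DataFrame(rows, columns=list(_LANDMARK_CSV_COLUMNS))

    @classmethod
    def from_rows(cls, image_id: str,
                  rows: Iterable[Mapping[str, object]]) -> "LandmarkSet":
        """Build from an iterable of {vertebra, corner, x, y} mappings.

        Duplicated (vertebra, corner) pairs are reported by name.
        """
        points: dict[tuple[str, str], tuple[float, float]] = {}
        duplicates: list[str] = []
        for row in rows:
            key = (str(row["vertebra"]), str(row["corner"]))
            if key in points:
                duplicates.append(f"{key[0]}/{key[1]}")
                continue
            points[key] = (float(row["x"]), float(row["y"]))  # type: ignore[arg-type]
        if duplicates:
            raise SchemaError(f"duplicated landmarks: {', '.join(sorted(set(duplicates)))}")
        return cls(image_id=image_id, points=points)


def _from_array(arr: np.ndarray, source_id: str) -> GrayImage:
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim != 2:
        n_channels = arr.shape[-1] if arr.ndim == 3 else arr.ndim
        raise UnsupportedFormatError(
            f"expected a single-channel grayscale image, got {n_channels} channels"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    elif arr.dtype == bool:
        arr, depth = arr.astype(np.uint8) * 255, 8
    else:
        raise UnsupportedFormatError(f"unsupported pixel dtype {arr.dtype}")
    return GrayImage(pixels=arr, bit_depth=depth, source_id=source_id)


def _read_dicom(path: Path) -> GrayImage:
    ds = pydicom.dcmread(path)
    samples = int(getattr(ds, "SamplesPerPixel", 1))
    if samples != 1:
        raise UnsupportedFormatError(
            f"expected a monochrome DICOM, got {samples} samples per pixel"
        )
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    bits = int(getattr(ds, "BitsStored", 16))
    depth = 8 if bits <= 8 else 16
    max_val = (1 << depth) - 1
    arr = np.clip(np.rint(arr), 0, max_val)
    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    if photometric == "MONOCHROME1":  # low stored value = bright; flip polarity
        arr = max_val - arr
    dtype = np.uint8 if depth == 8 else np.uint16
    return GrayImage(pixels=arr.astype(dtype), bit_depth=depth, source_id=path.stem)


def read_image(path: str | Path) -> GrayImage:
    """Read a PNG, TIFF, or monochrome DICOM radiograph.

    Bit depth is inferred (uint8 → 8, uint16 → 16; DICOM BitsStored rounded
    up to 8 or 16). Color images raise :class:`UnsupportedFormatError`.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ""):
        return _read_dicom(path)
    if suffix in (".png", ".tif", ".tiff"):
        return _from_array(iio.imread(path), source_id=path.stem)
    # Unknown extension: try raster first, fall back to DICOM.
    try:
        return _from_array(iio.imread(path), source_id=path.stem)
    except UnsupportedFormatError:
        raise
    except Exception:
        return _read_dicom(path)


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write losslessly as PNG or TIFF; ``read_image`` round-trips bit-exactly."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    iio.imwrite(path, img.pixels.astype(dtype))


def read_landmarks(path: str | Path, image: GrayImage | None = None) -> LandmarkSet:
    """Read a landmark CSV (header ``vertebra,corner,x,y``) or JSON file.

    Rows may appear in any order. Missing or duplicated pairs raise
    :class:`SchemaError` naming the offenders; negative coordinates raise
    :class:`ValidationError`. The anatomical orientation invariant is
    enforced (and the bounds check when ``image`` is given).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        lm = LandmarkSet.from_rows(str(payload.get("image_id", path.stem)),
                                   payload["points"])
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        missing_cols = [c for c in _LANDMARK_CSV_COLUMNS if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"landmark CSV missing columns: {missing_cols}")
        lm = LandmarkSet.from_rows(path.stem, df.to_dict("records"))
    lm.validate(image=image)
    return lm


def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    """Write landmarks as CSV (default) or JSON (``.json`` suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "image_id": lm.image_id,
            "points": [
                {"vertebra": v, "corner": c, "x": lm.points[(v, c)][0],
                 "y": lm.points[(v, c)][1]}
                for v in VERTEBRAE
                for c in CORNERS
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        # %.17g round-trips IEEE doubles exactly
        lm.to_dataframe().to_csv(path, index=False, float_format="%.17g")
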