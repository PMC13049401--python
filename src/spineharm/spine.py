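"""Spinal-alignment geometry from endplate landmarks.

Implements the classical Cobb construction on the 72-landmark annotation
scheme (18 vertebrae C7–L5, 4 endplate corners each): endplate slopes, Cobb
angle of a vertebra pair, exhaustive curve detection with apex localization,
curve-type classification by apex level, and severity grading.

Severity grading uses the closed/half-open partition [0°, 20°] normal-mild,
(20°, 40°] moderate, (40°, ∞) severe, so every non-negative angle receives
exactly one grade. Curves with an apex at T1–T11 are thoracic; T12–L5 are
thoracolumbar/lumbar (C7, never assigned by the clinical rule, is mapped to
thoracic as the conservative cranial extension).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateEndplateError,
    OrderingError,
    ValidationError,
)
from .imgio import VERTEBRAE, LandmarkSet, vertebra_index

THORACIC = "thoracic"
THORACOLUMBAR_LUMBAR = "thoracolumbar_lumbar"

NORMAL_MILD = "normal_mild"
MODERATE = "moderate"
SEVERE = "severe"

#: Curves below this Cobb angle (degrees) are not reported; the conventional
#: radiographic floor for calling a scoliotic curve.
CURVE_DETECTION_THRESHOLD_DEG = 10.0


@dataclass
class EndplateSlopes:
    """Signed endplate slope angles (degrees from image-horizontal, left→right,
    y-down convention) for all 18 vertebrae."""

    superior: dict[str, float]
    inferior: dict[str, float]

    def __post_init__(self) -> None:
        for d in (self.superior, self.inferior):
            if set(d) != set(VERTEBRAE):
                raise ValidationError("slopes must cover exactly the 18 vertebrae")
            for v, a in d.items():
                if not -90.0 <= a < 90.0:
                    raise ValidationError(f"slope at {v} outside [-90, 90): {a}")


@dataclass
class CurveMeasurement:
    """One detected scoliotic curve."""

    cobb_deg: float
    upper_end_vertebra: str
    lower_end_vertebra: str
    apex_vertebra: str
    curve_type: str
    severity: str

    def __post_init__(self) -> None:
        u = vertebra_index(self.upper_end_vertebra)
        l = vertebra_index(self.lower_end_vertebra)
        a = vertebra_index(self.apex_vertebra)
        if u >= l:
            raise ValidationError(
                f"upper end {self.upper_end_vertebra} not above lower end "
                f"{self.lower_end_vertebra}"
            )
        if not u <= a <= l:
            raise ValidationError(
                f"apex {self.apex_vertebra} outside [{self.upper_end_vertebra}, "
                f"{self.lower_end_vertebra}]"
            )
        if not 0.0 <= self.cobb_deg < 180.0:
            raise ValidationError(f"cobb_deg outside [0, 180): {self.cobb_deg}")
        if self.severity != classify_severity(self.cobb_deg):
            raise ValidationError(
                f"severity {self.severity!r} inconsistent with {self.cobb_deg}°"
            )


def _fold_line_angle(a: float) -> float:
    """Fold an angle into [-90, 90): the direction of an undirected line."""
    return ((a + 90.0) % 180.0) - 90.0


def _slope_deg(p_left: tuple[float, float], p_right: tuple[float, float],
               vertebra: str, which: str) -> float:
    dx = p_right[0] - p_left[0]
    dy = p_right[1] - p_left[1]
    if abs(dx) < 1e-12 and abs(dy) < 1e-12:
        raise DegenerateEndplateError(
            f"coincident left/right corners on the {which} endplate of {vertebra}"
        )
    # An endplate is an undirected line: its slope lives modulo 180 degrees,
    # which keeps slopes well defined under arbitrary landmark rotations.
    return _fold_line_angle(float(np.degrees(np.arctan2(dy, dx))))


def endplate_slopes(lm: LandmarkSet) -> EndplateSlopes:
    """Superior and inferior endplate slopes of every vertebra.

    Slope of an endplate = atan2(y_right - y_left, x_right - x_left) in
    degrees (y grows downward, so a positive slope tilts down to the right).
    """
    sup: dict[str, float] = {}
    inf: dict[str, float] = {}
    for v in VERTEBRAE:
        sup[v] = _slope_deg(lm.get(v, "sup_left"), lm.get(v, "sup_right"), v, "superior")
        inf[v] = _slope_deg(lm.get(v, "inf_left"), lm.get(v, "inf_right"), v, "inferior")
    return EndplateSlopes(superior=sup, inferior=inf)


def _angle_between(a: float, b: float) -> float:
    """Acute angle between two undirected lines given by angles in degrees."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def cobb_angle(lm: LandmarkSet, upper: str, lower: str,
               slopes: EndplateSlopes | None = None) -> float:
    """Cobb angle between the superior endplate of ``upper`` and the inferior
    endplate of ``lower``: the acute angle between the two endplate lines,
    in [0°, 90°] (a subset of the [0°, 180°) range of the measurement type)."""
    if vertebra_index(upper) >= vertebra_index(lower):
        raise OrderingError(f"{upper} is not above {lower}")
    if slopes is None:
        slopes = endplate_slopes(lm)
    return _angle_between(slopes.superior[upper], slopes.inferior[lower])


def classify_curve_type(apex: str) -> str:
    """Thoracic for apex C7–T11; thoracolumbar/lumbar for apex T12–L5."""
    idx = vertebra_index(apex)
    return THORACIC if idx < vertebra_index("T12") else THORACOLUMBAR_LUMBAR


def classify_severity(cobb: float) -> str:
    """Grade a Cobb angle: [0, 20] normal-mild, (20, 40] moderate, >40 severe."""
    if cobb < 0:
        raise ValidationError(f"Cobb angle cannot be negative: {cobb}")
    if cobb <= 20.0:
        return NORMAL_MILD
    if cobb <= 40.0:
        return MODERATE
    return SEVERE


def _apex_index(centroids: np.ndarray, u: int, l: int) -> int:
    """Vertebra (index) between the end vertebrae whose centroid deviates most,
    perpendicular to the chord joining the end-vertebra centroids."""
    chord = centroids[l] - centroids[u]
    norm = np.linalg.norm(chord)
    if norm < 1e-12:
        return u  # degenerate chord: all candidates equivalent
    # Perpendicular distance via the 2D cross product.
    rel = centroids[u:l + 1] - centroids[u]
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
    return u + int(dist.argmax())


def find_curves(lm: LandmarkSet,
                min_cobb_deg: float = CURVE_DETECTION_THRESHOLD_DEG
                ) -> list[CurveMeasurement]:
    """Detect scoliotic curves from a landmark set.

    The primary curve is the maximal-Cobb pair over all 153 ordered vertebra
    pairs (exhaustive search); the cranial and caudal segments strictly
    outside it are then searched recursively for further curves of at least
    ``min_cobb_deg``. For each curve the apex is the vertebra with maximal
    perpendicular centroid deviation from the end-vertebra chord. Curves are
    returned sorted cranial→caudal; a spine with no pair reaching the
    threshold yields an empty list.
    """
    slopes = endplate_slopes(lm)
    sup = np.array([slopes.superior[v] for v in VERTEBRAE])
    inf = np.array([slopes.inferior[v] for v in VERTEBRAE])
    centroids = np.array([lm.centroid(v) for v in VERTEBRAE])

    def pair_angle(u: int, l: int) -> float:
        return _angle_between(sup[u], inf[l])

    def best_pair(lo: int, hi: int) -> tuple[int, int, float] | None:
        best: tuple[int, int, float] | None = None
        for u in range(lo, hi):
            for l in range(u + 1, hi + 1):
                ang = pair_angle(u, l)
                if best is None or ang > best[2]:
                    best = (u, l, ang)
        return best

    curves: list[tuple[int, int, float]] = []

    def search(lo: int, hi: int) -> None:
        if hi - lo < 1:
            return
        found = best_pair(lo, hi)
        if found is None or found[2] < min_cobb_deg:
            return
        u, l, ang = found
        curves.append((u, l, ang))
        search(lo, u - 1)
        search(l + 1, hi)

    search(0, len(VERTEBRAE) - 1)
    curves.sort(key=lambda c: c[0])
    out = []
    for u, l, ang in curves:
        apex = VERTEBRAE[_apex_index(centroids, u, l)]
        out.append(
            CurveMeasurement(
                cobb_deg=ang,
                upper_end_vertebra=VERTEBRAE[u],
                lower_end_vertebra=VERTEBRAE[l],
                apex_vertebra=apex,
                curve_type=classify_curve_type(apex),
                severity=classify_severity(ang),
            )
        )
    return out


def max_cobb(lm: LandmarkSet) -> float:
    """Per-patient maximum Cobb angle over all detected curves (0 if none)."""
    curves = find_curves(lm)
    return max((c.cobb_deg for c in curves), default=0.0)
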