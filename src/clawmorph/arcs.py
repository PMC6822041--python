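"""Traditional claw metrics: inscribed-circle dorsal arcs and length ratio.

Seven named points per claw anchor three-point circle fits; arc angles are
disambiguated by an explicit "through" point rather than an orientation
convention, so measurements are invariant under rigid motion and reflection
of the input points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .data import CURVE_SLICES, ClawConfiguration
from .errors import DegenerateGeometryError

#: relative collinearity tolerance: twice the triangle area must exceed this
#: times the squared largest pairwise distance
COLLINEARITY_RTOL = 1e-9


@dataclass(frozen=True)
class SevenPointSet:
    """The seven points of the traditional measurement protocol."""

    sheath_tip: np.ndarray
    core_tip: np.ndarray
    articulation_mid: np.ndarray
    core_dorsal_lip: np.ndarray
    sheath_dorsal_lip: np.ndarray
    core_arc_mid: np.ndarray
    sheath_arc_mid: np.ndarray

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (2,) or not np.all(np.isfinite(p)):
                raise ValueError(f"{name} must be a finite 2D point")
            object.__setattr__(self, name, p)


@dataclass(frozen=True)
class ArcMeasurement:
    """Arc angles (degrees), arc lengths, and the core/sheath length ratio."""

    core_arc_deg: float
    sheath_arc_deg: float
    core_length: float
    sheath_length: float
    length_ratio: float

    def __post_init__(self):
        if not (0 < self.core_arc_deg < 360 and 0 < self.sheath_arc_deg < 360):
            raise ValueError("arc angles must lie in (0, 360) degrees")
        if self.core_length <= 0 or self.sheath_length <= 0:
            raise ValueError("arc lengths must be positive")
        if self.length_ratio > 1.2:
            warnings.warn(
                f"length ratio {self.length_ratio:.3f} > 1.2 is biologically "
                "implausible",
                stacklevel=2,
            )


def fit_circle(p1, p2, p3) -> tuple[np.ndarray, float]:
    """Circumcircle through three non-collinear points -> (center, radius)."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    d12 = p2 - p1
    d13 = p3 - p1
    cross = d12[0] * d13[1] - d12[1] * d13[0]  # = 2 * signed area
    dmax2 = max(
        float(np.dot(d12, d12)),
        float(np.dot(d13, d13)),
        float(np.dot(p3 - p2, p3 - p2)),
    )
    if abs(cross) < COLLINEARITY_RTOL * dmax2:
        raise DegenerateGeometryError(
            f"points {p1.tolist()}, {p2.tolist()}, {p3.tolist()} are collinear "
            "within tolerance"
        )
    # perpendicular bisectors: 2 d . (c - p1) = |d|^2
    A = 2.0 * np.array([d12, d13])
    rhs = np.array([np.dot(d12, d12), np.dot(d13, d13)])
    center = p1 + np.linalg.solve(A, rhs)
    radius = float(np.linalg.norm(center - p1))
    return center, radius


def subtended_arc_deg(center, a, b, through) -> float:
    """Central angle (degrees) of the arc from a to b that contains `through`."""
    center, a, b, through = (
        np.asarray(p, dtype=float) for p in (center, a, b, through)
    )
    radii = [np.linalg.norm(p - center) for p in (a, b, through)]
    r = radii[0]
    if r <= 0:
        raise DegenerateGeometryError("arc endpoints coincide with center")
    if any(abs(x - r) > 0.01 * r for x in radii):
        raise DegenerateGeometryError(
            "arc points are not equidistant from center (beyond 1% of radius)"
        )
    ang = [math.atan2(p[1] - center[1], p[0] - center[0]) for p in (a, b, through)]
    if np.allclose(through, a) or np.allclose(through, b):
        raise DegenerateGeometryError(
            "'through' point coincides with an arc endpoint"
        )
    ccw = (ang[1] - ang[0]) % (2 * math.pi)  # CCW sweep a -> b
    t = (ang[2] - ang[0]) % (2 * math.pi)
    angle = ccw if t <= ccw else 2 * math.pi - ccw
    return math.degrees(angle)


def _arc(name, lip, mid, tip):
    try:
        center, radius = fit_circle(lip, mid, tip)
    except DegenerateGeometryError as exc:
        raise DegenerateGeometryError(f"{name} circle degenerate: {exc}") from exc
    deg = subtended_arc_deg(center, lip, tip, mid)
    return deg, radius


def measure_claw(points: SevenPointSet, chord_lengths: bool = False) -> ArcMeasurement:
    """Apply the seven-point protocol.

    Dorsal arcs come from circles through (lip, arc midpoint, tip); lengths
    come from circles through (articulation midpoint, arc midpoint, tip) as
    radius x subtended angle.  With ``chord_lengths=True`` lengths are the
    straight-line articulation-to-tip distances instead (non-default
    alternative protocol).
    """
    core_deg, _ = _arc(
        "core arc", points.core_dorsal_lip, points.core_arc_mid, points.core_tip
    )
    sheath_deg, _ = _arc(
        "sheath arc",
        points.sheath_dorsal_lip,
        points.sheath_arc_mid,
        points.sheath_tip,
    )
    if chord_lengths:
        core_len = float(np.linalg.norm(points.core_tip - points.articulation_mid))
        sheath_len = float(
            np.linalg.norm(points.sheath_tip - points.articulation_mid)
        )
    else:
        deg, radius = _arc(
            "core length",
            points.articulation_mid,
            points.core_arc_mid,
            points.core_tip,
        )
        core_len = radius * math.radians(deg)
        deg, radius = _arc(
            "sheath length",
            points.articulation_mid,
            points.sheath_arc_mid,
            points.sheath_tip,
        )
        sheath_len = radius * math.radians(deg)
    return ArcMeasurement(
        core_arc_deg=core_deg,
        sheath_arc_deg=sheath_deg,
        core_length=core_len,
        sheath_length=sheath_len,
        length_ratio=core_len / sheath_len,
    )


def extract_seven_points(config: ClawConfiguration) -> SevenPointSet:
    """Map the 83-point configuration onto the seven protocol points.

    sheath_tip = LM6, core_tip = LM4, articulation_mid = midpoint(LM1, LM2),
    core_dorsal_lip = LM1, sheath_dorsal_lip = first SL3 point (adjacent to
    LM1), arc midpoints = middle-by-index points of SL1 and SL3.
    """
    c = config.coords
    sl1 = c[CURVE_SLICES["SL1"]]
    sl3 = c[CURVE_SLICES["SL3"]]
    return SevenPointSet(
        sheath_tip=c[5],
        core_tip=c[3],
        articulation_mid=(c[0] + c[1]) / 2.0,
        core_dorsal_lip=c[0],
        sheath_dorsal_lip=sl3[0],
        core_arc_mid=sl1[len(sl1) // 2],
        sheath_arc_mid=sl3[len(sl3) // 2],
    )


def measure_configuration(
    config: ClawConfiguration, chord_lengths: bool = False
) -> ArcMeasurement:
    """Convenience: extract the seven points and measure in one call."""
    return measure_claw(extract_seven_points(config), chord_lengths=chord_lengths)
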