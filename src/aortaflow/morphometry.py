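"""Aortic-root morphometry: maximal cross-sectional diameters and BSA scaling.

Diameters are measured on manually traced ROI contours at four levels of
the aortic root — aortic valve plane (AOV), sinus of Valsalva (SOV),
sinotubular junction (STJ) and mid-ascending aorta (AAO).  The diameter
is operationalized as the maximum Feret diameter of the contour (largest
vertex-to-vertex distance in patient millimetres); an option restricts
to chords through the centroid for sensitivity checks.

The ascending-aorta measurement on the oblique-sagittal "candy-cane"
view is the largest chord perpendicular to a user-supplied centerline,
taken between the sinotubular-junction marker and the brachiocephalic
trunk marker.

For group analysis all diameters are divided by the square root of the
body surface area (Haycock formula).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist
from shapely.geometry import LineString, MultiLineString, Point, Polygon

from .errors import ValidationError
from .geometry import PlaneGeometry, pixel_to_patient

__all__ = [
    "LEVELS",
    "ContourROI",
    "Anthropometrics",
    "max_diameter",
    "haycock_bsa",
    "bsa_adjust",
    "aao_max_diameter",
]

LEVELS = ("AOV", "SOV", "STJ", "AAO")

# Haycock, Schwartz & Wisotsky (J Pediatr 1978): BSA in m^2 from
# weight in kg and height in cm.
_HAYCOCK_COEF = 0.024265
_HAYCOCK_W_EXP = 0.5378
_HAYCOCK_H_EXP = 0.3964


@dataclass(frozen=True)
class Anthropometrics:
    """Height (cm) and weight (kg); both strictly positive."""

    height_cm: float
    weight_kg: float

    def __post_init__(self):
        if not (self.height_cm > 0 and self.weight_kg > 0):
            raise ValidationError("height and weight must be positive")


@dataclass
class ContourROI:
    """Ordered pixel-coordinate polygon traced on one slice.

    The polygon must be simple (non-self-intersecting) with at least
    three vertices; ``level_label`` names the aortic level it outlines.
    """

    vertices: np.ndarray
    geometry: PlaneGeometry
    level_label: str

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValidationError(
                f"contour needs >= 3 (row, col) vertices, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("contour has non-finite vertices")
        if not Polygon(v).is_simple:
            raise ValidationError("contour polygon is self-intersecting")
        if self.level_label not in LEVELS:
            raise ValidationError(
                f"level_label must be one of {LEVELS}, got {self.level_label!r}")
        self.vertices = v

    def patient_vertices(self) -> np.ndarray:
        """(N, 3) vertex coordinates in patient millimetres."""
        return np.array([pixel_to_patient(p, self.geometry) for p in self.vertices])

    def _plane_mm(self) -> np.ndarray:
        """(N, 2) vertices in in-plane millimetres (row*sr, col*sc)."""
        sr, sc = self.geometry.spacing_row, self.geometry.spacing_col
        return self.vertices * np.array([sr, sc])


def max_diameter(c: ContourROI, through_centroid: bool = False) -> float:
    """Largest cross-sectional diameter of a traced contour, mm.

    Default is the maximum Feret diameter (max pairwise vertex
    distance).  With ``through_centroid=True`` only chords passing
    through the vertex centroid count: for each vertex the chord is its
    distance to the centroid plus the distance from the centroid to the
    boundary along the opposite ray.
    """
    pts = c.patient_vertices()
    if not through_centroid:
        return float(pdist(pts).max())

    pts2 = c._plane_mm()
    centroid = pts2.mean(axis=0)
    poly = Polygon(pts2)
    ring = LineString(list(poly.exterior.coords))
    reach = 4.0 * float(pdist(pts2).max())
    best = 0.0
    for p in pts2:
        u = centroid - p
        n = np.linalg.norm(u)
        if n < 1e-12:
            continue
        ray = LineString([centroid, centroid + u / n * reach])
        hit = ray.intersection(ring)
        if hit.is_empty:
            continue
        opposite = min(
            (g for g in getattr(hit, "geoms", [hit])),
            key=lambda g: g.distance(Point(centroid)),
        )
        d = float(np.linalg.norm(p - centroid)) + opposite.distance(Point(centroid))
        best = max(best, d)
    return best


def haycock_bsa(a: Anthropometrics) -> float:
    """Body surface area (m^2) by the Haycock power-law formula."""
    return float(
        _HAYCOCK_COEF
        * a.weight_kg ** _HAYCOCK_W_EXP
        * a.height_cm ** _HAYCOCK_H_EXP
    )


def bsa_adjust(diameter_mm: float, bsa_m2: float) -> float:
    """Diameter divided by sqrt(BSA); the indexed size used for group stats."""
    if not bsa_m2 > 0:
        raise ValidationError("BSA must be positive")
    return float(diameter_mm) / float(np.sqrt(bsa_m2))


def aao_max_diameter(
    c: ContourROI,
    centerline_px: Sequence[Sequence[float]],
    stj_marker_px: Sequence[float],
    brachio_marker_px: Sequence[float],
    n_samples: int = 200,
) -> float:
    """Largest mid-vessel chord perpendicular to the centerline, mm.

    The vessel outline *c* and the centerline polyline live on the
    candy-cane view.  The chord is evaluated at ``n_samples`` positions
    along the centerline between the projections of the STJ and
    brachiocephalic markers; at each position the full line through the
    centerline point perpendicular to the local tangent is intersected
    with the outline and the length of the segment containing the point
    is recorded.
    """
    line_pts = np.asarray(centerline_px, dtype=float)
    if line_pts.ndim != 2 or line_pts.shape[0] < 2:
        raise ValidationError("centerline needs >= 2 points")
    sr, sc = c.geometry.spacing_row, c.geometry.spacing_col
    scale = np.array([sr, sc])
    line_mm = line_pts * scale
    poly = Polygon(c._plane_mm())
    center = LineString(line_mm)
    s0 = center.project(Point(np.asarray(stj_marker_px, float) * scale))
    s1 = center.project(Point(np.asarray(brachio_marker_px, float) * scale))
    lo, hi = sorted((s0, s1))
    if hi - lo < 1e-9:
        raise ValidationError("STJ and brachiocephalic markers coincide on centerline")
    reach = 4.0 * poly.length
    best = 0.0
    eps = min(1.0, (hi - lo) / 10)
    for s in np.linspace(lo, hi, n_samples):
        p = np.array(center.interpolate(s).coords[0])
        a = np.array(center.interpolate(max(s - eps, 0.0)).coords[0])
        b = np.array(center.interpolate(min(s + eps, center.length)).coords[0])
        t = b - a
        tn = np.linalg.norm(t)
        if tn < 1e-12:
            continue
        perp = np.array([-t[1], t[0]]) / tn
        chord = LineString([p - perp * reach, p + perp * reach]).intersection(poly)
        if chord.is_empty:
            continue
        pieces = chord.geoms if isinstance(chord, MultiLineString) else [chord]
        for piece in pieces:
            if piece.distance(Point(p)) < 1e-6:
                best = max(best, piece.length)
    if best == 0.0:
        raise ValidationError("centerline segment does not cross the vessel outline")
    return float(best)
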