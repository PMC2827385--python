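"""3-D vector/plane arithmetic and LVOT channel-axis reconstruction.

All positions are expressed in a right-handed RAS patient coordinate
frame in millimetres.  Image planes carry their placement in that frame
(origin of pixel (0, 0), unit row/column directions, pixel spacings);
pixel coordinates are (row, col) pairs and may be fractional.

The channel axis of the left ventricular outflow tract is not measured
directly: each of two oblique long-axis views (``LVOT1``/``LVOT2``)
yields the *projection* of the axis onto that view, as the vector
average of two manually drawn wall segments running proximal->distal on
either side of the sinus of Valsalva.  :func:`reconstruct_axis` lifts
the two planar projections back to the single 3-D direction consistent
with both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateGeometryError,
    GeometryError,
    InconsistentLandmarksError,
    InconsistentProjectionsError,
)

__all__ = [
    "normalize",
    "angle_between",
    "PlaneGeometry",
    "LandmarkSet",
    "pixel_to_patient",
    "patient_to_pixel",
    "in_plane_direction",
    "reconstruct_axis",
    "project_onto_plane",
]

_ZERO_TOL = 1e-9
#: two view planes with |nA x nB| below this are treated as parallel;
#: the protocol acquires near-orthogonal views, so anything close to
#: parallel indicates corrupt plane metadata.
PARALLEL_PLANE_TOL = 0.05


def _as_vec3(v, name: str = "vector") -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError(f"{name} has non-finite components: {a}")
    return a


def normalize(v, tol: float = _ZERO_TOL) -> np.ndarray:
    """Return ``v / |v|``; reject vectors with norm below *tol*."""
    a = _as_vec3(v)
    n = float(np.linalg.norm(a))
    if n < tol:
        raise GeometryError(f"cannot normalize near-zero vector (|v|={n:g})")
    return a / n


def angle_between(u, v) -> float:
    """Angle between two non-zero vectors in degrees, in [0, 180].

    The normalized dot product is clamped to [-1, 1] before the arccos
    so antiparallel inputs do not fall victim to rounding.
    """
    un = normalize(u)
    vn = normalize(v)
    c = float(np.clip(np.dot(un, vn), -1.0, 1.0))
    return math.degrees(math.acos(c))


def project_onto_plane(v, normal) -> np.ndarray:
    """Orthogonal projection of *v* onto the plane with unit *normal*."""
    a = _as_vec3(v)
    n = normalize(normal)
    return a - np.dot(a, n) * n


@dataclass(frozen=True)
class PlaneGeometry:
    """Placement of a 2-D image slice in 3-D patient space (RAS, mm).

    Parameters
    ----------
    origin
        Patient coordinates (mm) of pixel (0, 0).
    row_dir, col_dir
        Unit direction of increasing row / column index.  Must be
        mutually orthogonal within 1e-6.
    spacing_row, spacing_col
        Pixel spacing along each index, mm/pixel, strictly positive.
    """

    origin: np.ndarray
    row_dir: np.ndarray
    col_dir: np.ndarray
    spacing_row: float
    spacing_col: float

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_vec3(self.origin, "origin"))
        object.__setattr__(self, "row_dir", normalize(self.row_dir))
        object.__setattr__(self, "col_dir", normalize(self.col_dir))
        if abs(float(np.dot(self.row_dir, self.col_dir))) > 1e-6:
            raise GeometryError("row_dir and col_dir are not orthogonal")
        if not (self.spacing_row > 0 and self.spacing_col > 0):
            raise GeometryError("pixel spacings must be positive")

    @property
    def normal(self) -> np.ndarray:
        """Unit plane normal, ``row_dir x col_dir``."""
        return normalize(np.cross(self.row_dir, self.col_dir))

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "row_dir": self.row_dir.tolist(),
            "col_dir": self.col_dir.tolist(),
            "spacing_row": self.spacing_row,
            "spacing_col": self.spacing_col,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlaneGeometry":
        return cls(
            origin=np.asarray(d["origin"], dtype=float),
            row_dir=np.asarray(d["row_dir"], dtype=float),
            col_dir=np.asarray(d["col_dir"], dtype=float),
            spacing_row=float(d["spacing_row"]),
            spacing_col=float(d["spacing_col"]),
        )


@dataclass(frozen=True)
class LandmarkSet:
    """Four labeled points on one LVOT view (pixel coordinates).

    ``p1 -> p2`` and ``p3 -> p4`` are the two wall segments of the sinus
    of Valsalva, each oriented proximal (valve-plane end) to distal
    (sinotubular-ridge end) by convention; the file format stores the
    anatomical labels so the orientation is explicit.
    """

    p1: tuple[float, float]
    p2: tuple[float, float]
    p3: tuple[float, float]
    p4: tuple[float, float]

    def __post_init__(self):
        for name in ("p1", "p2", "p3", "p4"):
            p = tuple(float(c) for c in getattr(self, name))
            if len(p) != 2 or not all(math.isfinite(c) for c in p):
                raise GeometryError(f"landmark {name} must be a finite pixel pair")
            object.__setattr__(self, name, p)
        if self.p1 == self.p2 or self.p3 == self.p4:
            raise GeometryError("degenerate landmark segment (coincident endpoints)")

    def to_dict(self) -> dict:
        return {"p1": list(self.p1), "p2": list(self.p2),
                "p3": list(self.p3), "p4": list(self.p4)}

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(p1=tuple(d["p1"]), p2=tuple(d["p2"]),
                   p3=tuple(d["p3"]), p4=tuple(d["p4"]))


def pixel_to_patient(p, g: PlaneGeometry) -> np.ndarray:
    """Map a (row, col) pixel coordinate to patient coordinates (mm)."""
    pr, pc = (float(c) for c in p)
    if not (math.isfinite(pr) and math.isfinite(pc)):
        raise GeometryError("non-finite pixel coordinate")
    return g.origin + pr * g.spacing_row * g.row_dir + pc * g.spacing_col * g.col_dir


def patient_to_pixel(x, g: PlaneGeometry) -> tuple[float, float]:
    """Inverse of :func:`pixel_to_patient` for points lying in the plane."""
    d = _as_vec3(x) - g.origin
    return (float(np.dot(d, g.row_dir)) / g.spacing_row,
            float(np.dot(d, g.col_dir)) / g.spacing_col)


def in_plane_direction(l: LandmarkSet, g: PlaneGeometry,
                       tol: float = 1e-6) -> np.ndarray:
    """Projection of the outflow-channel direction onto one image plane.

    The two proximal->distal wall segments are mapped to patient
    coordinates and their vector sum (twice the vector average, same
    direction) is normalized.  A near-zero sum means the traced segments
    point in opposite directions, i.e. the landmarks are inconsistent.
    """
    seg1 = pixel_to_patient(l.p2, g) - pixel_to_patient(l.p1, g)
    seg2 = pixel_to_patient(l.p4, g) - pixel_to_patient(l.p3, g)
    s = seg1 + seg2
    if float(np.linalg.norm(s)) < tol * max(np.linalg.norm(seg1), np.linalg.norm(seg2)):
        raise InconsistentLandmarksError(
            "landmark segments nearly cancel; check proximal->distal orientation")
    return normalize(s)


def reconstruct_axis(pA, gA: PlaneGeometry, pB, gB: PlaneGeometry) -> np.ndarray:
    """Lift two planar projections of one direction back to 3-D.

    A direction ``d`` whose projection onto plane A is parallel to
    ``pA`` must lie in the plane spanned by ``pA`` and ``nA``, i.e. be
    orthogonal to ``pA x nA``; likewise for B.  Hence

        d  ∝  (pA x nA) x (pB x nB)

    The sign is fixed so ``d . (pA + pB) > 0``: both projections point
    distally by the landmark convention, so the axis does too.
    """
    pA = normalize(pA)
    pB = normalize(pB)
    nA = gA.normal
    nB = gB.normal
    if float(np.linalg.norm(np.cross(nA, nB))) < PARALLEL_PLANE_TOL:
        raise DegenerateGeometryError(
            "view planes are near-parallel; cannot triangulate the axis")
    d = np.cross(np.cross(pA, nA), np.cross(pB, nB))
    n = float(np.linalg.norm(d))
    if n < _ZERO_TOL:
        raise InconsistentProjectionsError(
            "projections are inconsistent with a single 3-D direction")
    d = d / n
    s = float(np.dot(d, pA + pB))
    if abs(s) < _ZERO_TOL:
        raise InconsistentProjectionsError(
            "cannot orient the reconstructed axis (projections cancel)")
    return d if s > 0 else -d
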