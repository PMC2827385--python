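"""Tubular flow phantom with a jet tilted by a known angle.

The phantom is a straight rigid tube (the aortic root) carrying a jet
whose direction is tilted by a configurable angle psi away from the tube
axis, with plug or parabolic speed profile and optional i.i.d. Gaussian
noise per velocity component.  It emits exactly what the measurement
pipeline consumes:

* a mid-sinus velocity slice (grid perpendicular to the tube axis, ROI
  mask of in-lumen pixels),
* two orthogonal LVOT-view planes containing the tube axis, each with
  four wall landmarks whose proximal->distal segments run parallel to
  the axis,
* a ground-truth record (tilt, axis, jet direction) for closing the
  recovery loop.

Because the landmark segments are parallel to the axis and both view
planes contain it, the reconstructed axis is exact and any measured
angle error is attributable to the jet-averaging step alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ..errors import ValidationError
from ..flowjet import VelocitySlice
from ..geometry import LandmarkSet, PlaneGeometry, normalize, patient_to_pixel

__all__ = ["PhantomConfig", "PhantomDataset", "generate_phantom"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, flow and noise parameters of the tube phantom.

    Defaults describe a realistic adolescent aortic root under peak
    systole: 15 mm lumen radius, 100 cm/s peak jet speed, 1 mm in-plane
    grid.  ``tilt_deg`` (psi) is the ground-truth misdirection angle,
    ``azimuth_deg`` the direction within the cross-section the jet
    leans toward.
    """

    tilt_deg: float = 0.0
    azimuth_deg: float = 0.0
    profile: str = "plug"            # "plug" or "parabolic"
    peak_speed: float = 100.0        # cm/s
    noise_sd: float = 0.0            # cm/s per velocity component
    radius_mm: float = 15.0
    length_mm: float = 80.0
    sinus_length_mm: float = 25.0    # proximal->distal landmark separation
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    spacing_mm: float = 1.0
    grid_n: int = 48
    slice_offset_mm: float = 0.0     # along the axis from the tube midpoint
    venc: float = 200.0
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.tilt_deg <= 60.0:
            raise ValidationError("tilt_deg must be in [0, 60]")
        if self.profile not in ("plug", "parabolic"):
            raise ValidationError("profile must be 'plug' or 'parabolic'")
        for name in ("peak_speed", "radius_mm", "length_mm",
                     "sinus_length_mm", "spacing_mm", "venc"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.grid_n < 4:
            raise ValidationError("grid_n too small to contain the lumen")
        if abs(self.slice_offset_mm) > self.length_mm / 2:
            raise ValidationError("slice plane lies outside the tube")


@dataclass
class PhantomDataset:
    """Everything a phantom run produces, in pipeline-ready form."""

    slice: VelocitySlice
    landmarks: dict[str, tuple[PlaneGeometry, LandmarkSet]]
    truth: dict

    @property
    def truth_axis(self) -> np.ndarray:
        return np.asarray(self.truth["axis"], dtype=float)

    @property
    def truth_jet_dir(self) -> np.ndarray:
        return np.asarray(self.truth["jet_dir"], dtype=float)


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing *axis* to a right-handed frame."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = normalize(np.cross(helper, axis))
    e2 = normalize(np.cross(axis, e1))
    return e1, e2


def generate_phantom(cfg: PhantomConfig,
                     rng: np.random.Generator | None = None) -> PhantomDataset:
    """Build the phantom dataset for one configuration.

    ``rng`` overrides ``cfg.seed`` when given; with neither, noise uses
    fresh OS entropy (only relevant when ``noise_sd > 0``).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    axis = normalize(np.asarray(cfg.axis, dtype=float))
    e1, e2 = _orthonormal_frame(axis)
    center = np.zeros(3)

    psi = math.radians(cfg.tilt_deg)
    az = math.radians(cfg.azimuth_deg)
    lean = math.cos(az) * e1 + math.sin(az) * e2
    jet_dir = math.cos(psi) * axis + math.sin(psi) * lean

    # --- mid-sinus velocity slice, grid perpendicular to the axis ------
    n, sp = cfg.grid_n, cfg.spacing_mm
    half = (n - 1) / 2.0
    slice_center = center + cfg.slice_offset_mm * axis
    origin = slice_center - half * sp * e1 - half * sp * e2
    geom = PlaneGeometry(origin=origin, row_dir=e1, col_dir=e2,
                         spacing_row=sp, spacing_col=sp)

    idx = np.arange(n, dtype=float)
    u = (idx[:, None] - half) * sp        # in-plane mm along e1 (rows)
    w = (idx[None, :] - half) * sp        # along e2 (cols)
    r2 = u**2 + w**2
    roi = r2 <= cfg.radius_mm**2
    if not np.any(roi):
        raise ValidationError("grid does not intersect the lumen")

    if cfg.profile == "plug":
        weight = roi.astype(float)
    else:
        weight = np.where(roi, 1.0 - r2 / cfg.radius_mm**2, 0.0)
    velocities = weight[:, :, None] * (cfg.peak_speed * jet_dir)[None, None, :]
    if cfg.noise_sd > 0:
        velocities = velocities + rng.normal(0.0, cfg.noise_sd, size=velocities.shape)
    # noise can nudge a component past venc only pathologically; clip to
    # keep the slice valid rather than fail a stochastic draw
    velocities = np.clip(velocities, -cfg.venc, cfg.venc)
    vslice = VelocitySlice(geometry=geom, velocities=velocities, roi_mask=roi,
                           phase_index=0, venc=cfg.venc)

    # --- two orthogonal LVOT views containing the axis -----------------
    landmarks: dict[str, tuple[PlaneGeometry, LandmarkSet]] = {}
    hs = cfg.sinus_length_mm / 2.0
    extent = max(cfg.length_mm, 4 * cfg.radius_mm)
    for name, wall_dir in (("LVOT1", e1), ("LVOT2", e2)):
        v_origin = center - (extent / 2) * wall_dir - (cfg.length_mm / 2) * axis
        v_geom = PlaneGeometry(origin=v_origin, row_dir=wall_dir, col_dir=axis,
                               spacing_row=sp, spacing_col=sp)
        pts = {
            "p1": center - cfg.radius_mm * wall_dir - hs * axis,
            "p2": center - cfg.radius_mm * wall_dir + hs * axis,
            "p3": center + cfg.radius_mm * wall_dir - hs * axis,
            "p4": center + cfg.radius_mm * wall_dir + hs * axis,
        }
        lset = LandmarkSet(**{k: patient_to_pixel(v, v_geom)
                              for k, v in pts.items()})
        landmarks[name] = (v_geom, lset)

    truth = {
        "tilt_deg": cfg.tilt_deg,
        "azimuth_deg": cfg.azimuth_deg,
        "axis": axis.tolist(),
        "jet_dir": jet_dir.tolist(),
        "n_roi_pixels": int(roi.sum()),
    }
    return PhantomDataset(slice=vslice, landmarks=landmarks, truth=truth)
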