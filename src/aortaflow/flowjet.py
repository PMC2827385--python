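"""Systolic flow-jet direction and jet/axis misdirection angle.

The jet direction is the unweighted arithmetic mean of the 3-component
velocity vectors over all *forward-flow* pixels inside the aortic ROI
of a mid-sinus slice at peak systole.  "Forward" means a positive
velocity component along the reconstructed LVOT channel axis (the
analysis reference); a config switch allows the slice normal instead,
which coincides with the axis when scan planning is perfect.

The misdirection angle — the flow-eccentricity metric this pipeline
exists to measure — is the angle between this mean jet vector and the
channel axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import GeometryError, NoForwardFlowError, ValidationError
from .geometry import PlaneGeometry, angle_between, normalize

__all__ = [
    "VelocitySlice",
    "forward_flow_mask",
    "jet_direction",
    "flow_jet_angle",
    "pick_peak_phase",
]


@dataclass
class VelocitySlice:
    """One cardiac phase of a 3-component velocity-encoded slice.

    Attributes
    ----------
    geometry
        Plane placement in patient space.
    velocities
        (rows, cols, 3) array, cm/s, vector components in the patient
        frame (not the in-plane frame).
    roi_mask
        (rows, cols) boolean, True inside the manually traced aorta.
    phase_index
        Cardiac phase number this slice was reconstructed at.
    venc
        Velocity-encoding limit of the acquisition, cm/s.  Components
        exceeding it indicate aliased or corrupt data.
    """

    geometry: PlaneGeometry
    velocities: np.ndarray
    roi_mask: np.ndarray
    phase_index: int = 0
    venc: float = 200.0

    def __post_init__(self):
        v = np.asarray(self.velocities, dtype=float)
        m = np.asarray(self.roi_mask, dtype=bool)
        if v.ndim != 3 or v.shape[2] != 3:
            raise ValidationError(f"velocities must be (rows, cols, 3), got {v.shape}")
        if m.shape != v.shape[:2]:
            raise ValidationError("roi_mask shape does not match velocity grid")
        if not np.all(np.isfinite(v)):
            raise ValidationError("velocity field contains non-finite values")
        if self.venc <= 0:
            raise ValidationError("venc must be positive")
        if np.any(np.abs(v[m]) > self.venc * (1 + 1e-9)):
            raise ValidationError("ROI velocity component exceeds venc (aliasing?)")
        self.velocities = v
        self.roi_mask = m


def _reference_direction(s: VelocitySlice, axis,
                         reference: Literal["axis", "normal"]) -> np.ndarray:
    if reference == "axis":
        return normalize(axis)
    if reference == "normal":
        return s.geometry.normal
    raise ValidationError(f"unknown forward-flow reference {reference!r}")


def forward_flow_mask(s: VelocitySlice, axis,
                      reference: Literal["axis", "normal"] = "axis") -> np.ndarray:
    """Boolean mask of ROI pixels with positive velocity along the reference.

    Raises :class:`NoForwardFlowError` when empty — the usual causes are
    a diastolic phase or a retrograde axis orientation.
    """
    if not np.any(s.roi_mask):
        raise ValidationError("ROI mask is empty")
    ref = _reference_direction(s, axis, reference)
    along = s.velocities @ ref
    mask = s.roi_mask & (along > 0)
    if not np.any(mask):
        raise NoForwardFlowError(
            f"no forward flow along reference at phase {s.phase_index}")
    return mask


def jet_direction(s: VelocitySlice, axis,
                  reference: Literal["axis", "normal"] = "axis",
                  ) -> tuple[np.ndarray, float]:
    """Mean systolic jet vector over forward-flow pixels.

    Returns
    -------
    direction : unit 3-vector (patient frame)
    speed : norm of the mean velocity vector, cm/s

    The average is unweighted over pixels; pixels do not contribute
    proportionally to their speed beyond their own vector.
    """
    mask = forward_flow_mask(s, axis, reference)
    mean_v = s.velocities[mask].mean(axis=0)
    speed = float(np.linalg.norm(mean_v))
    if speed < 1e-12:
        raise NoForwardFlowError("forward-flow vectors average to zero")
    return mean_v / speed, speed


def flow_jet_angle(s: VelocitySlice, axis,
                   reference: Literal["axis", "normal"] = "axis") -> float:
    """Misdirection angle (degrees) between the mean jet and the channel axis."""
    direction, _ = jet_direction(s, axis, reference)
    return angle_between(direction, axis)


def pick_peak_phase(slices: Sequence[VelocitySlice], axis,
                    reference: Literal["axis", "normal"] = "axis") -> int:
    """Index (into *slices*) of the phase with maximal mean forward speed.

    Helper for when peak systole was not identified upstream; phases
    with no forward flow at all are skipped.
    """
    if not slices:
        raise ValidationError("no phases supplied")
    best_i, best_speed = None, -np.inf
    for i, s in enumerate(slices):
        try:
            _, speed = jet_direction(s, axis, reference)
        except NoForwardFlowError:
            continue
        if speed > best_speed:
            best_i, best_speed = i, speed
    if best_i is None:
        raise NoForwardFlowError("no phase shows forward flow")
    return best_i
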