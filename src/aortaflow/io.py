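"""File formats: NIfTI velocity datasets, JSON sidecars/landmarks, CSV tables.

A velocity dataset is a pair ``<base>.nii`` + ``<base>.json``: the NIfTI
holds a (rows, cols, phases, 3) float array of velocity components in
cm/s in the patient frame; the sidecar carries the plane geometry, venc,
phase indices, units and a run-length-encoded ROI mask.  The sidecar is
authoritative for geometry (and is validated on read); the NIfTI affine
is populated for viewer convenience.

Landmark files are JSON with one entry per LVOT view (plane geometry
plus four labeled pixel points) and round-trip bit-exactly: floats are
serialized with ``repr`` precision, which Python guarantees to re-read
to the identical double.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .flowjet import VelocitySlice
from .geometry import LandmarkSet, PlaneGeometry

__all__ = [
    "write_velocity_dataset",
    "read_velocity_dataset",
    "write_landmark_file",
    "read_landmark_file",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_duplicates_csv",
    "RunManifest",
    "rle_encode",
    "rle_decode",
    "file_digest",
]

COHORT_REQUIRED_COLUMNS = ("id", "group", "flow_angle_deg")


def rle_encode(mask: np.ndarray) -> list[list[int]]:
    """Run-length encode a boolean mask (row-major) as [start, length] runs."""
    flat = np.asarray(mask, dtype=bool).ravel()
    runs = []
    diff = np.diff(flat.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if flat.size and flat[0]:
        starts = np.r_[0, starts]
    if flat.size and flat[-1]:
        ends = np.r_[ends, flat.size]
    for s, e in zip(starts, ends):
        runs.append([int(s), int(e - s)])
    return runs


def rle_decode(runs: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for s, length in runs:
        flat[s:s + length] = True
    return flat.reshape(shape)


def write_velocity_dataset(base: str | Path, slices: list[VelocitySlice]) -> None:
    """Write a phase stack sharing one geometry/ROI to ``base.nii`` + ``base.json``."""
    if not slices:
        raise ValidationError("no slices to write")
    g = slices[0].geometry
    roi = slices[0].roi_mask
    for s in slices[1:]:
        if s.velocities.shape != slices[0].velocities.shape:
            raise ValidationError("phase slices have inconsistent grids")
    base = Path(base)
    data = np.stack([s.velocities for s in slices], axis=2)  # (r, c, t, 3)
    affine = np.eye(4)
    affine[:3, 0] = g.row_dir * g.spacing_row
    affine[:3, 1] = g.col_dir * g.spacing_col
    affine[:3, 2] = g.normal
    affine[:3, 3] = g.origin
    nib.save(nib.Nifti1Image(data.astype(np.float64), affine),
             str(base.with_suffix(".nii")))
    sidecar = {
        "format_version": 1,
        "units": "cm/s",
        "geometry": g.to_dict(),
        "venc": slices[0].venc,
        "phase_indices": [s.phase_index for s in slices],
        "roi_rle": rle_encode(roi),
        "grid_shape": list(roi.shape),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_velocity_dataset(base: str | Path) -> list[VelocitySlice]:
    """Read and validate a velocity dataset written by the twin writer."""
    base = Path(base)
    sidecar_path = base.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValidationError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("units") != "cm/s":
        raise ValidationError(f"unexpected velocity units {sidecar.get('units')!r}")
    geometry = PlaneGeometry.from_dict(sidecar["geometry"])  # validates axes
    shape = tuple(sidecar["grid_shape"])
    roi = rle_decode(sidecar["roi_rle"], shape)
    data = np.asarray(nib.load(str(base.with_suffix(".nii"))).dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 3 or data.shape[:2] != shape:
        raise ValidationError(f"velocity volume has unexpected shape {data.shape}")
    phases = sidecar["phase_indices"]
    if len(phases) != data.shape[2]:
        raise ValidationError("phase count mismatch between volume and sidecar")
    return [VelocitySlice(geometry=geometry, velocities=data[:, :, t, :],
                          roi_mask=roi, phase_index=int(phases[t]),
                          venc=float(sidecar["venc"]))
            for t in range(data.shape[2])]


def write_landmark_file(path: str | Path,
                        views: dict[str, tuple[PlaneGeometry, LandmarkSet]]) -> None:
    payload = {name: {"geometry": g.to_dict(), "landmarks": l.to_dict()}
               for name, (g, l) in views.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_landmark_file(path: str | Path,
                       ) -> dict[str, tuple[PlaneGeometry, LandmarkSet]]:
    payload = json.loads(Path(path).read_text())
    return {name: (PlaneGeometry.from_dict(v["geometry"]),
                   LandmarkSet.from_dict(v["landmarks"]))
            for name, v in payload.items()}


def write_cohort_csv(path: str | Path, df: pd.DataFrame) -> None:
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns {missing}")
    df.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns {missing}")
    if df["id"].duplicated().any():
        raise ValidationError("duplicate subject ids in cohort table")
    bad = set(df["group"].unique()) - {"BAV", "control"}
    if bad:
        raise ValidationError(f"unknown group labels {sorted(bad)}")
    return df


def read_duplicates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"subject", "context", "quantity", "replicate", "value"}
    if not needed <= set(df.columns):
        raise ValidationError(f"duplicate table needs columns {sorted(needed)}")
    return df


def file_digest(path: str | Path) -> str:
    return "sha256:" + hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every CLI/pipeline output."""

    seed: int | None
    parameters: dict
    inputs: dict = field(default_factory=dict)     # path -> digest
    tool_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))
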