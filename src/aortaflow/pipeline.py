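"""End-to-end orchestration: simulate or load, measure, analyze, report.

``run_full_pipeline`` chains every stage the study performed: per-subject
jet-angle measurement (through the landmark -> axis -> jet path, not by
copying the simulated truth), per-subject diameter measurement on traced
contours with BSA adjustment, cohort statistics, and the
observer-agreement table from duplicate measurements.  Each run writes a
manifest; identical manifest inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import agreement_table
from .cohort_stats import (
    angle_diameter_correlations,
    biomarker_correlations,
    group_summary,
)
from .errors import AortaflowError, StageError
from .flowjet import flow_jet_angle
from .geometry import in_plane_direction, reconstruct_axis
from .io import RunManifest, read_cohort_csv, read_duplicates_csv
from .morphometry import LEVELS, Anthropometrics, ContourROI, bsa_adjust, haycock_bsa
from .synthetic.cohort import CohortConfig, generate_cohort, simulate_duplicates
from .synthetic.phantom import PhantomConfig, generate_phantom

__all__ = ["measure_phantom_angle", "measure_subject", "run_full_pipeline"]


def measure_phantom_angle(dataset) -> dict:
    """Jet/axis angle of a phantom dataset via the full measurement path.

    The channel axis is triangulated from the two LVOT-view landmark
    sets, never taken from the ground-truth record, so the returned
    angle exercises every geometric stage.
    """
    (g1, l1) = dataset.landmarks["LVOT1"]
    (g2, l2) = dataset.landmarks["LVOT2"]
    p1 = in_plane_direction(l1, g1)
    p2 = in_plane_direction(l2, g2)
    axis = reconstruct_axis(p1, g1, p2, g2)
    angle = flow_jet_angle(dataset.slice, axis)
    return {"angle_deg": angle, "axis": axis.tolist(),
            "truth_tilt_deg": dataset.truth["tilt_deg"]}


def _circle_contour(diameter_mm: float, geometry, n_points: int = 64,
                    center_px: tuple[float, float] = (40.0, 40.0)) -> np.ndarray:
    theta = np.linspace(0.0, 2 * math.pi, n_points, endpoint=False)
    r_row = diameter_mm / 2.0 / geometry.spacing_row
    r_col = diameter_mm / 2.0 / geometry.spacing_col
    return np.column_stack([center_px[0] + r_row * np.cos(theta),
                            center_px[1] + r_col * np.sin(theta)])


def measure_subject(row: pd.Series, rng: np.random.Generator,
                    phantom_kw: dict | None = None) -> dict:
    """Re-measure one simulated subject through the imaging pipeline.

    A phantom is built whose true tilt is the subject's flow angle and
    whose lumen radius follows the subject's SOV size; the jet angle is
    then measured from the velocity slice, and the four diameters from
    64-point circular contours of the subject's true vessel sizes.
    """
    kw = {"noise_sd": 3.0, "grid_n": 40, "peak_speed": 100.0}
    if phantom_kw:
        kw.update(phantom_kw)
    cfg = PhantomConfig(tilt_deg=float(row["flow_angle_deg"]),
                        azimuth_deg=float(rng.uniform(0.0, 360.0)),
                        radius_mm=float(row["diam_sov_mm"]) / 2.0, **kw)
    dataset = generate_phantom(cfg, rng=rng)
    measured = measure_phantom_angle(dataset)

    bsa = haycock_bsa(Anthropometrics(float(row["height_cm"]),
                                      float(row["weight_kg"])))
    out = {"id": row["id"], "group": row["group"],
           "flow_angle_deg": measured["angle_deg"], "bsa_m2": bsa}
    for level in LEVELS:
        true_mm = float(row[f"diam_{level.lower()}_mm"])
        contour = ContourROI(
            vertices=_circle_contour(true_mm, dataset.slice.geometry),
            geometry=dataset.slice.geometry, level_label=level)
        from .morphometry import max_diameter
        d = max_diameter(contour)
        out[f"diam_{level.lower()}_mm"] = d
        out[f"diam_{level.lower()}_adj"] = bsa_adjust(d, bsa)
    for marker in ("mmp2", "mmp9", "timp1", "timp2"):
        if marker in row.index:
            out[marker] = row[marker]
    return out


def _report_round(df: pd.DataFrame) -> pd.DataFrame:
    """Report rounding: angles/mm to 0.01, p-values to 3 significant figures."""
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind != "f":
            continue
        if c in ("p", "cv_percent"):
            out[c] = out[c].map(lambda v: float(f"{v:.3g}"))
        else:
            out[c] = out[c].round(2)
    return out


def run_full_pipeline(out_dir: str | Path, seed: int = 0,
                      cohort_csv: str | Path | None = None,
                      duplicates_csv: str | Path | None = None,
                      cohort_config: CohortConfig | None = None,
                      phantom_kw: dict | None = None) -> dict:
    """Run simulate -> measure -> analyze and write the results bundle.

    With no ``cohort_csv`` a cohort is simulated from ``cohort_config``
    (defaults reproduce the study's group structure).  Outputs under
    *out_dir*: ``subject_measurements.csv``, ``cohort_stats.json``,
    ``reproducibility.csv`` and ``manifest.json``.  Returns the result
    dict that was serialized.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed, parameters={
        "cohort_csv": str(cohort_csv) if cohort_csv else None,
        "duplicates_csv": str(duplicates_csv) if duplicates_csv else None,
    })
    root = np.random.SeedSequence(seed)
    sim_ss, subj_ss, dup_ss = root.spawn(3)

    # stage: cohort ---------------------------------------------------------
    try:
        if cohort_csv is not None:
            cohort = read_cohort_csv(cohort_csv)
            manifest.add_input(cohort_csv)
        else:
            cfg = cohort_config or CohortConfig()
            cohort = generate_cohort(cfg, rng=np.random.default_rng(sim_ss))
    except AortaflowError as e:
        raise StageError("cohort", None, e) from e

    # stage: per-subject measurement ---------------------------------------
    measured_rows = []
    can_measure = {"height_cm", "weight_kg", "diam_sov_mm"} <= set(cohort.columns)
    if can_measure:
        child_rngs = [np.random.default_rng(s) for s in subj_ss.spawn(len(cohort))]
        for (_, row), rng in zip(cohort.iterrows(), child_rngs):
            try:
                measured_rows.append(measure_subject(row, rng, phantom_kw))
            except AortaflowError as e:
                raise StageError("measurement", str(row["id"]), e) from e
        measured = pd.DataFrame(measured_rows)
    else:
        measured = cohort  # externally measured table: analyze as-is
    _report_round(measured).to_csv(out_dir / "subject_measurements.csv", index=False)

    # stage: cohort statistics ---------------------------------------------
    try:
        results = {
            "group_summary": group_summary(measured).to_dict(orient="records"),
            "correlations": {
                name: angle_diameter_correlations(measured, group=g)
                .to_dict(orient="records")
                for name, g in (("pooled", None), ("BAV", "BAV"),
                                ("control", "control"))
            },
        }
        biomarkers = biomarker_correlations(measured)
        if len(biomarkers):
            results["biomarkers"] = biomarkers.to_dict(orient="records")
    except AortaflowError as e:
        raise StageError("cohort_stats", None, e) from e
    (out_dir / "cohort_stats.json").write_text(json.dumps(results, indent=1))

    # stage: reproducibility ------------------------------------------------
    try:
        if duplicates_csv is not None:
            dups = read_duplicates_csv(duplicates_csv)
            manifest.add_input(duplicates_csv)
        else:
            dups = simulate_duplicates(measured,
                                       rng=np.random.default_rng(dup_ss))
        repro = agreement_table(dups)
    except AortaflowError as e:
        raise StageError("reproducibility", None, e) from e
    _report_round(repro).to_csv(out_dir / "reproducibility.csv", index=False)

    manifest.write(out_dir / "manifest.json")
    return results
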