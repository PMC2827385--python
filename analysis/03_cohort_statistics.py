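"""Group comparisons and correlation tables on the simulated cohort.

Reproduces the analysis structure of the study on results/cohort.csv:
BAV-vs-control pooled t-tests per variable, Pearson angle-diameter
correlations per group and pooled, and the Spearman biomarker block
(BAV only).  Run 02_simulate_cohort.py first.
"""

import sys
from pathlib import Path

from aortaflow.cohort_stats import (
    angle_diameter_correlations,
    biomarker_correlations,
    group_summary,
)
from aortaflow.io import read_cohort_csv

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    cohort_path = OUT / "cohort.csv"
    if not cohort_path.exists():
        print("run analysis/02_simulate_cohort.py first", file=sys.stderr)
        return 1
    df = read_cohort_csv(cohort_path)

    summary = group_summary(df)
    summary.to_csv(OUT / "group_summary.csv", index=False)
    angle = summary.set_index("variable").loc["flow_angle_deg"]
    print(f"flow angle: BAV {angle['mean_bav']:.2f} vs control "
          f"{angle['mean_control']:.2f} deg (p = {angle['p']:.3g})")

    frames = []
    for name, g in (("pooled", None), ("BAV", "BAV"), ("control", "control")):
        tbl = angle_diameter_correlations(df, group=g).assign(population=name)
        frames.append(tbl)
        sig = tbl[tbl["p"] < 0.05]["level"].tolist()
        print(f"{name:8s} significant angle-diameter correlations: "
              f"{', '.join(sig) if sig else 'none'}")
    import pandas as pd
    pd.concat(frames).to_csv(OUT / "angle_diameter_correlations.csv", index=False)

    bio = biomarker_correlations(df)
    bio.to_csv(OUT / "biomarker_correlations.csv", index=False)
    sig = bio[bio["p"] < 0.05]
    for _, row in sig.iterrows():
        print(f"biomarker {row['biomarker']} vs {row['against']}: "
              f"rho = {row['rho']:.3f} (p = {row['p']:.3g})")
    print(f"tables -> {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
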