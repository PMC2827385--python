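"""Observer-agreement analysis on simulated duplicate measurements.

Simulates two reads per subject (intra-rater) and reads by a second
observer (inter-rater) for the ascending-aorta diameter and the flow
angle, then computes the agreement table: replicate SD, CV%, Lin CCC
and Bland-Altman 95% limits.  Run 02_simulate_cohort.py first.
"""

import sys
from pathlib import Path

import numpy as np

from aortaflow.agreement import agreement_table
from aortaflow.io import read_cohort_csv
from aortaflow.synthetic import simulate_duplicates

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    cohort_path = OUT / "cohort.csv"
    if not cohort_path.exists():
        print("run analysis/02_simulate_cohort.py first", file=sys.stderr)
        return 1
    df = read_cohort_csv(cohort_path)
    dups = simulate_duplicates(df, rng=np.random.default_rng(SEED))
    table = agreement_table(dups)
    table.to_csv(OUT / "reproducibility.csv", index=False)
    for _, row in table.iterrows():
        print(f"{row['quantity']:16s} {row['context']:5s}  "
              f"replicate SD {row['replicate_sd']:.2f}  "
              f"CV {row['cv_percent']:.1f}%  CCC {row['ccc']:.3f}  "
              f"BA [{row['ba_lower']:.2f}, {row['ba_upper']:.2f}]")
    print(f"table -> {OUT / 'reproducibility.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
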