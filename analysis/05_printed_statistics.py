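"""Re-derive published statistics that depend only on printed summaries.

The study's raw images and cohort are unavailable, but several printed
numbers are functions of other printed numbers: correlation p-values
follow from (r, N) via the exact t transform, the angle group-comparison
p from the group means/SEMs/sizes, and the reproducibility CV from the
replicate SD and grand mean.  Recomputing them checks our statistical
routines against the published tables.
"""

import json
import sys
from pathlib import Path

from aortaflow.agreement import cv_percent
from aortaflow.cohort_stats import pearson_p_from_r, ttest_from_summary

OUT = Path(__file__).resolve().parents[1] / "results"

#: printed (r, N) pairs: pooled population and BAV-only angle-diameter rows
PRINTED_CORRELATIONS = {
    "pooled_SOV": (0.405, 28), "pooled_STJ": (0.562, 28),
    "pooled_AAO": (0.645, 28), "pooled_AOV": (0.159, 28),
    "bav_SOV": (0.386, 18), "bav_STJ": (0.472, 18), "bav_AAO": (0.536, 18),
}


def main() -> None:
    out = {}
    for name, (r, n) in PRINTED_CORRELATIONS.items():
        out[f"p_{name}"] = pearson_p_from_r(r, n)
        print(f"{name:12s} r={r:6.3f} N={n}  ->  p = {out[f'p_{name}']:.3f}")
    t, df, p = ttest_from_summary(17.54, 0.87, 18, 10.01, 1.29, 10)
    out["angle_ttest"] = {"t": t, "df": df, "p": p}
    print(f"angle group comparison: t = {t:.2f} (df {df:.0f}), p = {p:.2g}")
    out["flow_angle_intra_cv_pct"] = cv_percent(13.7, 1.64)
    print(f"intra-rater flow-angle CV: {out['flow_angle_intra_cv_pct']:.1f} %")
    OUT.mkdir(exist_ok=True)
    (OUT / "printed_statistics.json").write_text(json.dumps(out, indent=1))
    print(f"values -> {OUT / 'printed_statistics.json'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
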