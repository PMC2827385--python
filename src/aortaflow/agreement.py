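"""Observer-agreement statistics for duplicate measurements.

Intra-rater agreement compares two measurements of the same quantity by
one observer; inter-rater compares measurements by two observers.  The
reported statistics are the within-subject replicate SD, the coefficient
of variation against the grand mean, Lin's concordance correlation
coefficient, and Bland-Altman 95% limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "DuplicateSet",
    "replicate_sd",
    "cv_percent",
    "lin_ccc",
    "bland_altman",
    "agreement_table",
]


@dataclass
class DuplicateSet:
    """Paired repeat measurements of one quantity across subjects.

    ``m1[i]`` and ``m2[i]`` are the two measurements for subject *i*;
    ``context`` records whether the pair is same-observer (intra) or
    two-observer (inter).
    """

    m1: np.ndarray
    m2: np.ndarray
    context: Literal["intra", "inter"] = "intra"
    quantity: str = ""

    def __post_init__(self):
        m1 = np.asarray(self.m1, dtype=float)
        m2 = np.asarray(self.m2, dtype=float)
        if m1.shape != m2.shape or m1.ndim != 1:
            raise ValidationError("m1 and m2 must be equal-length 1-D vectors")
        if m1.size < 2:
            raise ValidationError("need >= 2 measurement pairs")
        if not (np.all(np.isfinite(m1)) and np.all(np.isfinite(m2))):
            raise ValidationError("non-finite measurement values")
        if self.context not in ("intra", "inter"):
            raise ValidationError("context must be 'intra' or 'inter'")
        self.m1, self.m2 = m1, m2


def _pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("need equal-length vectors with n >= 2")
    return x, y


def replicate_sd(d: DuplicateSet) -> float:
    """Within-subject SD of duplicate measurements.

    For duplicates the one-way within-subject variance reduces to
    ``sum((m1-m2)^2) / (2n)``; the square root is in the units of the
    measurement.
    """
    diff = d.m1 - d.m2
    return float(np.sqrt(np.sum(diff**2) / (2 * diff.size)))


def cv_percent(mean_value: float, sd: float) -> float:
    """Coefficient of variation, percent: 100*sd/|mean|."""
    if mean_value == 0:
        raise ValidationError("CV undefined for zero mean")
    return 100.0 * float(sd) / abs(float(mean_value))


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    ``CCC = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` with 1/n
    moment normalization (Lin's original estimator).  Penalizes both
    scatter around the identity line and location/scale shift, so
    |CCC| <= |Pearson r| with equality only when the best fit is the
    identity.  Degenerate conventions: both vectors constant and equal
    -> 1; constant and unequal -> 0.
    """
    x, y = _pairs(x, y)
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        return 1.0  # identical constant vectors agree perfectly
    return 2.0 * sxy / denom


def bland_altman(x, y) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement for paired methods.

    Returns ``(bias, lower, upper)`` where the limits are
    ``bias -/+ 1.96*sd`` with the sample (n-1) SD of the differences
    x - y.  Zero inside the interval is the no-observer-bias criterion.
    """
    x, y = _pairs(x, y)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def agreement_table(df: pd.DataFrame) -> pd.DataFrame:
    """Reproducibility table from a long duplicate-measurement CSV.

    Expects columns ``subject, context, quantity, replicate, value``
    with two replicates per (subject, context, quantity).  Emits one row
    per quantity and context: grand mean, replicate SD, CV%, Lin CCC and
    the Bland-Altman interval — the shape of a published
    reproducibility table.
    """
    needed = {"subject", "context", "quantity", "replicate", "value"}
    if not needed <= set(df.columns):
        raise ValidationError(f"duplicate table needs columns {sorted(needed)}")
    rows = []
    for (quantity, context), g in df.groupby(["quantity", "context"], sort=True):
        wide = g.pivot_table(index="subject", columns="replicate", values="value")
        if wide.shape[1] != 2:
            raise ValidationError(
                f"{quantity}/{context}: expected exactly 2 replicates, "
                f"got {wide.shape[1]}")
        wide = wide.dropna()
        d = DuplicateSet(wide.iloc[:, 0].to_numpy(), wide.iloc[:, 1].to_numpy(),
                         context=context, quantity=quantity)
        sd = replicate_sd(d)
        grand_mean = float(np.concatenate([d.m1, d.m2]).mean())
        bias, lo, hi = bland_altman(d.m1, d.m2)
        rows.append({
            "quantity": quantity, "context": context, "n_pairs": d.m1.size,
            "mean_value": grand_mean, "replicate_sd": sd,
            "cv_percent": cv_percent(grand_mean, sd),
            "ccc": lin_ccc(d.m1, d.m2),
            "ba_bias": bias, "ba_lower": lo, "ba_upper": hi,
            "bias_evidence": not (lo <= 0.0 <= hi),
        })
    return pd.DataFrame(rows)
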