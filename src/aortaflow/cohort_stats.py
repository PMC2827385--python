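"""Group comparisons and correlation analysis for the study cohort.

Implements the statistical toolbox the study applied: pooled-variance
unpaired Student's t-tests for BAV-vs-control group comparisons (Welch
behind a flag), Pearson correlation with the exact t-transform p-value,
Spearman rank correlation (mid-ranks for ties, t-approximation p, exact
permutation p behind a flag for small n), Shapiro-Wilk normality
checks, and a Mahalanobis-distance multivariate outlier screen whose
flags are reported but never used to drop rows.

Closed-form twins (:func:`pearson_p_from_r`, :func:`ttest_from_summary`)
recompute p-values from printed summary statistics (r with N, or
mean/SEM/n per group), for verification against published tables.

Table-shaped drivers (:func:`group_summary`,
:func:`angle_diameter_correlations`, :func:`biomarker_correlations`)
assemble the full per-level output from a cohort table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "pearson_r",
    "pearson_p_from_r",
    "spearman_r",
    "unpaired_ttest",
    "ttest_from_summary",
    "shapiro_wilk",
    "mahalanobis_screen",
    "group_summary",
    "angle_diameter_correlations",
    "biomarker_correlations",
    "DIAMETER_COLUMNS",
    "BIOMARKER_COLUMNS",
]

#: cohort CSV columns holding BSA-adjusted diameters, keyed by level
DIAMETER_COLUMNS = {
    "AOV": "diam_aov_adj",
    "SOV": "diam_sov_adj",
    "STJ": "diam_stj_adj",
    "AAO": "diam_aao_adj",
}
BIOMARKER_COLUMNS = ("mmp2", "mmp9", "timp1", "timp2")


def _clean_xy(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < min_n:
        raise ValidationError(f"need >= {min_n} complete pairs, got {x.size}")
    return x, y


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p from the exact t transform.

    ``t = r*sqrt(n-2)/sqrt(1-r^2)`` referred to a central t with n-2 df;
    this is the classical test under bivariate normality.
    """
    x, y = _clean_xy(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance input to Pearson correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:  # exactly collinear sample: p underflows to 0
        return r, 0.0
    return r, pearson_p_from_r(r, x.size)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a printed correlation coefficient at sample size n."""
    if n < 3:
        raise ValidationError("need n >= 3")
    r = float(r)
    if abs(r) >= 1.0:
        warnings.warn("|r| >= 1: returning p = 0 by convention")
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, n - 2))


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_r(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rho (mid-ranks for ties) and two-sided p.

    Default p uses the t approximation on rho, matching
    :func:`pearson_r` applied to ranks.  With ``exact=True`` and
    n <= 8 the p-value is the exact permutation tail probability
    P(|rho_perm| >= |rho|) under the null of exchangeable ranks; for
    larger n the t approximation is used with a warning (full
    enumeration is combinatorially impractical).
    """
    x, y = _clean_xy(x, y)
    rx, ry = _midranks(x), _midranks(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValidationError("zero variance in ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if exact:
        if n <= 8:
            obs = abs(rho)
            count = total = 0
            sy = ry - ry.mean()
            sx = rx - rx.mean()
            denom = np.sqrt((sx**2).sum() * (sy**2).sum())
            for perm in itertools.permutations(range(n)):
                r_p = float((sx[list(perm)] * sy).sum()) / denom
                count += abs(r_p) >= obs - 1e-12
                total += 1
            return rho, count / total
        warnings.warn("exact Spearman p only enumerated for n <= 8; "
                      "falling back to t approximation")
    if abs(rho) >= 1.0:  # perfect rank agreement: t transform degenerates
        return rho, 0.0
    return rho, pearson_p_from_r(rho, n)


def unpaired_ttest(a, b, welch: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test: (t, df, two-sided p).

    Pooled-variance Student's test by default (the study's method);
    ``welch=True`` drops the equal-variance assumption.  Degenerate
    zero-variance inputs follow the conventions: equal means -> t=0,
    p=1; unequal means -> infinite t, p=0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        df = a.size + b.size - 2
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(df), 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), float(df), 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def ttest_from_summary(mean_a: float, sem_a: float, n_a: int,
                       mean_b: float, sem_b: float, n_b: int,
                       ) -> tuple[float, float, float]:
    """Pooled Student's t-test from printed group summaries (mean, SEM, n).

    Published tables report mean +/- SEM; the group SDs are recovered as
    ``SEM * sqrt(n)`` before pooling.  Returns (t, df, two-sided p).
    """
    if sem_a < 0 or sem_b < 0:
        raise ValidationError("SEMs must be non-negative")
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs n >= 2")
    sd_a = sem_a * np.sqrt(n_a)
    sd_b = sem_b * np.sqrt(n_b)
    df = n_a + n_b - 2
    if sd_a == 0 and sd_b == 0:
        if np.isclose(mean_a, mean_b):
            return 0.0, float(df), 1.0
        return float(np.sign(mean_a - mean_b) * np.inf), float(df), 0.0
    res = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                     equal_var=True)
    return float(res.statistic), float(df), float(res.pvalue)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p (delegates to the vetted scipy routine)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= x.size <= 5000:
        raise ValidationError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValidationError("constant vector has no defined W statistic")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def mahalanobis_screen(pairs, alpha: float = 0.025) -> pd.DataFrame:
    """Multivariate outlier screen by squared Mahalanobis distance.

    *pairs* is an (n, k) table (k >= 1).  Each row's squared distance
    from the sample mean under the sample covariance is compared with
    the chi-square(k) quantile at 1-alpha.  Flags are for reporting
    only — the screened rows stay in every downstream analysis, as in
    the study protocol.
    """
    X = np.asarray(pairs, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if n <= k + 1:
        raise ValidationError("need n > n_columns + 1 for a stable covariance")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    cov = np.cov(X, rowvar=False, ddof=1).reshape(k, k)
    if np.linalg.matrix_rank(cov) < k:
        raise ValidationError("singular sample covariance")
    prec = np.linalg.inv(cov)
    d = X - X.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", d, prec, d)
    thresh = float(stats.chi2.ppf(1 - alpha, df=k))
    return pd.DataFrame({"d2": d2, "flagged": d2 > thresh})


# ---------------------------------------------------------------------------
# Table-shaped drivers over a cohort DataFrame
# ---------------------------------------------------------------------------

def _require_groups(df: pd.DataFrame, min_per_group: int = 3) -> None:
    if "group" not in df.columns:
        raise ValidationError("cohort table needs a 'group' column")
    counts = df["group"].value_counts()
    for g in ("BAV", "control"):
        if counts.get(g, 0) < min_per_group:
            raise ValidationError(
                f"group {g!r} has {counts.get(g, 0)} subjects; need >= {min_per_group}")


def group_summary(df: pd.DataFrame, welch: bool = False) -> pd.DataFrame:
    """Per-variable group means +/- SEM and the BAV-vs-control p-value.

    Covers the four BSA-adjusted diameters and the flow-jet angle; one
    row per variable with n/mean/sem per group and the pooled Student's
    t-test p, mirroring the published group-comparison table.
    """
    _require_groups(df)
    variables = list(DIAMETER_COLUMNS.values()) + ["flow_angle_deg"]
    rows = []
    for var in variables:
        a = df.loc[df["group"] == "BAV", var].dropna().to_numpy()
        b = df.loc[df["group"] == "control", var].dropna().to_numpy()
        t, dof, p = unpaired_ttest(a, b, welch=welch)
        rows.append({
            "variable": var,
            "n_bav": a.size, "mean_bav": a.mean(),
            "sem_bav": a.std(ddof=1) / np.sqrt(a.size),
            "n_control": b.size, "mean_control": b.mean(),
            "sem_control": b.std(ddof=1) / np.sqrt(b.size),
            "t": t, "df": dof, "p": p,
        })
    return pd.DataFrame(rows)


def angle_diameter_correlations(df: pd.DataFrame, group: str | None = None,
                                ) -> pd.DataFrame:
    """Pearson r/p of flow angle vs adjusted diameter per aortic level.

    ``group=None`` pools BAV and controls (the combined-population
    analysis); otherwise restricts to one group.
    """
    sub = df if group is None else df[df["group"] == group]
    rows = []
    for level, col in DIAMETER_COLUMNS.items():
        pair = sub[["flow_angle_deg", col]].dropna()
        r, p = pearson_r(pair["flow_angle_deg"], pair[col])
        rows.append({"level": level, "n": len(pair), "r": r, "p": p})
    return pd.DataFrame(rows)


def biomarker_correlations(df: pd.DataFrame, exact: bool = False) -> pd.DataFrame:
    """Spearman correlations of plasma biomarkers with diameters and angle.

    Biomarkers were assayed in BAV patients only; rows are restricted to
    that group and each correlation uses pairwise-complete observations
    with its n reported.
    """
    sub = df[df["group"] == "BAV"]
    targets = {**DIAMETER_COLUMNS, "ANGLE": "flow_angle_deg"}
    rows = []
    for marker in BIOMARKER_COLUMNS:
        if marker not in sub.columns:
            continue
        for label, col in targets.items():
            pair = sub[[marker, col]].dropna()
            if len(pair) < 3:
                continue
            rho, p = spearman_r(pair[marker], pair[col], exact=exact)
            rows.append({"biomarker": marker, "against": label,
                         "n": len(pair), "rho": rho, "p": p})
    return pd.DataFrame(rows)
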