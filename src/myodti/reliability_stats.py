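"""Inter-rater and inter-method reliability statistics.

The battery applied to paired per-muscle metric tables: coefficient of
variation (CV = sample SD / mean), paired t-tests, Pearson correlation,
intraclass correlation (two-way mixed model from the ANOVA mean squares;
absolute-agreement ICC(A,1) by default, consistency ICC(C,1) selectable),
Cronbach's alpha with the two raters as items, and Bland-Altman limits of
agreement (mean difference +/- 1.96 SD of differences).  Sample standard
deviations (n-1 denominator) are used throughout.

ICC from the two-way mean squares with n subjects and k = 2 raters:

    ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE)
    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

where MSR, MSC, MSE are the rows (subjects), columns (raters) and residual
mean squares.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cv",
    "cv_from_summary",
    "paired_t",
    "pearson_r",
    "icc",
    "cronbach_alpha",
    "bland_altman",
    "BlandAltman",
    "ReliabilityReport",
    "reliability_report",
]


def cv(values, ddof: int = 1) -> float:
    """Coefficient of variation: sample standard deviation over mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=ddof) / mean)


def cv_from_summary(mean: float, sd: float) -> float:
    """CV from printed summary statistics (SD / mean)."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return sd / mean


def _pairs(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired inputs must be equal-length 1D arrays")
    return a, b


def paired_t(a, b) -> tuple[float, float]:
    """Classical paired t-test; two-sided p from Student t with n-1 df.

    Degenerate difference variances are handled explicitly: all-zero
    differences give (0, 1); zero variance with nonzero mean gives the
    p -> 0 limit.
    """
    a, b = _pairs(a, b)
    if len(a) < 3:
        raise ValueError("paired t-test needs n >= 3")
    d = a - b
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def pearson_r(a, b) -> float:
    a, b = _pairs(a, b)
    if len(a) < 3:
        raise ValueError("Pearson r needs n >= 3")
    return float(stats.pearsonr(a, b)[0])


def _mean_squares(a: np.ndarray, b: np.ndarray):
    x = np.column_stack([a, b])  # n subjects x k raters
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc(a, b, model: str = "absolute") -> float:
    """Single-measures two-way ICC for two raters.

    ``model='absolute'`` gives ICC(A,1) (two-way mixed, absolute agreement,
    single measures); ``model='consistency'`` gives ICC(C,1).
    """
    a, b = _pairs(a, b)
    if len(a) < 3:
        raise ValueError("ICC needs n >= 3")
    msr, msc, mse, n, k = _mean_squares(a, b)
    if msr < 1e-14 * max(1.0, abs(np.mean(a))) ** 2:
        raise ValueError(
            "degenerate variance decomposition: no between-subject variance "
            "(MSR ~ 0), ICC undefined"
        )
    if model == "consistency":
        return float((msr - mse) / (msr + (k - 1) * mse))
    if model == "absolute":
        return float(
            (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        )
    raise ValueError("model must be 'absolute' or 'consistency'")


def cronbach_alpha(a, b) -> float:
    """Cronbach's alpha with the two raters as items.

    alpha = k/(k-1) * (1 - sum of item variances / variance of sums).
    """
    a, b = _pairs(a, b)
    if len(a) < 3:
        raise ValueError("Cronbach's alpha needs n >= 3")
    k = 2
    item_vars = a.var(ddof=1) + b.var(ddof=1)
    total_var = (a + b).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance: alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray  # per-pair (a+b)/2, for plotting
    diffs: np.ndarray  # per-pair a-b


def bland_altman(a, b) -> BlandAltman:
    """Bland-Altman agreement: differences a-b, mean, SD and LoA.

    Limits of agreement are mean +/- 1.96 sample SD of the differences.
    """
    a, b = _pairs(a, b)
    if len(a) < 2:
        raise ValueError("Bland-Altman needs n >= 2")
    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return BlandAltman(
        mean_diff,
        sd_diff,
        mean_diff - 1.96 * sd_diff,
        mean_diff + 1.96 * sd_diff,
        (a + b) / 2.0,
        d,
    )


@dataclass
class ReliabilityReport:
    """All pairwise statistics for one metric and one rater/method pair."""

    metric: str
    n: int
    cv_a: float
    cv_b: float
    icc: float
    icc_consistency: float
    icc_model: str
    cronbach_alpha: float
    pearson_r: float
    paired_t: float
    paired_t_p: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float

    def to_dict(self) -> dict:
        return asdict(self)


def reliability_report(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    metric: str,
    ff_threshold: float | None = None,
    icc_model: str = "absolute",
) -> ReliabilityReport:
    """Full reliability battery for one metric between two rating tables.

    Tables carry one row per (subject, muscle) with metric columns, as
    produced by the MSB and VBT extractors; rows are aligned on
    (subject, muscle) and one-sided entries dropped.  With ``ff_threshold``
    the analysis is restricted to the fatty-infiltrated stratum where the
    mean of the two raters' fat fractions exceeds the threshold.
    """
    keys = [c for c in ("subject", "muscle") if c in table_a.columns]
    if not keys:
        raise ValueError("tables need 'subject' and/or 'muscle' key columns")
    merged = table_a.merge(table_b, on=keys, suffixes=("_a", "_b"))
    col_a, col_b = f"{metric}_a", f"{metric}_b"
    if col_a not in merged.columns:
        raise ValueError(f"metric '{metric}' not present in both tables")
    merged = merged.dropna(subset=[col_a, col_b])
    if ff_threshold is not None:
        if "ff_a" not in merged.columns:
            raise ValueError("fat-fraction stratification needs an 'ff' column")
        ff_mean = (merged["ff_a"] + merged["ff_b"]) / 2.0
        merged = merged[ff_mean > ff_threshold]
    a = merged[col_a].to_numpy(dtype=float)
    b = merged[col_b].to_numpy(dtype=float)
    if len(a) < 3:
        raise ValueError(
            f"fewer than 3 aligned pairs for metric '{metric}' "
            f"(got {len(a)})"
        )
    t, p = paired_t(a, b)
    ba = bland_altman(a, b)
    return ReliabilityReport(
        metric=metric,
        n=len(a),
        cv_a=cv(a),
        cv_b=cv(b),
        icc=icc(a, b, model=icc_model),
        icc_consistency=icc(a, b, model="consistency"),
        icc_model=icc_model,
        cronbach_alpha=cronbach_alpha(a, b),
        pearson_r=pearson_r(a, b),
        paired_t=t,
        paired_t_p=p,
        mean_diff=ba.mean_diff,
        sd_diff=ba.sd_diff,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
    )
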