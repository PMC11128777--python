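"""Test-retest reliability via the intraclass correlation ICC(2,1).

Two-way random-effects, single-measure, absolute-agreement ICC with
F-distribution confidence limits (Shrout & Fleiss; McGraw & Wong case 2A,1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["ICCResult", "icc_two_way_single_absolute", "icc_table"]


@dataclass
class ICCResult:
    region: str
    icc: float
    ci95: tuple[float, float]
    n_subjects: int
    warnings: list[str] = field(default_factory=list)


def _anova_mean_squares(Y: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares for an n-subject x k-visit matrix:
    rows (subjects), columns (visits), residual error."""
    n, k = Y.shape
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way_single_absolute(
    retest: pd.DataFrame,
    region: str,
    *,
    level: float = 0.95,
) -> ICCResult:
    """ICC(2,1) for one region of a test-retest table.

    Subjects missing either visit for the region are dropped pairwise.
    With mean squares MSR (subjects), MSC (visits), MSE (error), n subjects
    and k = 2 visits::

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1)*MSE + (k/n)*(MSC - MSE))

    The 95% interval uses the Shrout-Fleiss F approximation. Degenerate
    data (zero between-subject variance) returns a value near 0 with a
    warning rather than raising.
    """
    wide = retest.pivot(index="individual_id", columns="visit", values=region)
    if "test" not in wide.columns or "retest" not in wide.columns:
        raise ValidationError(f"region {region!r}: need both test and retest visits")
    wide = wide[["test", "retest"]].dropna()
    n = len(wide)
    if n < 3:
        raise ValidationError(
            f"region {region!r}: need >= 3 subjects with both visits, got {n}")
    Y = wide.to_numpy(dtype=float)
    k = 2
    msr, msc, mse = _anova_mean_squares(Y)
    warnings: list[str] = []
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or np.isclose(msr, 0.0) and np.isclose(mse, 0.0):
        warnings.append("degenerate data: zero between-subject variance")
        return ICCResult(region, 0.0, (0.0, 0.0), n, warnings)
    icc = (msr - mse) / denom
    if mse == 0 and msc == 0:
        # perfect agreement; the F interval collapses
        return ICCResult(region, 1.0, (1.0, 1.0), n, warnings)
    alpha = 1.0 - level
    # Satterthwaite df and F limits (McGraw & Wong case 2A, single measure)
    fj = msc / mse if mse > 0 else np.inf
    if not np.isfinite(fj) or icc >= 1.0:
        return ICCResult(region, float(min(icc, 1.0)), (1.0, 1.0), n, warnings)
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k ** 2 * icc ** 2 * fj ** 2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_upper = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_upper * mse) / (
        f_upper * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_lower * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_lower * msr)
    lower, upper = float(min(lower, icc)), float(max(upper, icc))
    return ICCResult(region, float(icc), (lower, upper), n, warnings)


def icc_table(retest: pd.DataFrame, regions=None, *, level: float = 0.95) -> pd.DataFrame:
    """ICC(2,1) per region as a tidy frame (region, icc, ci_low, ci_high, n)."""
    if regions is None:
        regions = [c for c in retest.columns
                   if c not in ("individual_id", "visit", "rescan_interval_days")]
    rows = []
    for reg in regions:
        res = icc_two_way_single_absolute(retest, reg, level=level)
        rows.append({"region": reg, "icc": res.icc, "ci_low": res.ci95[0],
                     "ci_high": res.ci95[1], "n": res.n_subjects})
    return pd.DataFrame(rows)
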