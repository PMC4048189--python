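"""Shared statistics primitives.

Every comparative test in the pipeline is the two-tailed pooled-variance
(equal-variance) Student's t test; degenerate comparisons with zero
pooled variance are reported rather than raised: p = 1 with a
``zero_variance`` flag when the group means agree (no evidence of a
difference, no spread to judge it by), p = 0 with the flag when the
means differ with literally no within-group spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import InsufficientDataError

__all__ = ["TTestResult", "pooled_ttest", "pooled_ttest_rows", "round_half_up", "bh_adjust"]


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    df: float
    zero_variance: bool


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[~np.isnan(x)]


def pooled_ttest(a, b) -> TTestResult:
    """Two-tailed equal-variance Student's t test on two samples.

    Missing values are dropped; each group needs >= 2 usable values.
    """
    a, b = _clean(a), _clean(b)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"need >=2 values per group, got {len(a)} and {len(b)}"
        )
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        same = a.mean() == b.mean()
        return TTestResult(0.0 if same else np.inf, 1.0 if same else 0.0, df, True)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(p), df, False)


def pooled_ttest_rows(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise pooled-variance t test with NaN-aware counts.

    ``a`` and ``b`` are 2-D arrays (rows x observations).  Returns
    (p_values, zero_variance_flags, valid) where ``valid`` marks rows
    with >= 2 non-missing values in each group; other rows get NaN p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(a, axis=1)
        m2 = np.nanmean(b, axis=1)
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.where(df > 0, df, np.nan)
        zero = valid & (sp2 == 0.0)
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(zero, np.where(m1 == m2, 1.0, 0.0), p)
    p = np.where(valid, p, np.nan)
    return p, zero, valid


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 86.75 -> 86.8 at 1 digit)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values; NaNs pass through."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
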