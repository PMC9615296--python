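"""Nonparametric and parametric statistics for the clinical table.

EDSS change is tested with a paired Wilcoxon signed-rank test (zero
differences dropped, midranks for ties, exact sign-flip enumeration for
small samples); lesion load with a paired t-test.  Summary statistics use
the median-of-halves quartile rule, which matches how ordinal disability
scores are conventionally summarized.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats

from .types import DegenerateDataError, ValidationError

__all__ = [
    "PairedSample",
    "wilcoxon_signed_rank",
    "paired_t",
    "median_iqr",
    "summarize_demographics",
    "WilcoxonResult",
]

EXACT_LIMIT = 15  # exact sign-flip enumeration up to this many nonzero pairs


@dataclass
class PairedSample:
    """Matched pre/post values; pairs with any missing member are excluded
    up front and counted."""

    ids: list[str]
    pre: np.ndarray
    post: np.ndarray
    unit: str = ""
    n_excluded: int = 0

    @classmethod
    def from_columns(cls, ids, pre, post, unit: str = "") -> "PairedSample":
        ids = list(ids)
        pre = np.asarray(pre, dtype=float)
        post = np.asarray(post, dtype=float)
        if not (len(ids) == len(pre) == len(post)):
            raise ValidationError("paired columns must have equal length")
        keep = np.isfinite(pre) & np.isfinite(post)
        return cls(
            ids=[i for i, k in zip(ids, keep) if k],
            pre=pre[keep],
            post=post[keep],
            unit=unit,
            n_excluded=int((~keep).sum()),
        )


@dataclass
class WilcoxonResult:
    w: float           # positive-rank sum of (pre - post)
    n_effective: int   # nonzero differences entering the ranking
    p: float
    method: str        # "exact" | "normal-approximation"


def _signed_midranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ranks = stats.rankdata(np.abs(d), method="average")
    return ranks, d > 0


def wilcoxon_signed_rank(
    pre: np.ndarray, post: np.ndarray
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on d = pre - post.

    Zero differences are discarded; |d| are midranked; W is the sum of
    ranks of positive differences.  The two-tailed p is computed by exact
    enumeration of all sign assignments when the effective sample is small,
    and by the tie-corrected normal approximation otherwise.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValidationError("pre and post must have equal length")
    d = pre - post
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError(
            "all paired differences are zero; no information"
        )
    ranks, positive = _signed_midranks(d)
    w = float(ranks[positive].sum())
    total = float(ranks.sum())  # n(n+1)/2 after midranking
    if n <= EXACT_LIMIT:
        # enumerate all 2^n sign assignments of the midranks
        signs = np.array(list(product((0.0, 1.0), repeat=n)))
        w_null = signs @ ranks
        w_hi = max(w, total - w)
        w_lo = min(w, total - w)
        count = np.sum(w_null >= w_hi) + np.sum(w_null <= w_lo)
        p = min(1.0, float(count) / len(w_null))
        method = "exact"
    else:
        mean = total / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts
        ) / 48.0
        z = (w - mean) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
        method = "normal-approximation"
    return WilcoxonResult(w=w, n_effective=n, p=p, method=method)


def paired_t(pre: np.ndarray, post: np.ndarray) -> tuple[float, int, float]:
    """Two-tailed paired t-test on d = pre - post; returns (t, df, p)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValidationError("pre and post must have equal length")
    keep = np.isfinite(pre) & np.isfinite(post)
    pre, post = pre[keep], post[keep]
    n = pre.size
    if n < 2:
        raise ValidationError("need >= 2 complete pairs")
    d = pre - post
    if np.std(d, ddof=1) == 0:
        raise DegenerateDataError(
            "paired differences have zero variance; t undefined"
        )
    res = stats.ttest_rel(pre, post)
    return float(res.statistic), int(res.df), float(res.pvalue)


def _median_of_halves(values: np.ndarray) -> tuple[float, float]:
    s = np.sort(values)
    n = s.size
    half = n // 2
    lower = s[:half]
    upper = s[half:] if n % 2 == 0 else s[half + 1:]
    return float(np.median(lower)), float(np.median(upper))


def median_iqr(values: np.ndarray) -> tuple[float, float]:
    """Sample median and IQR with quartiles by the median-of-halves rule
    (the overall median is excluded from both halves for odd n)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValidationError("cannot summarize an empty sample")
    med = float(np.median(values))
    if values.size == 1:
        return med, 0.0
    q1, q3 = _median_of_halves(values)
    return med, q3 - q1


def summarize_demographics(table) -> dict:
    """Mean/SD of age (n-1 denominator) and sex tally from a clinical
    table; SD is NaN-flagged for a single row."""
    frame = table.frame if hasattr(table, "frame") else table
    ages = np.asarray(frame["age"], dtype=float)
    out = {
        "n": int(len(frame)),
        "age_mean": float(ages.mean()),
        "age_sd": float(ages.std(ddof=1)) if len(ages) > 1 else float("nan"),
        "sex_counts": frame["sex"].value_counts().to_dict(),
    }
    return out
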