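"""Patient-level follow-up analysis.

Per patient and coherence direction, the set of attributed ROIs induces a
probability distribution over networks — how often each *original* (or
*altered*) network appears among the patient's ROIs.  The arcsine-transformed
probabilities enter a classical two-factor repeated-measures ANOVA (factors
Coherence and Network, subject as random factor).  Prevalence of a network
being the (equally-)most-likely original network across patients is tested
with an exact upper-tail binomial, and a generic binomial power computation
is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import (
    IncompleteDesignError,
    ROI,
    ValidationError,
)

__all__ = [
    "NetworkProbabilityProfile",
    "network_probabilities",
    "arcsine_transform",
    "AnovaResult",
    "rm_anova",
    "most_likely_networks",
    "prevalence_binomial",
    "binomial_power",
]


@dataclass
class NetworkProbabilityProfile:
    """Fraction of a patient's ROIs (one direction) attributed to each
    network; all-zero with ``missing=True`` when the patient has no ROIs."""

    patient_id: str
    direction: str
    basis: str  # "original" | "altered"
    probs: np.ndarray  # (K,)
    missing: bool


def network_probabilities(
    rois: list[ROI],
    basis: str,
    direction: str,
    K: int,
    patient_id: str,
) -> NetworkProbabilityProfile:
    """Count the chosen basis network among the patient's direction-matching
    ROIs and normalize by their total."""
    if basis not in ("original", "altered"):
        raise ValidationError(f"unknown basis {basis!r}")
    counts = np.zeros(K)
    for roi in rois:
        if roi.patient_id != patient_id or roi.direction != direction:
            continue
        idx = (
            roi.original_network if basis == "original"
            else roi.altered_network
        )
        if idx is None:
            raise ValidationError("ROI not attributed")
        counts[idx] += 1
    total = counts.sum()
    if total == 0:
        return NetworkProbabilityProfile(
            patient_id, direction, basis, counts, missing=True
        )
    return NetworkProbabilityProfile(
        patient_id, direction, basis, counts / total, missing=False
    )


def arcsine_transform(p: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing transform for proportions: arcsin(sqrt(p)),
    radians."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) else out


@dataclass
class AnovaResult:
    """Two-factor within-subject ANOVA table (Coherence x Network)."""

    f_network: float
    df_network: tuple[int, int]
    p_network: float
    f_coherence: float
    df_coherence: tuple[int, int]
    p_coherence: float
    f_interaction: float
    df_interaction: tuple[int, int]
    p_interaction: float
    undefined: bool = False  # zero error variance everywhere


def rm_anova(data: np.ndarray) -> AnovaResult:
    """Classical two-factor repeated-measures ANOVA on an
    ``(n_subjects, 2, K)`` array (factor A = Coherence with 2 levels,
    factor B = Network with K levels; subject as random factor).

    Each effect is tested against its own subject-by-factor interaction
    error term; no sphericity correction is applied.  A design with any
    non-finite cell raises (no imputation); an everywhere-constant response
    yields an ``undefined`` flag rather than F values.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3 or y.shape[1] != 2:
        raise IncompleteDesignError(
            "need a complete (n_subjects, 2, K) array"
        )
    if not np.isfinite(y).all():
        raise IncompleteDesignError(
            "design incomplete: non-finite cells present (no imputation)"
        )
    n, a, b = y.shape
    if n < 2 or b < 2:
        raise IncompleteDesignError("need n >= 2 subjects and K >= 2 levels")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))          # subject means, (n,)
    m_a = y.mean(axis=(0, 2))          # coherence means, (a,)
    m_b = y.mean(axis=(0, 1))          # network means, (b,)
    m_ab = y.mean(axis=0)              # (a, b)
    m_sa = y.mean(axis=2)              # (n, a)
    m_sb = y.mean(axis=1)              # (n, b)

    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * (
        (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2
    ).sum()
    ss_sa = b * (
        (m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2
    ).sum()
    ss_sb = a * (
        (m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2
    ).sum()
    ss_sab = (
        (
            y
            - m_sa[:, :, None]
            - m_sb[:, None, :]
            - m_ab[None, :, :]
            + m_s[:, None, None]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - grand
        )
        ** 2
    ).sum()

    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_sa, df_sb, df_sab = (
        (n - 1) * df_a,
        (n - 1) * df_b,
        (n - 1) * df_ab,
    )

    def f_and_p(ss_eff, df_eff, ss_err, df_err):
        if ss_err == 0:
            return np.nan, np.nan
        f = (ss_eff / df_eff) / (ss_err / df_err)
        return f, float(stats.f.sf(f, df_eff, df_err))

    f_a, p_a = f_and_p(ss_a, df_a, ss_sa, df_sa)
    f_b, p_b = f_and_p(ss_b, df_b, ss_sb, df_sb)
    f_ab, p_ab = f_and_p(ss_ab, df_ab, ss_sab, df_sab)
    undefined = ss_sa == 0 or ss_sb == 0 or ss_sab == 0
    return AnovaResult(
        f_network=f_b, df_network=(df_b, df_sb), p_network=p_b,
        f_coherence=f_a, df_coherence=(df_a, df_sa), p_coherence=p_a,
        f_interaction=f_ab, df_interaction=(df_ab, df_sab),
        p_interaction=p_ab, undefined=bool(undefined),
    )


def most_likely_networks(profile: NetworkProbabilityProfile) -> set[int]:
    """Indices of the (equally-)most-likely networks of a profile; a tie
    including a target network counts as an occurrence of that network.
    Empty for missing profiles."""
    if profile.missing:
        return set()
    top = profile.probs.max()
    return {int(i) for i in np.flatnonzero(profile.probs == top)}


def prevalence_binomial(k_patients: int, n_patients: int, p0: float) -> float:
    """Exact upper-tail binomial P(X >= k) with X ~ Binomial(n, p0)."""
    if not 0 <= k_patients <= n_patients:
        raise ValidationError("k must lie in [0, n]")
    if not 0 < p0 < 1:
        raise ValidationError("p0 must lie in (0, 1)")
    return float(stats.binom.sf(k_patients - 1, n_patients, p0))


def binomial_power(
    n: int, p0: float, alpha: float, p1: float
) -> tuple[float, int | None]:
    """Power of the exact upper-tail binomial test.

    Finds the smallest critical count ``k*`` with
    ``P(X >= k* | p0) <= alpha`` and returns
    ``(P(X >= k* | p1), k*)``; ``(0.0, None)`` when no attainable critical
    count exists.
    """
    for p, name in ((p0, "p0"), (p1, "p1"), (alpha, "alpha")):
        if not 0 < p < 1:
            raise ValidationError(f"{name} must lie in (0, 1)")
    counts = np.arange(n + 2)  # k = n + 1 has upper tail 0
    tails = stats.binom.sf(counts - 1, n, p0)
    ok = np.flatnonzero(tails <= alpha)
    if ok.size == 0:  # pragma: no cover - sf(n+1 - 1) = P(X >= n+1) = 0
        return 0.0, None
    k_star = int(ok[0])
    if k_star > n:
        return 0.0, None
    return float(stats.binom.sf(k_star - 1, n, p1)), k_star
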