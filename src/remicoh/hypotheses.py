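"""Group-level hypothesis tests on the adjacency frequency matrices.

Four patterns are tested on each direction's K x K frequency matrix:

* one-with-self  — a single diagonal cell beyond the Bonferroni threshold;
* one-with-other — a single off-diagonal cell beyond the same threshold;
* one-with-many  — a row of cells above the per-cell threshold (z > 1.96);
* many-with-one  — a column of cells above the per-cell threshold.

Per-cell evidence comes from an upper-tail binomial test of the observed
patient count against the matrix-wide expected count, converted to a
standard-normal z for thresholding.  Row/column effects are assessed against
Monte Carlo null distributions of the maximum row and column counts obtained
by shuffling each patient's binary matrix (preserving that patient's number
of ones) and re-running the whole per-cell procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import (
    DegenerateDataError,
    GroupFrequency,
    PatientAdjacency,
    ValidationError,
)

__all__ = [
    "expected_count",
    "cell_binomial",
    "p_to_z",
    "CellTestMatrix",
    "cell_tests",
    "single_cell_effects",
    "row_col_counts",
    "shuffle_null",
    "effect_pvalues",
    "run_direction_tests",
    "EffectTestResult",
]

Z_CELL = 1.96          # per-cell threshold, p < 0.025 upper tail
Z_BONFERRONI = 3.6623  # p < 0.025 / 200 (two matrices of 100 cells)


def expected_count(freq: GroupFrequency) -> float:
    """Mean patient count per cell: sum of all K^2 frequencies over K^2."""
    m = freq.matrix
    if m.shape[0] != m.shape[1]:
        raise ValidationError("frequency matrix must be square")
    return float(m.sum()) / m.size


def cell_binomial(
    observed: int | np.ndarray, n_patients: int, expected: float
) -> float | np.ndarray:
    """Upper-tail binomial probability P(X >= observed) with
    X ~ Binomial(n_patients, expected / n_patients)."""
    if expected < 0:
        raise ValidationError("expected count must be >= 0")
    if expected > n_patients:
        raise ValidationError(
            f"expected count {expected} exceeds n_patients {n_patients}"
        )
    obs = np.asarray(observed)
    if np.any(obs < 0) or np.any(obs > n_patients):
        raise ValidationError("observed count outside [0, n_patients]")
    p0 = expected / n_patients
    p = stats.binom.sf(obs - 1, n_patients, p0)
    return float(p) if np.isscalar(observed) else p


def p_to_z(p: float | np.ndarray) -> float | np.ndarray:
    """Upper-tail standard-normal quantile: z = Phi^-1(1 - p)."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValidationError("p must lie in (0, 1]")
    z = stats.norm.isf(arr)
    return float(z) if np.isscalar(p) else z


@dataclass
class CellTestMatrix:
    """Per-cell binomial p-values and their z conversions for one
    direction's frequency matrix."""

    direction: str
    expected: float
    p0: float
    p_matrix: np.ndarray  # (K, K)
    z_matrix: np.ndarray  # (K, K)


def cell_tests(freq: GroupFrequency) -> CellTestMatrix:
    """Binomial test of every cell against the matrix-wide expected count,
    with z conversion."""
    exp = expected_count(freq)
    p = cell_binomial(freq.matrix, freq.n_patients, exp)
    return CellTestMatrix(
        direction=freq.direction,
        expected=exp,
        p0=exp / freq.n_patients,
        p_matrix=np.asarray(p),
        z_matrix=np.asarray(p_to_z(p)),
    )


def single_cell_effects(
    z_matrix: np.ndarray,
    bonferroni_threshold: float = Z_BONFERRONI,
    significant_rows: set[int] | None = None,
    significant_cols: set[int] | None = None,
) -> list[dict]:
    """Lone cells beyond the Bonferroni threshold (strict inequality).

    Diagonal hits are labelled ``one-with-self``, off-diagonal
    ``one-with-other``.  Cells lying inside an already-significant row or
    column are still reported but flagged ``subsumed``.
    """
    # p = 1 cells convert to z = -inf, which is legitimately subthreshold;
    # only NaN indicates a broken matrix
    if np.isnan(z_matrix).any():
        raise ValidationError("z matrix contains NaN")
    significant_rows = significant_rows or set()
    significant_cols = significant_cols or set()
    hits = []
    for i, j in zip(*np.nonzero(z_matrix > bonferroni_threshold)):
        hits.append(
            {
                "altered": int(i),
                "original": int(j),
                "z": float(z_matrix[i, j]),
                "kind": "one-with-self" if i == j else "one-with-other",
                "subsumed": int(i) in significant_rows
                or int(j) in significant_cols,
            }
        )
    return hits


def row_col_counts(
    z_matrix: np.ndarray, threshold: float = Z_CELL
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row and per-column counts of cells with z strictly above the
    threshold."""
    sup = z_matrix > threshold
    return sup.sum(axis=1), sup.sum(axis=0)


def _critical_count(n_patients: int, p0: float, threshold: float) -> int:
    """Smallest observed count whose upper-tail binomial p converts to a z
    strictly above ``threshold``; n_patients + 1 if unattainable."""
    counts = np.arange(n_patients + 1)
    p = stats.binom.sf(counts - 1, n_patients, p0)
    ok = np.flatnonzero(stats.norm.isf(np.clip(p, 1e-300, 1.0)) > threshold)
    return int(ok[0]) if ok.size else n_patients + 1


def shuffle_null(
    patient_adjacencies: list[PatientAdjacency],
    n_reps: int = 100_000,
    seed: int = 0,
    threshold: float = Z_CELL,
    chunk: int = 2_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte Carlo null of the maximum row and column counts.

    Each repetition independently permutes the K^2 entries of every
    patient's binary matrix (preserving that patient's number of ones),
    rebuilds the group frequency matrix, recomputes the expected count and
    the per-cell binomial z, thresholds at ``threshold``, and stores the
    maximum row count and maximum column count.

    Because every patient's total is preserved, the recomputed expected
    count is identical in every repetition, so the per-cell threshold
    reduces to a critical patient count; the procedure exploits this for
    speed without changing the result.
    """
    if not patient_adjacencies:
        raise ValidationError("need at least one patient matrix")
    K = patient_adjacencies[0].matrix.shape[0]
    flats = np.stack([p.matrix.reshape(-1) for p in patient_adjacencies])
    n_pat, ncell = flats.shape
    if ncell != K * K:
        raise ValidationError("patient matrices must be K x K")
    total = int(flats.sum())
    expected = total / ncell
    k_star = _critical_count(n_pat, expected / n_pat, threshold)
    rng = np.random.default_rng(seed)
    max_rows = np.empty(n_reps, dtype=int)
    max_cols = np.empty(n_reps, dtype=int)
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        # one independent uniform permutation of the K^2 cells per
        # (rep, patient): rank random keys
        keys = rng.random((m, n_pat, ncell))
        perm = np.argsort(keys, axis=2)
        shuffled = np.take_along_axis(
            np.broadcast_to(flats, (m, n_pat, ncell)), perm, axis=2
        )
        freq = shuffled.sum(axis=1)  # (m, ncell)
        sup = (freq >= k_star).reshape(m, K, K)
        max_rows[done:done + m] = sup.sum(axis=2).max(axis=1)
        max_cols[done:done + m] = sup.sum(axis=1).max(axis=1)
        done += m
    return max_rows, max_cols


def effect_pvalues(
    observed_counts: np.ndarray,
    null_max: np.ndarray,
    convention: str = "add-one",
) -> np.ndarray:
    """FWER-corrected p-value per network for a row- or column-effect:
    the null exceedance fraction of the observed count (ties count as
    extreme).  ``add-one`` uses (c + 1)/(N + 1); ``literal`` uses c/N."""
    if convention not in ("add-one", "literal"):
        raise ValidationError(f"unknown p-value convention {convention!r}")
    null_max = np.asarray(null_max)
    if null_max.size == 0:
        raise DegenerateDataError("empty null distribution")
    obs = np.asarray(observed_counts)[..., None]
    c = (null_max[None, :] >= obs).sum(axis=-1)
    if convention == "add-one":
        return (c + 1) / (null_max.size + 1)
    return c / null_max.size


@dataclass
class EffectTestResult:
    """Full row/column hypothesis-test output for one direction."""

    direction: str
    cells: CellTestMatrix
    row_counts: np.ndarray
    col_counts: np.ndarray
    null_max_row: np.ndarray
    null_max_col: np.ndarray
    p_fwer_row: np.ndarray
    p_fwer_col: np.ndarray
    single_cells: list[dict] = field(default_factory=list)


def run_direction_tests(
    patient_adjacencies: list[PatientAdjacency],
    n_reps: int = 100_000,
    seed: int = 0,
    alpha_fwer: float = 0.05,
    convention: str = "add-one",
) -> EffectTestResult:
    """Run the complete per-direction procedure: cell tests, row/column
    counts, shuffle null, FWER p-values, and single-cell screening."""
    freq = _group_from(patient_adjacencies)
    cells = cell_tests(freq)
    rows, cols = row_col_counts(cells.z_matrix)
    null_r, null_c = shuffle_null(patient_adjacencies, n_reps=n_reps,
                                  seed=seed)
    p_r = effect_pvalues(rows, null_r, convention=convention)
    p_c = effect_pvalues(cols, null_c, convention=convention)
    sig_rows = {int(i) for i in np.flatnonzero(p_r < alpha_fwer)}
    sig_cols = {int(j) for j in np.flatnonzero(p_c < alpha_fwer)}
    singles = single_cell_effects(
        cells.z_matrix, significant_rows=sig_rows, significant_cols=sig_cols
    )
    return EffectTestResult(
        direction=freq.direction,
        cells=cells,
        row_counts=rows,
        col_counts=cols,
        null_max_row=null_r,
        null_max_col=null_c,
        p_fwer_row=p_r,
        p_fwer_col=p_c,
        single_cells=singles,
    )


def _group_from(pats: list[PatientAdjacency]) -> GroupFrequency:
    from .adjacency import group_frequency

    return group_frequency(pats)
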