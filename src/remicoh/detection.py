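"""Max/min-statistic permutation FWER detection of longitudinal coherence
changes.

For each network, a null distribution of extreme z-scores is built by
repeatedly drawing a pseudo-patient group (the size of the patient sample)
from the pooled subjects, z-scoring each selected difference map against the
remaining subjects, and storing every selected map's maximum and minimum z
over evaluable voxels.  A patient map's voxelwise empirical p-values against
these extreme-value nulls are family-wise-error corrected by construction;
thresholding at ``alpha`` per tail (default 0.025, i.e. 0.05 two-tailed) and
extracting connected components yields ROIs.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import (
    DegenerateDataError,
    DifferenceMapSet,
    NullDistributions,
    ROI,
    ValidationError,
    ZMapSet,
)

__all__ = [
    "build_null",
    "empirical_p",
    "threshold_and_cluster",
]


def build_null(
    all_diffs: list[DifferenceMapSet],
    n_select: int = 18,
    n_perm: int = 10_000,
    seed: int = 0,
    pooling: str = "per-map",
) -> NullDistributions:
    """Permutation null of per-map extreme z-scores, per network.

    Each permutation draws ``n_select`` subjects without replacement from the
    pooled set, z-scores each selected difference map voxelwise against the
    remaining subjects (which may contain patients), and stores each selected
    map's max and min z over unmasked voxels.  With ``per-map`` pooling all
    ``n_select`` extrema of every permutation enter the null
    (N = n_select * n_perm); ``per-permutation`` keeps only the single most
    extreme value per permutation (sensitivity analysis).
    """
    if pooling not in ("per-map", "per-permutation"):
        raise ValidationError(f"unknown pooling {pooling!r}")
    stack = np.stack([d.diff for d in all_diffs])  # (n, K, V)
    n_total, K, V = stack.shape
    if n_select >= n_total:
        raise ValidationError(
            f"n_select={n_select} must be < total subjects ({n_total})"
        )
    rng = np.random.default_rng(seed)
    maxima = np.empty((n_perm, n_select, K))
    minima = np.empty((n_perm, n_select, K))
    any_valid = False
    for i in range(n_perm):
        sel = rng.choice(n_total, size=n_select, replace=False)
        rest = np.setdiff1d(np.arange(n_total), sel, assume_unique=True)
        ref = stack[rest]
        mean = ref.mean(0)
        sd = ref.std(0, ddof=1)
        mask = sd > 0  # (K, V)
        if mask.any():
            any_valid = True
        z = np.where(mask, (stack[sel] - mean) / np.where(mask, sd, 1.0),
                     np.nan)
        with np.errstate(invalid="ignore"):
            maxima[i] = np.nanmax(np.where(mask, z, -np.inf), axis=2)
            minima[i] = np.nanmin(np.where(mask, z, np.inf), axis=2)
    if not any_valid:
        raise DegenerateDataError(
            "all voxels masked in every permutation (zero reference SD "
            "everywhere); the null is empty"
        )
    # fully-masked maps in an otherwise valid null would appear as +/-inf
    if not np.isfinite(maxima).all() or not np.isfinite(minima).all():
        raise DegenerateDataError(
            "some permutations produced fully masked maps; null undefined"
        )
    if pooling == "per-map":
        mx = maxima.reshape(-1, K).T  # (K, n_perm * n_select)
        mn = minima.reshape(-1, K).T
    else:
        mx = maxima.max(1).T  # (K, n_perm)
        mn = minima.min(1).T
    return NullDistributions(
        maxima=np.sort(mx, axis=1),
        minima=np.sort(mn, axis=1),
        n_perm=n_perm,
        pooling=pooling,  # type: ignore[arg-type]
    )


def empirical_p(
    zmap: ZMapSet,
    null: NullDistributions,
    convention: str = "add-one",
) -> tuple[np.ndarray, np.ndarray]:
    """FWER-corrected empirical p-value maps from the extreme-value nulls.

    ``p_upper(v) = (#{maxima >= z(v)} + 1) / (N + 1)`` and
    ``p_lower(v) = (#{minima <= z(v)} + 1) / (N + 1)`` under the default
    ``add-one`` convention (never zero); ``convention="literal"`` restores
    the plain count/N ratio.  Ties count as extreme.  Masked voxels are NaN.
    """
    if convention not in ("add-one", "literal"):
        raise ValidationError(f"unknown p-value convention {convention!r}")
    K, V = zmap.z.shape
    if null.maxima.shape[0] != K:
        raise ValidationError("null and z-map network counts differ")
    N = null.maxima.shape[1]
    if N == 0:
        raise DegenerateDataError("empty null distribution")
    p_upper = np.full((K, V), np.nan)
    p_lower = np.full((K, V), np.nan)
    for k in range(K):
        valid = zmap.mask[k]
        z = zmap.z[k, valid]
        # maxima sorted ascending: count >= z
        c_up = N - np.searchsorted(null.maxima[k], z, side="left")
        c_lo = np.searchsorted(null.minima[k], z, side="right")
        if convention == "add-one":
            p_upper[k, valid] = (c_up + 1) / (N + 1)
            p_lower[k, valid] = (c_lo + 1) / (N + 1)
        else:
            p_upper[k, valid] = c_up / N
            p_lower[k, valid] = c_lo / N
    return p_upper, p_lower


def _connectivity_structure(grid_shape: tuple[int, ...]) -> np.ndarray:
    """Face connectivity (6-connectivity in 3D, 4-connectivity in 2D)."""
    return ndimage.generate_binary_structure(len(grid_shape), 1)


def threshold_and_cluster(
    p_upper: np.ndarray,
    p_lower: np.ndarray,
    zmap: ZMapSet,
    grid_shape: tuple[int, ...],
    alpha: float = 0.025,
    connectivity: np.ndarray | None = None,
    min_cluster_size: int = 1,
) -> list[ROI]:
    """Two-tailed thresholding and connected-component ROI extraction.

    Increase-ROIs are components of ``{v: p_upper(v) < alpha and z(v) > 0}``;
    decrease-ROIs use ``p_lower`` and ``z < 0``.  Components smaller than
    ``min_cluster_size`` are dropped.  Each ROI records the altered network
    it came from and the minimum FWER p in the cluster.
    """
    if not 0 < alpha < 0.5:
        raise ValidationError("alpha must be in (0, 0.5)")
    K, V = zmap.z.shape
    if p_upper.shape != (K, V) or p_lower.shape != (K, V):
        raise ValidationError("p-maps are not aligned with the z-maps")
    if int(np.prod(grid_shape)) != V:
        raise ValidationError("grid_shape does not match the maps")
    structure = (
        connectivity
        if connectivity is not None
        else _connectivity_structure(grid_shape)
    )
    rois: list[ROI] = []
    with np.errstate(invalid="ignore"):
        sup_up = (p_upper < alpha) & (zmap.z > 0) & zmap.mask
        sup_lo = (p_lower < alpha) & (zmap.z < 0) & zmap.mask
    for k in range(K):
        for direction, sup, pmap in (
            ("increase", sup_up[k], p_upper[k]),
            ("decrease", sup_lo[k], p_lower[k]),
        ):
            if not sup.any():
                continue
            labels, n_lab = ndimage.label(
                sup.reshape(grid_shape), structure=structure
            )
            labels = labels.reshape(V)
            for lab in range(1, n_lab + 1):
                vox = np.flatnonzero(labels == lab)
                if vox.size < min_cluster_size:
                    continue
                rois.append(
                    ROI(
                        patient_id=zmap.patient_id,
                        altered_network=k,
                        direction=direction,  # type: ignore[arg-type]
                        voxel_ids=tuple(int(v) for v in vox),
                        peak_p=float(np.min(pmap[vox])),
                    )
                )
    return rois
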