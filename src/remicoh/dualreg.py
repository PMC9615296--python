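"""Dual regression of template networks into subject data, PE-map smoothing,
longitudinal difference maps, and control-referenced z-maps.

Stage 1 (spatial regression): each time frame is regressed, across voxels, on
the K template maps (plus intercept), yielding K subject-specific network
time courses.  Stage 2 (temporal regression): each voxel's time series is
regressed on those time courses (plus intercept), yielding K subject-specific
spatial maps of parameter estimates (PE).

Both volumes and template maps are demeaned across voxels before stage 1, and
stage-1 time courses are scaled to unit variance before stage 2 (both
configurable, defaults on), mirroring common dual-regression practice.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, ndimage

from .types import (
    DifferenceMapSet,
    NetworkTemplateSet,
    PEMapSet,
    ScanSession,
    SingularDesignError,
    ValidationError,
    ZMapSet,
)

__all__ = [
    "spatial_regression",
    "temporal_regression",
    "dual_regress",
    "smooth_pe_maps",
    "difference_maps",
    "zscore_vs_controls",
]

_RANK_RTOL = 1e-10


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    """Raise with the offending regressors when the design is column-rank
    deficient."""
    rank = np.linalg.matrix_rank(
        design, tol=_RANK_RTOL * np.linalg.norm(design, 2)
    )
    if rank < design.shape[1]:
        # name the (near-)collinear columns via QR pivoting
        _, r, piv = linalg.qr(design, pivoting=True, mode="economic")
        diag = np.abs(np.diag(r))
        bad = sorted(piv[rank:].tolist())
        labels = [names[i] if i < len(names) else "intercept" for i in bad]
        raise SingularDesignError(
            f"rank-deficient design: collinear regressors {labels} "
            f"(rank {rank} < {design.shape[1]}, min |R_ii|={diag.min():.2e})"
        )


def spatial_regression(
    templates: NetworkTemplateSet,
    scan: ScanSession,
    demean: bool = True,
    variance_normalize: bool = True,
) -> np.ndarray:
    """Stage 1: OLS of each volume (time frame) on the K template maps.

    Returns a (K, T) matrix of network time courses.  With
    ``variance_normalize`` each nonzero course is scaled to unit variance
    before it is used as a stage-2 predictor.
    """
    M = templates.maps  # (K, V)
    data = scan.data  # (V, T)
    if data.shape[0] != M.shape[1]:
        raise ValidationError(
            f"scan has V={data.shape[0]} voxels, templates have "
            f"V={M.shape[1]}"
        )
    X = M.T.copy()
    Y = data
    if demean:
        X = X - X.mean(0, keepdims=True)
        Y = Y - Y.mean(0, keepdims=True)
    design = np.column_stack([X, np.ones(X.shape[0])])
    _check_rank(design, list(templates.names))
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    courses = coef[:-1, :]  # drop intercept
    if variance_normalize:
        sd = courses.std(axis=1, ddof=1)
        nz = sd > 0
        courses = courses.copy()
        courses[nz] /= sd[nz, None]
    return courses


def temporal_regression(
    time_courses: np.ndarray, scan: ScanSession
) -> PEMapSet:
    """Stage 2: per-voxel OLS of the time series on the K network time
    courses (plus intercept); PE = coefficient per network."""
    C = np.asarray(time_courses, dtype=float)  # (K, T)
    data = scan.data  # (V, T)
    if data.shape[1] != C.shape[1]:
        raise ValidationError(
            f"scan has T={data.shape[1]}, time courses have T={C.shape[1]}"
        )
    design = np.column_stack([C.T, np.ones(C.shape[1])])  # (T, K+1)
    _check_rank(design, [f"course{k}" for k in range(C.shape[0])])
    coef, *_ = np.linalg.lstsq(design, data.T, rcond=None)
    return PEMapSet(
        subject_id=scan.subject_id, timepoint=scan.timepoint, pe=coef[:-1, :]
    )


def dual_regress(
    templates: NetworkTemplateSet,
    scan: ScanSession,
    demean: bool = True,
    variance_normalize: bool = True,
) -> PEMapSet:
    """Full two-stage dual regression for one session."""
    courses = spatial_regression(
        templates, scan, demean=demean, variance_normalize=variance_normalize
    )
    return temporal_regression(courses, scan)


def smooth_pe_maps(
    pemaps: PEMapSet,
    fwhm: float,
    grid_shape: tuple[int, ...],
    voxel_size: float = 1.0,
) -> PEMapSet:
    """Gaussian-smooth each network map on its 3D grid.

    ``fwhm`` is in physical units; ``sigma = fwhm / (2 sqrt(2 ln 2)) /
    voxel_size`` voxels.  Symmetric-reflection boundaries keep the operator
    doubly stochastic, so constants and the spatial mean are preserved.
    ``fwhm = 0`` is the identity.
    """
    if fwhm < 0:
        raise ValidationError("fwhm must be >= 0")
    if voxel_size is None or voxel_size <= 0:
        raise ValidationError(
            "voxel size unknown or invalid; cannot convert FWHM to voxels"
        )
    if fwhm == 0:
        return PEMapSet(pemaps.subject_id, pemaps.timepoint, pemaps.pe.copy())
    K = pemaps.pe.shape[0]
    V = pemaps.pe.shape[1]
    if int(np.prod(grid_shape)) != V:
        raise ValidationError("grid_shape does not match the PE maps")
    sigma_vox = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size
    vols = pemaps.pe.reshape((K, *grid_shape))
    axes = tuple(range(1, vols.ndim))
    out = ndimage.gaussian_filter(vols, sigma=sigma_vox, axes=axes,
                                  mode="reflect")
    return PEMapSet(pemaps.subject_id, pemaps.timepoint, out.reshape(K, V))


def difference_maps(pe_post: PEMapSet, pe_pre: PEMapSet,
                    group: str) -> DifferenceMapSet:
    """Elementwise post-minus-pre PE difference maps for one subject."""
    if pe_post.subject_id != pe_pre.subject_id:
        raise ValidationError(
            f"cannot pair sessions of different subjects "
            f"({pe_post.subject_id!r} vs {pe_pre.subject_id!r})"
        )
    if pe_post.pe.shape != pe_pre.pe.shape:
        raise ValidationError("PE map dimensions differ between sessions")
    return DifferenceMapSet(
        subject_id=pe_post.subject_id,
        group=group,  # type: ignore[arg-type]
        diff=pe_post.pe - pe_pre.pe,
    )


def zscore_vs_controls(
    patient_diff: DifferenceMapSet,
    control_diffs: list[DifferenceMapSet] | np.ndarray,
) -> ZMapSet:
    """z-score a patient's difference maps voxelwise against the control
    difference distribution (mean, SD with n-1 denominator).

    Voxels with zero control SD are masked (NaN) and stay excluded from all
    downstream extrema and counts.
    """
    if isinstance(control_diffs, np.ndarray):
        stack = control_diffs
    else:
        stack = np.stack([c.diff for c in control_diffs])  # (n, K, V)
    if stack.shape[0] < 3:
        raise ValidationError(
            f"need >= 3 control difference maps, got {stack.shape[0]}"
        )
    mean = stack.mean(0)
    sd = stack.std(0, ddof=1)
    mask = sd > 0
    z = np.full_like(mean, np.nan)
    np.divide(patient_diff.diff - mean, sd, out=z, where=mask)
    return ZMapSet(patient_id=patient_diff.subject_id, z=z, mask=mask)
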