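"""ROI-to-network attribution and altered-by-original adjacency matrices.

Each detected ROI is attributed to the *original* network whose template
values dominate over the ROI's voxels (mean statistic by default, peak
optional; templates unthresholded by default).  Per patient and per
coherence direction, a K x K binary matrix marks which (altered, original)
network pairs appear at least once; summing the binaries across patients
yields the group-level frequency matrix.  These matrices need not be
symmetric and are never symmetrized.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (
    GroupFrequency,
    NetworkTemplateSet,
    PatientAdjacency,
    ROI,
    ValidationError,
)

__all__ = ["attribute_roi", "attribute_rois", "patient_adjacency",
           "group_frequency", "plot_group_frequency"]

logger = logging.getLogger(__name__)


def attribute_roi(
    roi: ROI,
    templates: NetworkTemplateSet,
    statistic: str = "mean",
    z_threshold: float | None = None,
) -> int:
    """Original-network index for an ROI: argmax over networks of the mean
    (or peak) template z across the ROI's voxels.

    ``z_threshold`` optionally zeroes template values below the threshold
    before aggregating.  Ties break toward the lower network index, with a
    logged warning.
    """
    vox = np.asarray(roi.voxel_ids, dtype=int)
    if vox.size == 0:
        raise ValidationError("cannot attribute an empty ROI")
    if vox.min() < 0 or vox.max() >= templates.n_voxels:
        raise IndexError("ROI voxels outside the template grid")
    values = templates.maps[:, vox]
    if z_threshold is not None:
        values = np.where(values >= z_threshold, values, 0.0)
    if statistic == "mean":
        scores = values.mean(axis=1)
    elif statistic == "peak":
        scores = values.max(axis=1)
    else:
        raise ValidationError(f"unknown attribution statistic {statistic!r}")
    winner = int(np.argmax(scores))
    if np.sum(scores == scores[winner]) > 1:
        logger.warning(
            "attribution tie for ROI of patient %s (altered network %d); "
            "breaking toward network %d",
            roi.patient_id, roi.altered_network, winner,
        )
    return winner


def attribute_rois(
    rois: list[ROI],
    templates: NetworkTemplateSet,
    statistic: str = "mean",
    z_threshold: float | None = None,
) -> list[ROI]:
    """Attribute every ROI in place and return the list."""
    for roi in rois:
        roi.original_network = attribute_roi(
            roi, templates, statistic=statistic, z_threshold=z_threshold
        )
    return rois


def patient_adjacency(
    rois: list[ROI], K: int, patient_id: str
) -> dict[str, PatientAdjacency]:
    """Binary altered-by-original incidence matrices, one per direction.

    Multiple ROIs for the same (altered, original) pair still contribute a
    single 1; diagonal entries encode one-with-self changes.
    """
    matrices = {
        d: np.zeros((K, K), dtype=int) for d in ("increase", "decrease")
    }
    for roi in rois:
        if roi.patient_id != patient_id:
            continue
        if roi.original_network is None:
            raise ValidationError(
                f"ROI of patient {patient_id} has not been attributed"
            )
        matrices[roi.direction][roi.altered_network, roi.original_network] = 1
    return {
        d: PatientAdjacency(patient_id=patient_id, direction=d, matrix=m)
        for d, m in matrices.items()
    }


def group_frequency(
    patient_adjacencies: list[PatientAdjacency],
) -> GroupFrequency:
    """Elementwise sum of same-direction patient binaries."""
    if not patient_adjacencies:
        raise ValidationError("no patient adjacency matrices given")
    directions = {p.direction for p in patient_adjacencies}
    if len(directions) != 1:
        raise ValidationError(
            f"cannot mix directions in one group matrix: {sorted(directions)}"
        )
    shapes = {p.matrix.shape for p in patient_adjacencies}
    if len(shapes) != 1:
        raise ValidationError("patient matrices have differing K")
    total = np.sum([p.matrix for p in patient_adjacencies], axis=0)
    return GroupFrequency(
        direction=patient_adjacencies[0].direction,
        matrix=total.astype(int),
        n_patients=len(patient_adjacencies),
    )


def plot_group_frequency(freq: GroupFrequency, names, path) -> None:
    """Heatmap of the altered-by-original frequency matrix (requires
    matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    K = freq.matrix.shape[0]
    fig, ax = plt.subplots(figsize=(1 + 0.5 * K, 1 + 0.5 * K))
    im = ax.imshow(freq.matrix, cmap="viridis", vmin=0)
    ax.set_xticks(range(K), names, rotation=90)
    ax.set_yticks(range(K), names)
    ax.set_xlabel("original network")
    ax.set_ylabel("altered network")
    ax.set_title(f"coherence {freq.direction}s (n={freq.n_patients})")
    fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
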