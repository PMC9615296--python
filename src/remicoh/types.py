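"""Domain containers shared across the pipeline stages.

All voxel data live in flat ``(K, V)`` or ``(V, T)`` arrays; ``grid_shape``
carries the 3D geometry needed for smoothing and cluster extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

Direction = Literal["increase", "decrease"]
Timepoint = Literal["pre", "post"]
Group = Literal["patient", "control"]

#: The ten canonical resting-state network labels used throughout.
DEFAULT_NETWORK_LABELS = (
    "MVA", "Occ", "LVA", "Crb", "SMN", "Aud", "ECN", "rFP", "lFP", "DMN",
)


class RemicohError(Exception):
    """Base class for all package errors."""


class ValidationError(RemicohError):
    """Invalid inputs (non-finite values, mismatched shapes, bad parameters)."""


class SingularDesignError(RemicohError):
    """Rank-deficient regression design."""


class DegenerateDataError(RemicohError):
    """Inputs carry no usable information (all-zero variance, empty null)."""


class IncompleteDesignError(RemicohError):
    """A repeated-measures design with missing cells."""


@dataclass
class NetworkTemplateSet:
    """K spatial network maps (z-score units) over a common voxel grid."""

    names: Sequence[str]
    maps: np.ndarray  # (K, V)
    grid_shape: tuple[int, ...]

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        K, V = self.maps.shape
        if K < 2:
            raise ValidationError("need at least two network templates")
        if len(self.names) != K or len(set(self.names)) != K:
            raise ValidationError("template names must be unique and match K")
        if int(np.prod(self.grid_shape)) != V:
            raise ValidationError(
                f"grid_shape {self.grid_shape} does not match V={V}"
            )
        if not np.isfinite(self.maps).all():
            raise ValidationError("template maps must be finite")
        if np.any(np.all(self.maps == 0, axis=1)):
            raise ValidationError("no template map may be all-zero")

    @property
    def n_networks(self) -> int:
        return self.maps.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.maps.shape[1]

    def territories(self) -> np.ndarray:
        """Per-voxel index of the dominating (argmax) network."""
        return np.argmax(self.maps, axis=0)


@dataclass
class ScanSession:
    """One subject/timepoint voxel-by-time data matrix."""

    subject_id: str
    group: Group
    timepoint: Timepoint
    data: np.ndarray  # (V, T)
    sampling_interval: float = 1.0
    #: ground-truth network time courses when synthetic (K, T), else None
    latent_courses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("session data must be a (V, T) matrix")
        if not np.isfinite(self.data).all():
            raise ValidationError("session data must be finite")


@dataclass(frozen=True)
class EffectEntry:
    """One injected longitudinal coherence change (ground truth)."""

    patient_id: str
    altered_network: int
    original_network: int
    direction: Direction
    delta: float
    roi_voxels: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.direction == "increase" and self.delta <= 0:
            raise ValidationError("increase effects need delta > 0")
        if self.direction == "decrease" and self.delta >= 0:
            raise ValidationError("decrease effects need delta < 0")


@dataclass
class EffectSpec:
    """Ground-truth list of injected effects for recovery scoring."""

    entries: list[EffectEntry] = field(default_factory=list)

    def validate_against(self, templates: NetworkTemplateSet) -> None:
        terr = templates.territories()
        V = templates.n_voxels
        for e in self.entries:
            vox = np.asarray(e.roi_voxels)
            if vox.size and (vox.min() < 0 or vox.max() >= V):
                raise IndexError(
                    f"effect voxels outside grid for patient {e.patient_id}"
                )
            if not np.all(terr[vox] == e.original_network):
                raise ValidationError(
                    f"roi voxels of {e.patient_id} do not lie in the territory "
                    f"of network {templates.names[e.original_network]}"
                )

    def for_patient(self, patient_id: str) -> list[EffectEntry]:
        return [e for e in self.entries if e.patient_id == patient_id]


@dataclass
class Cohort:
    """Two sessions per subject for patients and controls, plus ground truth."""

    templates: NetworkTemplateSet
    sessions: list[ScanSession]
    effect_spec: EffectSpec
    seed: int | None = None

    def subject_ids(self, group: Group | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sessions:
            if group is None or s.group == group:
                seen.setdefault(s.subject_id, None)
        return list(seen)

    def session(self, subject_id: str, timepoint: Timepoint) -> ScanSession:
        for s in self.sessions:
            if s.subject_id == subject_id and s.timepoint == timepoint:
                return s
        raise KeyError(f"no session {subject_id}/{timepoint}")


@dataclass
class PEMapSet:
    """Subject-specific parameter-estimate maps from dual regression."""

    subject_id: str
    timepoint: Timepoint
    pe: np.ndarray  # (K, V)

    def __post_init__(self) -> None:
        self.pe = np.asarray(self.pe, dtype=float)
        if not np.isfinite(self.pe).all():
            raise ValidationError("PE maps must be finite")


@dataclass
class DifferenceMapSet:
    """Post-minus-pre PE difference maps for one subject."""

    subject_id: str
    group: Group
    diff: np.ndarray  # (K, V)


@dataclass
class ZMapSet:
    """Patient difference maps z-scored against the control difference
    distribution.  Voxels where the control SD is zero are NaN-masked."""

    patient_id: str
    z: np.ndarray  # (K, V), NaN where masked
    mask: np.ndarray  # (K, V) bool, True = evaluable


@dataclass
class NullDistributions:
    """Permutation null of per-map extreme z-scores, one pair of
    distributions (maxima / minima) per network."""

    maxima: np.ndarray  # (K, N)
    minima: np.ndarray  # (K, N)
    n_perm: int
    pooling: Literal["per-map", "per-permutation"] = "per-map"


@dataclass
class ROI:
    """A contiguous cluster of suprathreshold voxels in one patient's z-map."""

    patient_id: str
    altered_network: int
    direction: Direction
    voxel_ids: tuple[int, ...]
    peak_p: float
    original_network: int | None = None


@dataclass
class PatientAdjacency:
    """Binary altered-by-original network incidence matrix for one patient."""

    patient_id: str
    direction: Direction
    matrix: np.ndarray  # (K, K) of {0,1}

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if not np.isin(m, (0, 1)).all():
            raise ValidationError("patient adjacency must be binary")
        self.matrix = m.astype(int)


@dataclass
class GroupFrequency:
    """Patient-count matrix: how many patients show each (altered, original)
    pair.  Not necessarily symmetric."""

    direction: Direction
    matrix: np.ndarray  # (K, K) non-negative ints
    n_patients: int
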