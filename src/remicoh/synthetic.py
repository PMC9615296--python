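"""Synthetic cohort generator.

Emulates the statistical structure of a two-session resting-state study:
K spatially localized network templates, per-subject voxel time series formed
as linear mixtures of band-limited network time courses plus Gaussian noise,
a patient group whose second session carries injected, spatially localized
coherence changes, and a control group with no systematic change.  Ground
truth for every injected effect is retained for recovery scoring.

The generative model matches the dual-regression forward model::

    data = M^T . diag(loadings) . C + noise

with ``M`` the (K, V) template matrix and ``C`` (K, T) unit-variance network
time courses.  An injected effect adds ``delta * C[a]`` to the post-session
time series of a small voxel set inside the territory of an *original*
network ``o``, i.e. a localized coherence change of *altered* network ``a``
within ``o``'s territory.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .types import (
    Cohort,
    DEFAULT_NETWORK_LABELS,
    EffectEntry,
    EffectSpec,
    NetworkTemplateSet,
    ScanSession,
    ValidationError,
)

__all__ = [
    "make_templates",
    "simulate_subject",
    "simulate_cohort",
    "load_clinical_fixture",
    "many_with_one_spec",
    "one_with_many_spec",
    "territory_roi",
    "ClinicalTable",
]

#: Default study dimensions: 18 patients, 44 controls (62 subjects).
N_PATIENTS = 18
N_CONTROLS = 44


def _network_labels(K: int) -> list[str]:
    if K <= len(DEFAULT_NETWORK_LABELS):
        return list(DEFAULT_NETWORK_LABELS[:K])
    return list(DEFAULT_NETWORK_LABELS) + [
        f"N{i}" for i in range(len(DEFAULT_NETWORK_LABELS), K)
    ]


def _blob_centers(K: int, grid_shape: tuple[int, ...]) -> np.ndarray:
    """Spread K blob centers on a regular sub-lattice of the grid."""
    dims = [g for g in grid_shape if g > 1]
    if not dims:
        raise ValidationError("grid has no extended dimension")
    # factor K into a near-square lattice over the extended dimensions
    n_rows = int(np.ceil(np.sqrt(K))) if len(dims) > 1 else K
    n_cols = int(np.ceil(K / n_rows)) if len(dims) > 1 else 1
    counts = [n_rows, n_cols][: len(dims)] + [1] * max(0, len(dims) - 2)
    centers = []
    for k in range(K):
        idx = [k // n_cols if len(dims) > 1 else k,
               k % n_cols if len(dims) > 1 else 0][: len(dims)]
        c = []
        j = 0
        for g in grid_shape:
            if g > 1:
                n = counts[j] if j < len(counts) else 1
                i = idx[j] if j < len(idx) else 0
                c.append((i + 0.5) * g / n)
                j += 1
            else:
                c.append(0.0)
        centers.append(c)
    return np.asarray(centers)


def make_templates(
    K: int = 10,
    grid_shape: tuple[int, ...] = (20, 20, 1),
    overlap_fraction: float = 0.2,
    seed: int = 0,
) -> NetworkTemplateSet:
    """Build K smooth, localized Gaussian-blob template maps, z-scored over
    voxels, with pairwise spatial correlation at most ``overlap_fraction``
    (up to a small floor set by the shared negative baseline of z-scored
    compact maps)."""
    grid_shape = tuple(int(g) for g in grid_shape)
    V = int(np.prod(grid_shape))
    if K < 2:
        raise ValidationError("K must be >= 2")
    if V < 40 * K:
        raise ValidationError(
            f"grid {grid_shape} too small for {K} non-degenerate blobs "
            f"(need V >= {40 * K}, got {V})"
        )
    rng = np.random.default_rng(seed)
    centers = _blob_centers(K, grid_shape)
    # nearest-neighbour spacing sets the blob width
    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    spacing = float(np.sqrt(d2.min()))
    jitter = rng.uniform(-0.08, 0.08, size=centers.shape) * spacing
    jitter[:, [g <= 1 for g in grid_shape]] = 0.0
    centers = centers + jitter

    coords = np.stack(
        np.meshgrid(*[np.arange(g) for g in grid_shape], indexing="ij"), -1
    ).reshape(V, len(grid_shape)).astype(float)

    # z-scored compact maps share a small negative baseline correlation, so
    # exactly-zero overlap is unattainable; 0.04 is the practical floor.
    target = max(overlap_fraction, 0.04)
    sigma = spacing / 4.0
    for _ in range(20):
        dist2 = ((coords[None, :, :] - centers[:, None, :]) ** 2).sum(-1)
        maps = np.exp(-dist2 / (2.0 * sigma**2))
        z = (maps - maps.mean(1, keepdims=True)) / maps.std(1, keepdims=True)
        corr = (z @ z.T) / V
        off = np.abs(corr - np.eye(K)).max()
        if off <= target or sigma <= 0.7:
            break
        sigma *= 0.85
    if off > target and sigma <= 0.7:
        raise ValidationError(
            "grid too small to place templates at the requested overlap"
        )
    return NetworkTemplateSet(
        names=_network_labels(K), maps=z, grid_shape=grid_shape
    )


def network_time_courses(
    K: int, T: int, rng: np.random.Generator, smooth_window: int = 5
) -> np.ndarray:
    """Band-limited, unit-variance network time courses: Gaussian white noise
    smoothed with a moving-average window, then standardized per course."""
    raw = rng.standard_normal((K, T + smooth_window - 1))
    kernel = np.ones(smooth_window) / smooth_window
    c = np.apply_along_axis(
        lambda x: np.convolve(x, kernel, mode="valid"), 1, raw
    )
    c = c - c.mean(1, keepdims=True)
    sd = c.std(1)
    if np.any(sd == 0):  # pragma: no cover - T>=2 white noise
        raise ValidationError("degenerate time course")
    return c / sd[:, None]


def simulate_subject(
    templates: NetworkTemplateSet,
    loadings: np.ndarray,
    T: int = 60,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
    subject_id: str = "S00",
    group: str = "control",
    timepoint: str = "pre",
    smooth_window: int = 5,
) -> ScanSession:
    """Simulate one session: ``data = M^T diag(loadings) C + noise``.

    The true time courses are retrievable via ``session.latent_courses``.
    """
    K = templates.n_networks
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape != (K,) or not np.isfinite(loadings).all():
        raise ValidationError("loadings must be a finite K-vector")
    if T < K + 1:
        raise ValidationError(f"need T >= K+1 = {K + 1}, got {T}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    C = network_time_courses(K, T, rng, smooth_window)
    data = templates.maps.T @ (loadings[:, None] * C)
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return ScanSession(
        subject_id=subject_id,
        group=group,  # type: ignore[arg-type]
        timepoint=timepoint,  # type: ignore[arg-type]
        data=data,
        latent_courses=C,
    )


def simulate_cohort(
    templates: NetworkTemplateSet,
    n_patients: int = N_PATIENTS,
    n_controls: int = N_CONTROLS,
    effect_spec: EffectSpec | None = None,
    T: int = 60,
    noise_sd: float = 1.0,
    loading_sd: float = 0.1,
    seed: int = 0,
) -> Cohort:
    """Simulate a two-session cohort of patients and controls.

    Loadings are drawn i.i.d. N(1, loading_sd^2) per subject, session, and
    network for both groups (the null longitudinal structure); injected
    effects additionally perturb the *post* session of the named patients in
    their ROI voxels by ``delta`` times the altered network's time course.
    """
    effect_spec = effect_spec or EffectSpec()
    effect_spec.validate_against(templates)
    rng = np.random.default_rng(seed)
    K = templates.n_networks
    sessions: list[ScanSession] = []

    def subject(sid: str, grp: str) -> None:
        for tp in ("pre", "post"):
            loadings = 1.0 + loading_sd * rng.standard_normal(K)
            sess = simulate_subject(
                templates, loadings, T=T, noise_sd=noise_sd, seed=rng,
                subject_id=sid, group=grp, timepoint=tp,
            )
            if grp == "patient" and tp == "post":
                for e in effect_spec.for_patient(sid):
                    vox = np.asarray(e.roi_voxels, dtype=int)
                    sess.data[vox, :] += (
                        e.delta * sess.latent_courses[e.altered_network]
                    )
            sessions.append(sess)

    for i in range(n_patients):
        subject(f"MS{i + 1:02d}", "patient")
    for i in range(n_controls):
        subject(f"HC{i + 1:02d}", "control")
    unknown = {e.patient_id for e in effect_spec.entries} - {
        s.subject_id for s in sessions
    }
    if unknown:
        raise ValidationError(f"effect spec names unknown patients: {unknown}")
    return Cohort(
        templates=templates, sessions=sessions, effect_spec=effect_spec,
        seed=seed,
    )


def territory_roi(
    templates: NetworkTemplateSet,
    network: int,
    size: int = 9,
    quantile: float = 0.7,
) -> tuple[int, ...]:
    """A compact patch of ``size`` voxels inside the territory of
    ``network``, seeded at the voxel whose template value sits at the given
    within-territory ``quantile``.

    Mid-territory placement (rather than the blob peak) keeps the injected
    signal from being collinear with the dominating template itself, which
    on small grids would let the spatial-regression stage absorb the effect
    into the original network's time course.
    """
    terr = templates.territories()
    candidates = np.flatnonzero(terr == network)
    if candidates.size == 0:
        raise ValidationError(
            f"network {network} dominates no voxel on this grid"
        )
    values = templates.maps[network, candidates]
    target = np.quantile(values, quantile)
    seed_vox = candidates[np.argmin(np.abs(values - target))]
    coords = np.stack(
        np.unravel_index(candidates, templates.grid_shape), axis=1
    ).astype(float)
    seed_xyz = np.asarray(
        np.unravel_index(seed_vox, templates.grid_shape), dtype=float
    )
    order = np.argsort(((coords - seed_xyz) ** 2).sum(1))
    return tuple(
        int(v) for v in candidates[order[: min(size, len(order))]]
    )


def _cycled_spec(
    templates: NetworkTemplateSet,
    n_affected: int,
    fixed: int,
    cycle: list[int],
    axis: str,
    delta: float,
    roi_size: int,
) -> EffectSpec:
    entries = []
    for i in range(n_affected):
        other = cycle[i % len(cycle)]
        a, o = (other, fixed) if axis == "column" else (fixed, other)
        entries.append(
            EffectEntry(
                patient_id=f"MS{i + 1:02d}",
                altered_network=a,
                original_network=o,
                direction="increase" if delta > 0 else "decrease",
                delta=delta,
                roi_voxels=territory_roi(templates, o, roi_size),
            )
        )
    return EffectSpec(entries)


def many_with_one_spec(
    templates: NetworkTemplateSet,
    target: int,
    altered_cycle: list[int] | None = None,
    n_affected: int = 13,
    delta: float = 2.0,
    roi_size: int = 9,
) -> EffectSpec:
    """Column-effect fixture: ``n_affected`` patients whose (various) altered
    networks all change coherence within the territory of one ``target``
    network — the many-with-one pattern."""
    K = templates.n_networks
    cycle = altered_cycle or [k for k in range(K) if k != target][:4]
    return _cycled_spec(
        templates, n_affected, target, cycle, "column", delta, roi_size
    )


def one_with_many_spec(
    templates: NetworkTemplateSet,
    altered: int,
    original_cycle: list[int] | None = None,
    n_affected: int = 13,
    delta: float = 2.0,
    roi_size: int = 9,
) -> EffectSpec:
    """Row-effect fixture: one ``altered`` network changes coherence within
    the territories of various original networks — the one-with-many
    pattern."""
    K = templates.n_networks
    cycle = original_cycle or [k for k in range(K) if k != altered][:4]
    return _cycled_spec(
        templates, n_affected, altered, cycle, "row", delta, roi_size
    )


class ClinicalTable:
    """The printed demographic/clinical table (18 patients), with explicit
    missingness: one missing pre-relapse lesion load (MS06) and six missing
    remission EDSS scores."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def complete_pairs(self, pre_col: str, post_col: str) -> pd.DataFrame:
        sub = self.frame[["id", pre_col, post_col]].dropna()
        return sub.reset_index(drop=True)


def load_clinical_fixture() -> ClinicalTable:
    """Load the embedded clinical table exactly as printed (values are never
    imputed; 'n.a.' cells become NaN)."""
    ref = importlib.resources.files("remicoh").joinpath(
        "data/clinical_table.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        frame = pd.read_csv(
            path, sep="\t", na_values=["n.a."], dtype={"id": str, "sex": str}
        )
    if len(frame) != 18:  # sanity: the fixture ships with the package
        raise ValidationError("clinical fixture must have 18 rows")
    return ClinicalTable(frame)
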