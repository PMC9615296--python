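"""End-to-end orchestration: simulate → dual-regress → detect → adjacency →
test-effects → individual → clinical.

A ``RunConfig`` carries every stage parameter (defaults are the study's
stated constants: 10,000 permutations, 100,000 shuffle repetitions, alpha
0.025 per tail, 5 mm FWHM smoothing, Bonferroni z > 3.6623) and named
per-stage seeds derived from one master seed.  ``run_pipeline`` executes all
stages, writes per-stage artifacts plus a machine-readable ``report.json``
into a run directory, and is bit-reproducible for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adjacency as adj
from . import clinical as clin
from . import detection, dualreg, hypotheses, synthetic
from .io import config_hash, load_session, load_templates, save_effect_spec, \
    save_matrix_tsv, write_sidecar
from .types import (
    Cohort,
    DifferenceMapSet,
    IncompleteDesignError,
    RemicohError,
    ROI,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]

_STAGE_SEED_NAMES = ("cohort", "null", "shuffle_increase", "shuffle_decrease")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    mode: str = "synthetic"
    seed: int = 0
    # synthetic cohort
    n_networks: int = 10
    grid_shape: tuple[int, ...] = (20, 20, 1)
    n_timepoints: int = 60
    noise_sd: float = 1.0
    loading_sd: float = 0.1
    n_patients: int = 18
    n_controls: int = 44
    overlap_fraction: float = 0.2
    effect_fixture: str = "none"  # none | many-with-one | one-with-many
    effect_target: int = 3        # Crb in the default label order
    effect_n_affected: int = 13
    effect_delta: float = 2.0
    effect_roi_size: int = 9
    # real-volume mode
    templates_path: str | None = None
    sessions_manifest: str | None = None
    # dual regression / smoothing
    fwhm: float = 5.0
    voxel_size: float = 1.0
    demean: bool = True
    variance_normalize: bool = True
    # detection
    n_perm: int = 10_000
    alpha: float = 0.025
    pooling: str = "per-map"
    p_convention: str = "add-one"
    min_cluster_size: int = 1
    # adjacency / hypothesis tests
    attribution_statistic: str = "mean"
    attribution_threshold: float | None = None
    n_reps: int = 100_000
    alpha_fwer: float = 0.05
    # output
    write_maps: bool = False

    def stage_seeds(self) -> dict[str, int]:
        rng = np.random.default_rng(self.seed)
        return {
            name: int(rng.integers(2**31))
            for name in _STAGE_SEED_NAMES
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise RemicohError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.grid_shape = tuple(cfg.grid_shape)
        return cfg

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    """In-memory pipeline outputs (the report holds the JSON view)."""

    cohort: Cohort
    diffs: list[DifferenceMapSet]
    rois: list[ROI]
    group_freq: dict
    effects: dict
    report: dict


def _stage(name: str, fingerprint: str):
    """Context wrapper: re-raise stage failures with stage name and input
    fingerprint."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s (input %s)", name, fingerprint)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, RemicohError):
                raise RemicohError(
                    f"stage {name!r} failed on input {fingerprint}: {exc}"
                ) from exc
            if exc is not None:
                exc.args = (
                    f"stage {name!r} (input {fingerprint}): {exc}",
                )
            return False

    return _Ctx()


def build_cohort(config: RunConfig, seeds: dict[str, int]) -> Cohort:
    """Synthesize or load the two-session cohort."""
    if config.mode == "synthetic":
        templates = synthetic.make_templates(
            K=config.n_networks,
            grid_shape=config.grid_shape,
            overlap_fraction=config.overlap_fraction,
            seed=seeds["cohort"],
        )
        if config.effect_fixture == "none":
            spec = None
        elif config.effect_fixture == "many-with-one":
            spec = synthetic.many_with_one_spec(
                templates, target=config.effect_target,
                n_affected=config.effect_n_affected,
                delta=config.effect_delta,
                roi_size=config.effect_roi_size,
            )
        elif config.effect_fixture == "one-with-many":
            spec = synthetic.one_with_many_spec(
                templates, altered=config.effect_target,
                n_affected=config.effect_n_affected,
                delta=config.effect_delta,
                roi_size=config.effect_roi_size,
            )
        else:
            raise RemicohError(
                f"unknown effect fixture {config.effect_fixture!r}"
            )
        return synthetic.simulate_cohort(
            templates,
            n_patients=config.n_patients,
            n_controls=config.n_controls,
            effect_spec=spec,
            T=config.n_timepoints,
            noise_sd=config.noise_sd,
            loading_sd=config.loading_sd,
            seed=seeds["cohort"],
        )
    if config.mode == "real":
        if not config.templates_path:
            raise RemicohError("real mode requires templates_path")
        templates = load_templates(Path(config.templates_path))
        if not config.sessions_manifest:
            raise RemicohError("real mode requires sessions_manifest")
        manifest = pd.read_csv(Path(config.sessions_manifest), sep="\t")
        sessions = [
            load_session(
                Path(r.path), subject_id=str(r.subject_id),
                group=r.group, timepoint=r.timepoint,
            )
            for r in manifest.itertuples()
        ]
        from .types import EffectSpec

        return Cohort(templates=templates, sessions=sessions,
                      effect_spec=EffectSpec())
    raise RemicohError(f"unknown mode {config.mode!r}")


def compute_differences(
    cohort: Cohort, config: RunConfig
) -> list[DifferenceMapSet]:
    """Dual-regress both sessions of every subject, smooth the PE maps, and
    form post-minus-pre difference maps."""
    diffs = []
    for sid in cohort.subject_ids():
        pes = {}
        for tp in ("pre", "post"):
            sess = cohort.session(sid, tp)
            pe = dualreg.dual_regress(
                cohort.templates, sess,
                demean=config.demean,
                variance_normalize=config.variance_normalize,
            )
            pes[tp] = dualreg.smooth_pe_maps(
                pe, config.fwhm, cohort.templates.grid_shape,
                voxel_size=config.voxel_size,
            )
        group = cohort.session(sid, "pre").group
        diffs.append(
            dualreg.difference_maps(pes["post"], pes["pre"], group=group)
        )
    return diffs


def detect_rois(
    diffs: list[DifferenceMapSet],
    cohort: Cohort,
    config: RunConfig,
    seeds: dict[str, int],
):
    """Patient z-maps against controls, permutation null over all subjects,
    FWER p-values, and cluster extraction."""
    control_diffs = [d for d in diffs if d.group == "control"]
    patient_diffs = [d for d in diffs if d.group == "patient"]
    null = detection.build_null(
        diffs,
        n_select=len(patient_diffs),
        n_perm=config.n_perm,
        seed=seeds["null"],
        pooling=config.pooling,
    )
    rois: list[ROI] = []
    zmaps = {}
    for pdiff in patient_diffs:
        zmap = dualreg.zscore_vs_controls(pdiff, control_diffs)
        p_up, p_lo = detection.empirical_p(
            zmap, null, convention=config.p_convention
        )
        rois.extend(
            detection.threshold_and_cluster(
                p_up, p_lo, zmap, cohort.templates.grid_shape,
                alpha=config.alpha,
                min_cluster_size=config.min_cluster_size,
            )
        )
        zmaps[pdiff.subject_id] = zmap
    return null, zmaps, rois


def build_adjacency(rois, cohort: Cohort, config: RunConfig):
    """Attribute ROIs and assemble per-patient and group matrices."""
    adj.attribute_rois(
        rois, cohort.templates,
        statistic=config.attribution_statistic,
        z_threshold=config.attribution_threshold,
    )
    K = cohort.templates.n_networks
    patients = cohort.subject_ids("patient")
    per_direction = {"increase": [], "decrease": []}
    for pid in patients:
        mats = adj.patient_adjacency(rois, K, pid)
        for d in per_direction:
            per_direction[d].append(mats[d])
    freqs = {d: adj.group_frequency(mats) for d, mats in
             per_direction.items()}
    return per_direction, freqs


def run_effect_tests(per_direction, config: RunConfig,
                     seeds: dict[str, int]):
    return {
        d: hypotheses.run_direction_tests(
            per_direction[d],
            n_reps=config.n_reps,
            seed=seeds[f"shuffle_{d}"],
            alpha_fwer=config.alpha_fwer,
            convention=config.p_convention,
        )
        for d in ("increase", "decrease")
    }


def individual_analysis(rois, cohort: Cohort):
    """Per-patient network probability profiles (both bases), modal-network
    tallies, and the Coherence x Network repeated-measures ANOVA where the
    design is complete."""
    from . import individual as indiv

    K = cohort.templates.n_networks
    patients = cohort.subject_ids("patient")
    out: dict = {"profiles": {}, "anova": {}, "modal_counts": {}}
    for basis in ("original", "altered"):
        profiles = {
            d: [
                indiv.network_probabilities(rois, basis, d, K, pid)
                for pid in patients
            ]
            for d in ("increase", "decrease")
        }
        out["profiles"][basis] = profiles
        modal = {}
        for d in ("increase", "decrease"):
            counts = np.zeros(K, dtype=int)
            for prof in profiles[d]:
                for k in indiv.most_likely_networks(prof):
                    counts[k] += 1
            modal[d] = counts
        out["modal_counts"][basis] = modal
        if all(
            not p.missing for d in profiles for p in profiles[d]
        ):
            data = np.stack(
                [
                    np.stack(
                        [
                            indiv.arcsine_transform(
                                profiles[d][i].probs
                            )
                            for d in ("increase", "decrease")
                        ]
                    )
                    for i in range(len(patients))
                ]
            )
            out["anova"][basis] = indiv.rm_anova(data)
        else:
            out["anova"][basis] = None  # incomplete design: skipped
    return out


def clinical_analysis() -> dict:
    """All clinical-table statistics from the embedded fixture."""
    table = synthetic.load_clinical_fixture()
    edss = table.complete_pairs("edss_pre", "edss_post")
    med_pre, iqr_pre = clin.median_iqr(edss["edss_pre"].to_numpy())
    med_post, iqr_post = clin.median_iqr(edss["edss_post"].to_numpy())
    wil = clin.wilcoxon_signed_rank(
        edss["edss_pre"].to_numpy(), edss["edss_post"].to_numpy()
    )
    ll = table.complete_pairs("ll_pre_ml", "ll_post_ml")
    t, df, p_t = clin.paired_t(
        ll["ll_pre_ml"].to_numpy(), ll["ll_post_ml"].to_numpy()
    )
    demo = clin.summarize_demographics(table)
    return {
        "n_patients": len(table),
        "edss_complete_pairs": int(len(edss)),
        "edss_median_relapse": med_pre,
        "edss_iqr_relapse": iqr_pre,
        "edss_median_remission": med_post,
        "edss_iqr_remission": iqr_post,
        "wilcoxon_w": wil.w,
        "wilcoxon_n_effective": wil.n_effective,
        "wilcoxon_p": wil.p,
        "wilcoxon_method": wil.method,
        "lesion_complete_pairs": int(len(ll)),
        "lesion_t": t,
        "lesion_df": df,
        "lesion_p": p_t,
        "age_mean": demo["age_mean"],
        "age_sd": demo["age_sd"],
        "sex_counts": demo["sex_counts"],
    }


def _effects_report(res: hypotheses.EffectTestResult) -> dict:
    return {
        "expected_count": res.cells.expected,
        "row_counts": res.row_counts.tolist(),
        "col_counts": res.col_counts.tolist(),
        "p_fwer_row": res.p_fwer_row.tolist(),
        "p_fwer_col": res.p_fwer_col.tolist(),
        "single_cells": res.single_cells,
        "null_max_row_mean": float(res.null_max_row.mean()),
        "null_max_col_mean": float(res.null_max_col.mean()),
    }


def _anova_report(a) -> dict | None:
    if a is None:
        return None
    return {
        "undefined": a.undefined,
        "network": {"F": a.f_network, "df": list(a.df_network),
                    "p": a.p_network},
        "coherence": {"F": a.f_coherence, "df": list(a.df_coherence),
                      "p": a.p_coherence},
        "interaction": {"F": a.f_interaction, "df": list(a.df_interaction),
                        "p": a.p_interaction},
    }


def run_pipeline(config: RunConfig,
                 out_dir: Path | str | None = None) -> PipelineResult:
    """Execute every stage in order; optionally write all artifacts and the
    final report into ``out_dir``."""
    seeds = config.stage_seeds()
    chash = config_hash(config.to_dict())

    with _stage("simulate", chash):
        cohort = build_cohort(config, seeds)
    with _stage("dual-regress", chash):
        diffs = compute_differences(cohort, config)
    with _stage("detect", chash):
        null, zmaps, rois = detect_rois(diffs, cohort, config, seeds)
    with _stage("adjacency", chash):
        per_direction, freqs = build_adjacency(rois, cohort, config)
    with _stage("test-effects", chash):
        effects = run_effect_tests(per_direction, config, seeds)
    with _stage("individual", chash):
        indiv_out = individual_analysis(rois, cohort)
    with _stage("clinical", chash):
        clinical = clinical_analysis()

    names = list(cohort.templates.names)
    report = {
        "config": config.to_dict(),
        "config_hash": chash,
        "stage_seeds": seeds,
        "networks": names,
        "cohort": {
            "n_patients": len(cohort.subject_ids("patient")),
            "n_controls": len(cohort.subject_ids("control")),
            "n_sessions": len(cohort.sessions),
            "n_injected_effects": len(cohort.effect_spec.entries),
        },
        "detection": {
            "null_size": int(null.maxima.shape[1]),
            "n_rois": {
                d: sum(1 for r in rois if r.direction == d)
                for d in ("increase", "decrease")
            },
        },
        "adjacency": {
            d: freqs[d].matrix.tolist() for d in ("increase", "decrease")
        },
        "effects": {
            d: _effects_report(effects[d]) for d in ("increase", "decrease")
        },
        "individual": {
            "modal_counts": {
                basis: {
                    d: counts.tolist() for d, counts in modal.items()
                }
                for basis, modal in indiv_out["modal_counts"].items()
            },
            "anova": {
                basis: _anova_report(indiv_out["anova"][basis])
                for basis in ("original", "altered")
            },
        },
        "clinical": clinical,
    }

    if out_dir is not None:
        _write_run_dir(Path(out_dir), config, cohort, rois, freqs, report,
                       zmaps)
    return PipelineResult(
        cohort=cohort, diffs=diffs, rois=rois, group_freq=freqs,
        effects=effects, report=report,
    )


def _write_run_dir(out: Path, config: RunConfig, cohort, rois, freqs,
                   report, zmaps) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_sidecar(out / "config.json", config.to_dict())
    names = list(cohort.templates.names)
    for d, freq in freqs.items():
        save_matrix_tsv(
            out / f"group_frequency_{d}.tsv", freq.matrix,
            row_labels=names, col_labels=names, index_name="altered",
        )
    roi_rows = [
        {
            "patient_id": r.patient_id,
            "altered_network": names[r.altered_network],
            "direction": r.direction,
            "size": len(r.voxel_ids),
            "peak_p": r.peak_p,
            "original_network": (
                names[r.original_network]
                if r.original_network is not None else ""
            ),
        }
        for r in rois
    ]
    pd.DataFrame(
        roi_rows,
        columns=["patient_id", "altered_network", "direction", "size",
                 "peak_p", "original_network"],
    ).to_csv(out / "rois.tsv", sep="\t", index=False)
    save_effect_spec(out / "injected_effects.tsv", cohort.effect_spec)
    if config.write_maps:
        arr = {pid: z.z for pid, z in zmaps.items()}
        np.savez_compressed(out / "zmaps.npz", **arr)
    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2) + "\n"
    )
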