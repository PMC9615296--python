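"""Format adapters: NIfTI-1 and headered-TSV volumes, TSV tables, JSON
sidecars.

Synthetic cohorts round-trip through either format; real-volume mode reads
4D NIfTI scans (voxel size taken from the header) or plain voxels-by-time
TSV matrices.  Every generated artifact can carry a JSON sidecar recording
the parameters and seeds that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    EffectEntry,
    EffectSpec,
    NetworkTemplateSet,
    RemicohError,
    ScanSession,
)

__all__ = [
    "write_sidecar",
    "config_hash",
    "save_matrix_tsv",
    "load_matrix_tsv",
    "save_templates",
    "load_templates",
    "save_session",
    "load_session",
    "save_effect_spec",
    "load_effect_spec",
]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_sidecar(path: Path, payload: dict) -> None:
    path = Path(path)
    path.write_text(json.dumps(payload, sort_keys=True, indent=2,
                               default=str) + "\n")


def save_matrix_tsv(
    path: Path,
    matrix: np.ndarray,
    row_labels=None,
    col_labels=None,
    index_name: str = "",
) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=row_labels,
                      columns=col_labels)
    df.index.name = index_name or None
    df.to_csv(path, sep="\t", index=row_labels is not None,
              header=col_labels is not None)


def load_matrix_tsv(path: Path, has_index: bool = True,
                    has_header: bool = True) -> pd.DataFrame:
    return pd.read_csv(
        Path(path), sep="\t",
        index_col=0 if has_index else None,
        header=0 if has_header else None,
    )


def _is_nifti(path: Path) -> bool:
    name = str(path)
    return name.endswith(".nii") or name.endswith(".nii.gz")


def save_templates(path: Path, templates: NetworkTemplateSet) -> None:
    """Templates as K x V TSV (rows = networks) or as a 4D NIfTI with K
    volumes; a JSON sidecar records grid shape and names."""
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        vol = templates.maps.reshape(
            (templates.n_networks, *templates.grid_shape)
        )
        img = nib.Nifti1Image(
            np.moveaxis(vol, 0, -1).astype(np.float32), affine=np.eye(4)
        )
        nib.save(img, path)
    else:
        save_matrix_tsv(
            path, templates.maps, row_labels=templates.names,
            col_labels=[f"v{j}" for j in range(templates.n_voxels)],
            index_name="network",
        )
    write_sidecar(
        path.with_suffix(path.suffix + ".json"),
        {"grid_shape": list(templates.grid_shape),
         "names": list(templates.names)},
    )


def load_templates(path: Path) -> NetworkTemplateSet:
    path = Path(path)
    if not path.exists():
        raise RemicohError(f"template file not found: {path}")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(path)
        vol = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
        grid_shape = vol.shape[1:]
        maps = vol.reshape(vol.shape[0], -1)
    else:
        df = load_matrix_tsv(path)
        maps = df.to_numpy(dtype=float)
        grid_shape = tuple(meta.get("grid_shape", (maps.shape[1],)))
        meta.setdefault("names", list(df.index))
    names = meta.get("names", [f"N{k}" for k in range(maps.shape[0])])
    return NetworkTemplateSet(
        names=names, maps=maps, grid_shape=tuple(meta.get(
            "grid_shape", grid_shape)),
    )


def save_session(path: Path, session: ScanSession,
                 grid_shape: tuple[int, ...] | None = None) -> None:
    """One session as a headered voxels-by-time TSV or a 4D NIfTI."""
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        if grid_shape is None:
            raise RemicohError("grid_shape required to write NIfTI sessions")
        V, T = session.data.shape
        vol = session.data.reshape((*grid_shape, T)).astype(np.float32)
        affine = np.eye(4)
        img = nib.Nifti1Image(vol, affine=affine)
        img.header.set_zooms(
            (*[1.0] * len(grid_shape), session.sampling_interval)
        )
        nib.save(img, path)
    else:
        V, T = session.data.shape
        save_matrix_tsv(
            path, session.data,
            row_labels=[f"v{j}" for j in range(V)],
            col_labels=[f"t{j}" for j in range(T)],
            index_name="voxel",
        )
    write_sidecar(
        path.with_suffix(path.suffix + ".json"),
        {
            "subject_id": session.subject_id,
            "group": session.group,
            "timepoint": session.timepoint,
            "sampling_interval": session.sampling_interval,
        },
    )


def load_session(path: Path, subject_id: str | None = None,
                 group: str | None = None,
                 timepoint: str | None = None) -> ScanSession:
    path = Path(path)
    if not path.exists():
        raise RemicohError(f"session file not found: {path}")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(path)
        arr = np.asarray(img.dataobj, dtype=float)
        data = arr.reshape(-1, arr.shape[-1])
        tr = float(img.header.get_zooms()[-1]) or 1.0
    else:
        data = load_matrix_tsv(path).to_numpy(dtype=float)
        tr = float(meta.get("sampling_interval", 1.0))
    return ScanSession(
        subject_id=subject_id or meta.get("subject_id", path.stem),
        group=group or meta.get("group", "control"),
        timepoint=timepoint or meta.get("timepoint", "pre"),
        data=data,
        sampling_interval=tr,
    )


_EFFECT_COLUMNS = [
    "patient_id", "altered_network", "original_network", "direction",
    "delta", "roi_voxels",
]


def save_effect_spec(path: Path, spec: EffectSpec) -> None:
    """Ground-truth effects as TSV; roi_voxels is a comma-joined index
    list (column dictionary in the header sidecar)."""
    rows = [
        {
            "patient_id": e.patient_id,
            "altered_network": e.altered_network,
            "original_network": e.original_network,
            "direction": e.direction,
            "delta": e.delta,
            "roi_voxels": ",".join(str(v) for v in e.roi_voxels),
        }
        for e in spec.entries
    ]
    pd.DataFrame(rows, columns=_EFFECT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def load_effect_spec(path: Path) -> EffectSpec:
    df = pd.read_csv(Path(path), sep="\t", dtype={"roi_voxels": str})
    entries = [
        EffectEntry(
            patient_id=str(r.patient_id),
            altered_network=int(r.altered_network),
            original_network=int(r.original_network),
            direction=r.direction,
            delta=float(r.delta),
            roi_voxels=tuple(
                int(v) for v in str(r.roi_voxels).split(",") if v
            ),
        )
        for r in df.itertuples()
    ]
    return EffectSpec(entries)
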