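"""File formats: NIfTI-1 volumes and masks, TSV tables and signals, JSON
configs and manifests.

Conventions: TSV is tab-delimited UTF-8 with "." decimals; NIfTI-1 stores
volumes with the repetition time in the 4th pixel dimension; all tables use
the fixed column names of the cohort schema.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import RegionMask, SessionSignals, VolumeSeries
from .stats import GROUP_SCORES

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_session_table",
    "write_table",
    "write_session_signals",
    "read_session_signals",
]

logger = logging.getLogger("boldcsf")

COHORT_COLUMNS = [
    "subject_id",
    "session_id",
    "group",
    "age",
    "gender",
    "apoe_e4_count",
    "suvr_base",
    "suvr_fu",
    "mmse_base",
    "mmse_fu",
    "batch",
]


def write_volume(volumes: VolumeSeries, path) -> Path:
    """Write a 4D series as NIfTI-1, recording voxel size and TR."""
    path = Path(path)
    img = nib.Nifti1Image(volumes.data.astype(np.float32), affine=np.eye(4))
    zooms = tuple(volumes.voxel_size_mm) + (volumes.tr_seconds,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def read_volume(path, tr_override: float | None = None) -> VolumeSeries:
    """Read a 4D NIfTI-1 series; TR comes from the header's 4th pixel
    dimension unless overridden (an override is logged)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4D volume series, got {data.ndim}D")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr_override is not None:
        if tr > 0 and abs(tr - tr_override) > 1e-9:
            logger.warning("%s: overriding header TR %.4g s with %.4g s", path, tr, tr_override)
        tr = float(tr_override)
    if tr <= 0:
        raise ValueError(f"{path}: repetition time missing from header; pass tr_override")
    return VolumeSeries(data, tr_seconds=tr, voxel_size_mm=tuple(float(z) for z in zooms[:3]))


def write_mask(mask: RegionMask, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine=np.eye(4))
    nib.save(img, str(path))
    return path


def read_mask(path, role: str = "gray_matter") -> RegionMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got {data.ndim}D")
    return RegionMask(data > 0, role=role)


def write_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_session_table(path) -> pd.DataFrame:
    """Read and validate a cohort session table (TSV, or CSV by extension).

    Checks: required columns present, unique session IDs, known group
    labels, MMSE within [0, 30], APOE allele count in {0, 1, 2}.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    dup = table["session_id"][table["session_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate session_id {dup.iloc[0]!r}")
    bad_group = set(table["group"].dropna()) - set(GROUP_SCORES)
    if bad_group:
        raise ValueError(f"{path}: unknown group labels {sorted(bad_group)}")
    for col in ("mmse_base", "mmse_fu"):
        out_of_range = table.index[table[col].notna() & ((table[col] < 0) | (table[col] > 30))]
        if len(out_of_range):
            raise ValueError(f"{path}: {col} outside [0, 30] at row {int(out_of_range[0])}")
    bad_apoe = table.index[table["apoe_e4_count"].notna() & ~table["apoe_e4_count"].isin([0, 1, 2])]
    if len(bad_apoe):
        raise ValueError(f"{path}: apoe_e4_count not in {{0,1,2}} at row {int(bad_apoe[0])}")
    bad_gender = set(table["gender"].dropna()) - {"M", "F"}
    if bad_gender:
        raise ValueError(f"{path}: unknown gender labels {sorted(bad_gender)}")
    return table


def write_session_signals(signals: SessionSignals, path_stem) -> tuple[Path, Path]:
    """Write one session's signals as a two-column-per-signal TSV plus a
    JSON provenance sidecar. Returns (tsv_path, json_path)."""
    path_stem = Path(path_stem)
    tsv = path_stem.with_suffix(".tsv")
    t = np.arange(signals.n_timepoints) * signals.tr_seconds
    pd.DataFrame(
        {"time_s": t, "global_bold": signals.global_bold, "csf": signals.csf}
    ).to_csv(tsv, sep="\t", index=False)
    sidecar = path_stem.with_suffix(".json")
    meta = {
        "tr_seconds": signals.tr_seconds,
        "n_discarded_edge_volumes": signals.n_discarded_edge_volumes,
        "provenance": signals.provenance,
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return tsv, sidecar


def read_session_signals(path_stem) -> SessionSignals:
    path_stem = Path(path_stem)
    df = pd.read_csv(path_stem.with_suffix(".tsv"), sep="\t")
    sidecar = path_stem.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    tr = meta.get("tr_seconds")
    if tr is None:
        t = df["time_s"].to_numpy()
        if t.size < 2:
            raise ValueError(f"{path_stem}: cannot infer TR from a single sample")
        tr = float(t[1] - t[0])
        warnings.warn(f"{path_stem}: provenance sidecar missing; TR inferred from time column")
    return SessionSignals(
        global_bold=df["global_bold"].to_numpy(dtype=float),
        csf=df["csf"].to_numpy(dtype=float),
        tr_seconds=float(tr),
        n_discarded_edge_volumes=int(meta.get("n_discarded_edge_volumes", 0)),
        provenance=meta.get("provenance", {}),
    )
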