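"""File-format handling: NIfTI volumes and the pipeline's TSV/JSON tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .glm import EventTable
from .images import BOLDRun, LabelVolume, StatMap
from .stimuli import EmbeddingTable, StimulusSet


def _load_nifti(path):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        return nib.load(str(path))
    except Exception as exc:  # nibabel raises several header/format errors
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc


def read_bold_run(path, tr: float | None = None) -> BOLDRun:
    """Load a 4D functional NIfTI; TR from the header unless overridden."""
    img = _load_nifti(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected 4D volume, got {data.ndim}D")
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    return BOLDRun(data, np.asarray(img.affine), tr)


def write_bold_run(run: BOLDRun, path) -> None:
    img = nib.Nifti1Image(run.data, run.affine)
    img.header.set_zooms(tuple(img.header.get_zooms()[:3]) + (run.tr,))
    nib.save(img, str(path))


def read_stat_map(path, kind: str = "t") -> StatMap:
    img = _load_nifti(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D volume, got {data.ndim}D")
    return StatMap(data, np.asarray(img.affine), kind=kind)


def write_stat_map(m: StatMap, path) -> None:
    nib.save(nib.Nifti1Image(m.data.astype(np.float32), m.affine), str(path))


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def read_label_volume(path, label_names: dict | None = None) -> LabelVolume:
    img = _load_nifti(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D label volume, got {data.ndim}D")
    return LabelVolume(data, np.asarray(img.affine), label_names or {})


def write_label_volume(vol: LabelVolume, path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.int16), vol.affine), str(path))


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


def read_events(path) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, EventTable.REQUIRED, path)
    return EventTable(df)


def read_motion(path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter="\t")
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise FormatError(f"{path}: motion table must have 6 columns")
    return arr


def read_manifest(path) -> StimulusSet:
    df = pd.read_csv(path, sep="\t")
    _require_columns(
        df,
        ("id", "condition", "logo_graphemes", "stroke_count", "pixel_fraction", "frequency"),
        path,
    )
    if df.id.duplicated().any():
        raise FormatError(f"{path}: duplicate stimulus ids")
    return StimulusSet.from_frame(df)


def read_embeddings(path) -> EmbeddingTable:
    return EmbeddingTable.from_tsv(path)


def read_json(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
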