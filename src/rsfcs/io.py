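"""NIfTI / CSV / text plumbing.

All volume I/O goes through nibabel; clinical tables are RFC-4180 CSV with
validation of the required covariate columns; motion traces are 6-column
whitespace-delimited text.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import BoldImage

__all__ = [
    "read_nifti", "write_nifti", "read_bold", "write_bold",
    "read_motion_trace", "write_motion_trace",
    "read_clinical_csv", "write_table", "write_json", "file_sha256",
]

REQUIRED_CLINICAL = ("subject", "group", "age", "gender", "education")


def write_nifti(path: str | Path, data: np.ndarray, affine: np.ndarray) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float)), path)
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_bold(path: str | Path, img: BoldImage) -> Path:
    path = Path(path)
    nii = nib.Nifti1Image(np.asarray(img.data), img.affine)
    nii.header.set_zooms((*nii.header.get_zooms()[:3], img.tr_seconds))
    nib.save(nii, path)
    return path


def read_bold(path: str | Path, tr_seconds: float | None = None,
              subject_id: str = "") -> BoldImage:
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj)
    if tr_seconds is None:
        zooms = nii.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    if not subject_id:
        subject_id = Path(path).name.split(".")[0]
        subject_id = subject_id.removesuffix("_bold")
    return BoldImage(data=data, affine=nii.affine, tr_seconds=tr_seconds,
                     subject_id=subject_id)


def write_motion_trace(path: str | Path, trace: np.ndarray) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(trace, dtype=float), fmt="%.8f")
    return path


def read_motion_trace(path: str | Path) -> np.ndarray:
    trace = np.loadtxt(path)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError(f"{path}: motion trace must have 6 columns")
    return trace


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate the clinical table.

    Requires subject/group/age/gender/education columns; any missing value
    among the required covariates raises an error naming the row.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in REQUIRED_CLINICAL if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    if df["subject"].duplicated().any():
        dup = df.loc[df["subject"].duplicated(), "subject"].iloc[0]
        raise ValueError(f"{path}: duplicate subject id {dup!r}")
    for col in REQUIRED_CLINICAL:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(
                f"{path}: missing {col!r} value in row {int(bad[0]) + 2} "
                f"(subject {df.loc[bad[0], 'subject'] if col != 'subject' else '?'})")
    return df


def write_table(path: str | Path, df: pd.DataFrame) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_json(path: str | Path, obj) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
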