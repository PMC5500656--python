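"""Subject-level temporal preprocessing.

Fixed stage order: initial-volume discard -> motion QC -> nuisance
regression -> band-pass.  The nuisance model holds 14 regressors (six
motion parameters, their six backward-difference derivatives, and mean
white-matter and CSF signals); the global mean signal is deliberately not
among them.  The band-pass is an ideal rectangular discrete-Fourier filter
(bins with frequency inside [low, high] retained inclusively, everything
else — including the mean — zeroed), which makes the filter idempotent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import BoldImage, VoxelTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "QcVerdict",
    "discard_initial_volumes",
    "motion_qc",
    "build_confounds",
    "regress_nuisance",
    "bandpass",
]

CONFOUND_COLUMNS = (
    [f"trans_{a}" for a in "xyz"] + [f"rot_{a}" for a in "xyz"]
    + [f"trans_{a}_deriv" for a in "xyz"] + [f"rot_{a}_deriv" for a in "xyz"]
    + ["wm_mean", "csf_mean"]
)


@dataclass
class QcVerdict:
    """Motion quality-control outcome for one subject.

    Exclusion requires strictly exceeding either limit on any axis
    (a maximum of exactly 2.0 mm passes).
    """

    subject_id: str
    max_abs_translation_mm: np.ndarray  # (3,)
    max_abs_rotation_deg: np.ndarray    # (3,)
    included: bool


def discard_initial_volumes(img: BoldImage, n_discard: int = 10) -> BoldImage:
    """Drop the first ``n_discard`` volumes (signal-equilibration scrub)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= img.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {img.n_volumes} volumes")
    return BoldImage(data=img.data[..., n_discard:], affine=img.affine,
                     tr_seconds=img.tr_seconds, subject_id=img.subject_id)


def motion_qc(trace: np.ndarray, trans_limit_mm: float = 2.0,
              rot_limit_deg: float = 2.0, subject_id: str = "") -> QcVerdict:
    """Apply the translation/rotation exclusion rule to a 6-column trace."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty motion trace")
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError("motion trace must have exactly 6 columns")
    if not np.all(np.isfinite(trace)):
        raise ValueError("motion trace contains non-finite values")
    max_trans = np.abs(trace[:, :3]).max(axis=0)
    max_rot = np.abs(trace[:, 3:]).max(axis=0)
    included = bool(np.all(max_trans <= trans_limit_mm)
                    and np.all(max_rot <= rot_limit_deg))
    return QcVerdict(subject_id=subject_id, max_abs_translation_mm=max_trans,
                     max_abs_rotation_deg=max_rot, included=included)


def build_confounds(trace: np.ndarray, img: BoldImage, wm_mask: np.ndarray,
                    csf_mask: np.ndarray) -> np.ndarray:
    """Time x 14 confound matrix in the order of :data:`CONFOUND_COLUMNS`.

    Derivatives are backward differences with a leading zero row.  WM and
    CSF columns are mean in-mask signals of ``img``.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError("motion trace must have exactly 6 columns")
    if trace.shape[0] != img.n_volumes:
        raise ValueError(
            f"trace has {trace.shape[0]} rows but image has {img.n_volumes} volumes")
    wm_mask = np.asarray(wm_mask, dtype=bool)
    csf_mask = np.asarray(csf_mask, dtype=bool)
    for name, m in (("WM", wm_mask), ("CSF", csf_mask)):
        if m.shape != img.grid_shape:
            raise ValueError(f"{name} mask shape mismatch")
        if not m.any():
            raise ValueError(f"{name} mask is empty")
    deriv = np.zeros_like(trace)
    deriv[1:] = np.diff(trace, axis=0)
    wm = img.data[wm_mask].mean(axis=0)
    csf = img.data[csf_mask].mean(axis=0)
    C = np.column_stack([trace, deriv, wm, csf])
    if not np.all(np.isfinite(C)):
        raise ValueError("confound matrix contains non-finite values")
    return C


def regress_nuisance(ts: VoxelTimeSeries, confounds: np.ndarray) -> VoxelTimeSeries:
    """Least-squares residuals of every voxel on confounds plus intercept.

    Residuals are exactly orthogonal (to numerical precision) to every
    confound column.  Rank-deficient confound matrices are handled via the
    pseudo-inverse with a logged warning.
    """
    C = np.asarray(confounds, dtype=float)
    if C.ndim != 2 or C.shape[0] != ts.n_timepoints:
        raise ValueError("confounds must be (time, regressors) matching the series")
    X = np.column_stack([np.ones(C.shape[0]), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient confound matrix; using pseudo-inverse",
                      stacklevel=2)
        logger.warning("rank-deficient confound matrix (rank %d < %d)",
                       rank, X.shape[1])
    beta = np.linalg.pinv(X) @ ts.values.T
    resid = ts.values - (X @ beta).T
    return ts.with_values(resid)


def bandpass(ts: VoxelTimeSeries, tr_seconds: float, low_hz: float = 0.01,
             high_hz: float = 0.08) -> VoxelTimeSeries:
    """Ideal rectangular DFT band-pass on every voxel time series.

    Frequency bins with ``low_hz <= f <= high_hz`` (and f > 0) are kept,
    all others zeroed, then inverse transformed; the 0 Hz bin is always
    removed so the output is mean-free.
    """
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist:
        raise ValueError(
            f"high_hz {high_hz} exceeds the Nyquist frequency {nyquist:.4g} Hz")
    T = ts.n_timepoints
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    spectrum = np.fft.rfft(ts.values, axis=1)
    spectrum[:, ~keep] = 0.0
    filtered = np.fft.irfft(spectrum, n=T, axis=1)
    return ts.with_values(filtered)
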