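"""Node time series -> Fisher-z connectivity, with motion handling.

Covers the subject-level steps that operate on extracted node time courses:
volume scrubbing by framewise displacement (FD), the three-part motion
exclusion rule, linear detrending / nuisance regression / band-pass
filtering, and the Pearson-correlation + Fisher-z connectome. Image-level
steps (slice timing, realignment, spatial normalization, smoothing) are out
of scope; this module starts where a parcellation's mean time courses end.

All motion-threshold comparisons are strict (``>``): a volume at exactly
FD = 0.5 mm survives scrubbing and a subject at exactly mean FD = 0.15 mm
is kept.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import signal

from .types import (
    ConnectivityMatrix,
    DegenerateInputError,
    InvalidParameterError,
    TimeSeries,
)

logger = logging.getLogger(__name__)

# Correlations are clipped to +/-(1 - FISHER_CLIP_EPS) before arctanh so
# perfect correlations map to a large finite z instead of infinity.
FISHER_CLIP_EPS = 1e-7


def scrub(ts: TimeSeries, fd_threshold: float = 0.5) -> TimeSeries:
    """Delete volumes with FD strictly above ``fd_threshold`` (mm).

    Volume order is preserved. Raises if scrubbing would remove every
    volume.
    """
    if fd_threshold <= 0:
        raise InvalidParameterError("fd_threshold must be positive")
    if ts.fd is None:
        raise InvalidParameterError(f"subject {ts.subject_id}: no FD trace to scrub on")
    keep = ts.fd <= fd_threshold
    if not keep.any():
        raise DegenerateInputError(
            f"subject {ts.subject_id}: scrubbing at FD>{fd_threshold} removes all volumes"
        )
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("subject %s: scrubbed %d/%d volumes (FD>%g mm)",
                    ts.subject_id, n_removed, ts.n_timepoints, fd_threshold)
    return replace(ts, data=ts.data[keep], fd=ts.fd[keep])


def motion_exclude(
    ts: TimeSeries,
    rot_max: float = 2.0,
    trans_max: float = 2.0,
    mean_fd_max: float = 0.15,
) -> bool:
    """Subject-level exclusion: rotation >2 deg, translation >2 mm, or mean FD >0.15 mm.

    Returns True if the subject should be excluded. Mean FD is computed on
    the trace as given (i.e., before scrubbing). All comparisons strict.
    """
    if min(rot_max, trans_max, mean_fd_max) <= 0:
        raise InvalidParameterError("motion thresholds must be positive")
    if ts.rotation_max > rot_max or ts.translation_max > trans_max:
        return True
    if ts.fd is not None and float(np.mean(ts.fd)) > mean_fd_max:
        return True
    return False


def clean(
    ts: TimeSeries,
    nuisance: np.ndarray | None = None,
    band: tuple[float, float] | None = (0.01, 0.1),
    detrend: bool = True,
) -> TimeSeries:
    """Detrend, regress out nuisance signals, band-pass filter each node.

    Order: linear detrend (if flagged) -> least-squares projection onto the
    orthogonal complement of the nuisance columns (an intercept is always
    included) -> zero-phase band-pass (2nd-order Butterworth applied
    forward-backward). Output has the same length as the input.

    ``nuisance`` is a (time x k) regressor matrix; with synthetic node data
    there is no voxelwise global signal, so the mean across nodes is the
    customary stand-in if global-signal regression is wanted.
    """
    data = ts.data.astype(float, copy=True)
    T = data.shape[0]

    if detrend:
        data = signal.detrend(data, axis=0, type="linear")

    if nuisance is not None:
        nuis = np.asarray(nuisance, dtype=float)
        if nuis.ndim == 1:
            nuis = nuis[:, None]
        if nuis.shape[0] != T:
            raise InvalidParameterError(
                f"nuisance matrix has {nuis.shape[0]} rows, expected {T}"
            )
        X = np.column_stack([np.ones(T), nuis])
        beta, *_ = np.linalg.lstsq(X, data, rcond=None)
        data = data - X @ beta

    if band is not None:
        low, high = band
        nyq = 1.0 / (2.0 * ts.tr)
        if not 0.0 <= low < high:
            raise InvalidParameterError(f"need 0 <= low < high, got band={band}")
        if high >= nyq:
            raise InvalidParameterError(
                f"band upper edge {high} Hz is not below Nyquist {nyq} Hz for tr={ts.tr}s"
            )
        if low == 0.0:
            sos = signal.butter(2, high / nyq, btype="lowpass", output="sos")
        else:
            sos = signal.butter(2, [low / nyq, high / nyq], btype="bandpass", output="sos")
        data = signal.sosfiltfilt(sos, data, axis=0)

    return replace(ts, data=data)


def connectivity(ts: TimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of node time courses, Fisher z-transformed.

    ``z[i, j] = arctanh(r[i, j])`` for i != j, with r clipped to
    +/-(1 - 1e-7) first; the diagonal is set to zero. Nodes with zero
    temporal variance produce z = 0 on all their edges (with a logged
    warning) rather than NaN, so the subject stays aligned with the cohort.
    """
    if ts.n_timepoints < 3:
        raise DegenerateInputError(
            f"subject {ts.subject_id}: need >= 3 time points, got {ts.n_timepoints}"
        )
    if ts.n_nodes < 2:
        raise DegenerateInputError("need >= 2 nodes for connectivity")

    data = ts.data
    sd = data.std(axis=0)
    flat = sd == 0
    if flat.any():
        logger.warning(
            "subject %s: %d zero-variance node(s); their edges set to z=0",
            ts.subject_id, int(flat.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip(r, -(1.0 - FISHER_CLIP_EPS), 1.0 - FISHER_CLIP_EPS)
    z = np.arctanh(r)
    if flat.any():
        z[flat, :] = 0.0
        z[:, flat] = 0.0
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # guard against float asymmetry from corrcoef
    return ConnectivityMatrix(subject_id=ts.subject_id, z=z)
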