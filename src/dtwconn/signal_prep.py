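"""Signal conditioning for resting-state BOLD series.

The chain mirrors common resting-state practice: nuisance regression
(head-motion parameters, mean white-matter and CSF signals and their first
five principal components, optionally the global brain signal) strictly
precedes band-pass filtering, and z-normalization comes last.  The band-pass
is a combination of a discrete-cosine-basis high-pass (order 9 by default)
and a bidirectional 12th-order Butterworth low-pass at 0.08 Hz.

All operations accept a 1-D series or a 2-D ``(n_series, n_time)`` array and
act along the last axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "DegenerateInputError",
    "dct_basis",
    "dct_highpass",
    "butter_lowpass",
    "bandpass",
    "nuisance_regress",
    "extract_nuisance",
    "zscore",
    "preprocess",
]


class DegenerateInputError(ValueError):
    """Input is constant (or otherwise degenerate) where variation is required."""


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification.

    highpass_order
        Number of discrete-cosine basis functions regressed out (the constant
        term is extra).  Order 9 over a 600 s run removes fluctuations below
        ~0.0075 Hz.
    lowpass_hz, lowpass_order, bidirectional
        Butterworth low-pass cutoff (Hz), design order, and whether it is
        applied forward-backward (zero phase; the effective magnitude order
        doubles).
    """

    highpass_order: int = 9
    lowpass_hz: float = 0.08
    lowpass_order: int = 12
    bidirectional: bool = True

    def __post_init__(self):
        if self.highpass_order < 1 or self.lowpass_order < 1:
            raise ValueError("filter orders must be >= 1")
        if not self.lowpass_hz > 0:
            raise ValueError("low-pass cutoff must be positive")


def _as_2d(x):
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    if arr.ndim == 2:
        return arr, False
    raise ValueError("expected a 1-D series or a (n_series, n_time) array")


def dct_basis(n: int, order: int) -> np.ndarray:
    """DCT-II basis, shape ``(n, order)``; column k has k half-cycles."""
    t = np.arange(n)
    ks = np.arange(1, order + 1)
    basis = np.sqrt(2.0 / n) * np.cos(
        np.pi * ks[None, :] * (2 * t[:, None] + 1) / (2 * n)
    )
    return basis


def dct_highpass(x, order: int = 9):
    """Residual of regressing the series on a low-order DCT basis + constant.

    Removes slow drifts: with ``order`` basis functions over a run of length
    ``T`` seconds, fluctuations slower than ``order / (2 T)`` Hz are
    suppressed.  The residual has (approximately) zero mean because the
    constant regressor is included.
    """
    arr, was_1d = _as_2d(x)
    n = arr.shape[-1]
    if order >= n:
        raise ValueError(f"DCT order {order} must be < series length {n}")
    X = np.column_stack([np.ones(n), dct_basis(n, order)])
    beta, *_ = np.linalg.lstsq(X, arr.T, rcond=None)
    resid = arr - (X @ beta).T
    return resid[0] if was_1d else resid


def butter_lowpass(x, tr: float, spec: FilterSpec | None = None):
    """Butterworth low-pass along the last axis; zero-phase when bidirectional.

    The filter is designed at ``spec.lowpass_order`` and, when bidirectional,
    applied forward and backward with :func:`scipy.signal.sosfiltfilt`.
    """
    spec = spec or FilterSpec()
    arr, was_1d = _as_2d(x)
    n = arr.shape[-1]
    if n < 3 * spec.lowpass_order:
        raise ValueError(
            f"series length {n} too short for stable order-{spec.lowpass_order} "
            "forward-backward filtering (need >= 3x the order)"
        )
    nyq = 0.5 / tr
    if not spec.lowpass_hz < nyq:
        raise ValueError(f"cutoff {spec.lowpass_hz} Hz must be below Nyquist {nyq} Hz")
    sos = sps.butter(spec.lowpass_order, spec.lowpass_hz, btype="low", fs=1.0 / tr, output="sos")
    if spec.bidirectional:
        out = sps.sosfiltfilt(sos, arr, axis=-1)
    else:
        out = sps.sosfilt(sos, arr, axis=-1)
    return out[0] if was_1d else out


def bandpass(x, tr: float, spec: FilterSpec | None = None):
    """DCT high-pass followed by Butterworth low-pass (0.009–0.08 Hz defaults)."""
    spec = spec or FilterSpec()
    return butter_lowpass(dct_highpass(x, spec.highpass_order), tr, spec)


def _confound_matrix(confounds) -> np.ndarray:
    if isinstance(confounds, pd.DataFrame):
        C = confounds.to_numpy(dtype=float)
    else:
        C = np.asarray(confounds, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    return C


def nuisance_regress(x, confounds):
    """Least-squares residual of the series on confounds plus an intercept.

    ``confounds`` is an ``(n_time, n_confounds)`` array or DataFrame.  The
    residual is orthogonal to every confound column.  A rank-deficient
    confound matrix triggers a warning; the minimum-norm (pseudoinverse)
    solution is used.
    """
    arr, was_1d = _as_2d(x)
    C = _confound_matrix(confounds)
    if C.shape[0] != arr.shape[-1]:
        raise ValueError(
            f"confound length {C.shape[0]} does not match series length {arr.shape[-1]}"
        )
    X = np.column_stack([np.ones(C.shape[0]), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("confound matrix is rank deficient; using pseudoinverse solution")
    beta, *_ = np.linalg.lstsq(X, arr.T, rcond=None)
    resid = arr - (X @ beta).T
    return resid[0] if was_1d else resid


def _principal_components(vox_by_time: np.ndarray, n_pcs: int, label: str) -> list:
    """Temporal PCs of a demeaned voxel-by-time block, by explained variance."""
    if vox_by_time.shape[0] < n_pcs + 1:
        raise ValueError(
            f"{label} mask has {vox_by_time.shape[0]} voxels; need more than "
            f"{n_pcs} for {n_pcs} principal components"
        )
    demeaned = vox_by_time - vox_by_time.mean(axis=1, keepdims=True)
    _, svals, vt = np.linalg.svd(demeaned, full_matrices=False)
    comps = []
    scale = max(svals[0], np.finfo(float).eps)
    for k in range(min(n_pcs, vt.shape[0])):
        if svals[k] / scale < 1e-10:
            warnings.warn(
                f"{label} PCA component {k + 1} carries ~zero variance; dropped"
            )
            break
        comps.append(vt[k])
    return comps


def extract_nuisance(
    data,
    wm_mask,
    csf_mask,
    brain_mask,
    motion=None,
    with_global: bool = False,
    n_pcs: int = 5,
) -> pd.DataFrame:
    """Build the confound table from a 4-D volume and tissue masks.

    Columns: six head-motion parameters (if given), mean WM, mean CSF, the
    first ``n_pcs`` temporal principal components of WM and of CSF voxels,
    and optionally the global (brain-mask mean) signal.  With motion and the
    global signal this totals 6+1+1+5+5+1 = 19 regressors.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("data must be a 4-D (x, y, z, t) array")
    cols: dict[str, np.ndarray] = {}
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.ndim != 2 or motion.shape[1] != 6:
            raise ValueError("motion must be an (n_time, 6) array")
        for k in range(6):
            cols[f"motion_{k + 1}"] = motion[:, k]
    for label, mask in (("wm", wm_mask), ("csf", csf_mask)):
        mask = np.asarray(mask, dtype=bool)
        block = data[mask]  # voxels x time
        if block.shape[0] == 0:
            raise ValueError(f"{label} mask is empty")
        cols[f"{label}_mean"] = block.mean(axis=0)
        for k, comp in enumerate(_principal_components(block, n_pcs, label)):
            cols[f"{label}_pc{k + 1}"] = comp
    if with_global:
        brain = np.asarray(brain_mask, dtype=bool)
        if not brain.any():
            raise ValueError("brain mask is empty")
        cols["global"] = data[brain].mean(axis=0)
    return pd.DataFrame(cols)


def zscore(x):
    """Normalize to mean 0, standard deviation 1 (population, 1/N, convention)."""
    arr, was_1d = _as_2d(x)
    sd = arr.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateInputError("cannot z-score a constant series")
    out = (arr - arr.mean(axis=-1, keepdims=True)) / sd
    return out[0] if was_1d else out


def preprocess(
    series,
    confounds=None,
    tr: float = 2.0,
    spec: FilterSpec | None = None,
    normalize: bool = True,
):
    """Full conditioning chain: nuisance regression, then band-pass, then z-score.

    The order is fixed — confound residuals are band-pass filtered, never the
    reverse — because filtering first would reintroduce confound energy
    outside the band into the regression.
    """
    out = series
    if confounds is not None:
        out = nuisance_regress(out, confounds)
    out = bandpass(out, tr, spec)
    if normalize:
        out = zscore(out)
    return out
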