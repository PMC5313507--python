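"""Whole-brain connectivity products: seed maps and ROI matrices.

A seed map evaluates one metric between a seed voxel's series and every
voxel of an inclusion mask; an ROI connectivity matrix evaluates it between
all pairs of atlas-region mean series.  DTW distances are additionally
converted to similarities (negated, demeaned over the map or matrix) so
their sign convention matches correlation-style group statistics; the raw
distances are retained for reanalysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conn_metrics import compute_metric, to_similarity
from .core_dtw import WarpWindow
from .signal_prep import zscore

__all__ = [
    "ConnectivityMap",
    "ConnectivityMatrix",
    "FeatureVector",
    "seed_map",
    "roi_timeseries",
    "connectivity_matrix",
    "matrix_to_features",
    "features_to_matrix",
    "map_to_nifti",
    "matrix_to_frame",
]


def _resolve_window(w, tr):
    if isinstance(w, WarpWindow):
        return w.samples
    return w


@dataclass(frozen=True)
class ConnectivityMap:
    """Per-voxel metric values of one seed over an inclusion mask.

    ``values`` is ordered like ``np.argwhere(mask)``.  For DTW the values
    are similarities (demeaned negated distances, mean exactly 0 over the
    map) and ``raw_distances`` keeps the untransformed distances.
    """

    seed: tuple
    metric: str
    values: np.ndarray
    mask: np.ndarray
    params: dict = field(default_factory=dict)
    raw_distances: np.ndarray | None = None
    lags_s: np.ndarray | None = None

    def to_volume(self, fill=np.nan) -> np.ndarray:
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = self.values
        return vol


def seed_map(
    data,
    mask,
    seed: tuple,
    metric: str,
    *,
    w=None,
    max_lag=None,
    tr: float = 2.0,
) -> ConnectivityMap:
    """Metric between the seed voxel's series and every mask voxel's series.

    ``data`` is a prepared 4-D array (the conditioning chain is assumed to
    have been applied already).  The seed must lie inside the mask; its own
    map value is the metric's self-value (r = 1, DTW distance 0).
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if data.ndim != 4:
        raise ValueError("data must be 4-D (x, y, z, t)")
    seed = tuple(int(c) for c in seed)
    if not mask[seed]:
        raise ValueError(f"seed {seed} lies outside the inclusion mask")
    seed_series = zscore(data[seed])
    coords = np.argwhere(mask)
    w_samples = _resolve_window(w, tr)
    ml = _resolve_window(max_lag, tr)
    vals = np.empty(coords.shape[0])
    lags = np.zeros(coords.shape[0]) if metric == "xcorr" else None
    for k, (x, y, z) in enumerate(coords):
        series = data[x, y, z]
        mv = compute_metric(metric, seed_series, zscore(series), w=w_samples, max_lag=ml, tr=tr)
        vals[k] = mv.value
        if lags is not None:
            lags[k] = mv.lag_seconds
    params = {"w": w_samples, "max_lag": ml, "tr": tr}
    if metric == "dtw":
        sim = to_similarity(vals, unit="map")
        return ConnectivityMap(
            seed=seed, metric=metric, values=sim.similarities, mask=mask,
            params=params, raw_distances=vals,
        )
    return ConnectivityMap(
        seed=seed, metric=metric, values=vals, mask=mask, params=params, lags_s=lags
    )


def roi_timeseries(data, atlas) -> pd.DataFrame:
    """Mean series per atlas label (ascending label order), z-scored.

    Label 0 is background; empty labels are excluded with a warning.
    """
    data = np.asarray(data, dtype=float)
    atlas = np.asarray(atlas)
    if atlas.shape != data.shape[:3]:
        raise ValueError("atlas grid does not match data grid")
    out = {}
    for label in np.unique(atlas):
        if label == 0:
            continue
        sel = atlas == label
        if not sel.any():  # pragma: no cover - unique() guarantees nonempty
            warnings.warn(f"atlas label {label} has no voxels; excluded")
            continue
        out[int(label)] = zscore(data[sel].mean(axis=0))
    if not out:
        raise ValueError("atlas contains no nonzero labels")
    return pd.DataFrame(out)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric ROI-by-ROI metric matrix; diagonal is the metric self-value."""

    labels: list
    values: np.ndarray
    metric: str
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.labels)


def connectivity_matrix(
    series: pd.DataFrame, metric: str, *, w=None, max_lag=None, tr: float = 2.0
) -> ConnectivityMatrix:
    """Metric over all unordered pairs of columns (computed once per pair)."""
    if series.shape[1] < 2:
        raise ValueError("need at least two series")
    labels = list(series.columns)
    X = series.to_numpy(dtype=float).T  # rois x time
    n = len(labels)
    w_samples = _resolve_window(w, tr)
    ml = _resolve_window(max_lag, tr)
    M = np.zeros((n, n))
    self_value = 1.0 if metric in ("corr", "xcorr") else 0.0
    np.fill_diagonal(M, self_value)
    for i in range(n):
        for j in range(i + 1, n):
            v = compute_metric(metric, X[i], X[j], w=w_samples, max_lag=ml, tr=tr).value
            M[i, j] = M[j, i] = v
    return ConnectivityMatrix(
        labels=labels, values=M, metric=metric,
        params={"w": w_samples, "max_lag": ml, "tr": tr},
    )


@dataclass(frozen=True)
class FeatureVector:
    """Strictly-upper-triangle values, row-major, with their (i, j) label pairs."""

    values: np.ndarray
    pairs: list
    metric: str

    def __len__(self) -> int:
        return self.values.size


def matrix_to_features(m: ConnectivityMatrix, atol: float = 1e-8) -> FeatureVector:
    """Vectorize the strictly-upper triangle (length n(n-1)/2, row-major).

    DTW matrices pass through the distance-to-similarity transform (demeaned
    over the matrix's pairs) before vectorization.
    """
    V = m.values
    if not np.allclose(V, V.T, atol=atol):
        raise ValueError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(m.n, k=1)
    vals = V[iu]
    if m.metric == "dtw":
        vals = to_similarity(vals, unit="matrix").similarities
    pairs = [(m.labels[i], m.labels[j]) for i, j in zip(*iu)]
    return FeatureVector(values=vals, pairs=pairs, metric=m.metric)


def features_to_matrix(fv: FeatureVector, labels=None, diagonal: float = 0.0) -> ConnectivityMatrix:
    """Rebuild the symmetric matrix from an upper-triangle feature vector."""
    d = fv.values.size
    n = int(round((1 + np.sqrt(1 + 8 * d)) / 2))
    if n * (n - 1) // 2 != d:
        raise ValueError(f"feature length {d} is not a triangular number")
    if labels is None:
        labels = sorted({lab for pair in fv.pairs for lab in pair}) if fv.pairs else list(range(n))
    M = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    M[iu] = fv.values
    M = M + M.T
    np.fill_diagonal(M, diagonal)
    return ConnectivityMatrix(labels=list(labels), values=M, metric=fv.metric)


def map_to_nifti(cmap: ConnectivityMap, affine=None):
    """Connectivity map as a 3-D NIfTI image (NaN outside the mask)."""
    import nibabel as nib

    if affine is None:
        affine = np.eye(4)
    return nib.Nifti1Image(cmap.to_volume().astype(np.float32), affine)


def matrix_to_frame(m: ConnectivityMatrix) -> pd.DataFrame:
    return pd.DataFrame(m.values, index=m.labels, columns=m.labels)
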