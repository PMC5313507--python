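"""Connectivity metrics on prepared BOLD series.

Three metrics quantify the coupling of two series: zero-lag Pearson
correlation, maximal-lag cross-correlation (the signed correlation of
largest magnitude over integer lags up to a bound), and the banded DTW
distance.  DTW distances are converted to similarities by negating and
demeaning over an analysis unit (a seed map or a connectivity matrix), so
that unconnected pairs scatter around zero and one-sample t statistics
apply.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_dtw import WarpWindow, dtw_distance
from .signal_prep import DegenerateInputError, zscore

__all__ = [
    "MetricValue",
    "SimilaritySet",
    "METRICS",
    "pearson",
    "max_lag_xcorr",
    "dtw_metric",
    "to_similarity",
    "compute_metric",
]

METRICS = ("corr", "xcorr", "dtw")


@dataclass(frozen=True)
class MetricValue:
    metric: str
    value: float
    lag_seconds: float = 0.0

    def to_tsv_row(self) -> str:
        return f"{self.metric}\t{self.value:.10g}\t{self.lag_seconds:.10g}"


@dataclass(frozen=True)
class SimilaritySet:
    """Negated, demeaned DTW distances over one analysis unit (mean exactly 0)."""

    raw_distances: np.ndarray
    similarities: np.ndarray
    unit: str = "map"


def _values(x) -> np.ndarray:
    from .core_dtw import _as_values

    return _as_values(x)


def _tr_of(x, default: float = 1.0) -> float:
    return getattr(x, "tr", default)


def pearson(x1, x2) -> MetricValue:
    """Zero-lag Pearson correlation coefficient."""
    v1, v2 = _values(x1), _values(x2)
    if v1.size != v2.size:
        raise ValueError("series lengths differ")
    if v1.std() == 0 or v2.std() == 0:
        raise DegenerateInputError("correlation undefined for a constant series")
    r = float(np.corrcoef(v1, v2)[0, 1])
    return MetricValue("corr", r)


def max_lag_xcorr(x1, x2, max_lag, tr: float | None = None) -> MetricValue:
    """Cross-correlation at the lag of maximal magnitude (sign preserved).

    The correlation at each integer lag in ``[-max_lag, +max_lag]`` is
    computed on the truncated overlap (re-normalized per lag, so |r| <= 1
    everywhere); the signed value with the largest |r| is returned together
    with its lag in seconds.  Positive lag means the second series trails the
    first.  Ties prefer smaller |lag|, then positive lag.  Lags whose overlap
    is shorter than 3 samples are skipped with a warning.
    """
    v1, v2 = _values(x1), _values(x2)
    if v1.size != v2.size:
        raise ValueError("series lengths differ")
    n = v1.size
    if tr is None:
        tr = _tr_of(x1)
    if isinstance(max_lag, WarpWindow):
        max_lag = max_lag.samples
    max_lag = int(max_lag)
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the series length")
    best: MetricValue | None = None
    best_abs = -np.inf
    # visiting order encodes the tie-break: |lag| ascending, positive first
    for a in range(0, max_lag + 1):
        for k in ((a,) if a == 0 else (a, -a)):
            if k >= 0:
                s1, s2 = v1[: n - k], v2[k:]
            else:
                s1, s2 = v1[-k:], v2[: n + k]
            if s1.size < 3:
                warnings.warn(f"lag {k}: overlap shorter than 3 samples, skipped")
                continue
            if s1.std() == 0 or s2.std() == 0:
                continue
            r = float(np.corrcoef(s1, s2)[0, 1])
            if abs(r) > best_abs:
                best_abs = abs(r)
                best = MetricValue("xcorr", r, lag_seconds=k * tr)
    if best is None:
        raise DegenerateInputError("no lag produced a defined correlation")
    return best


def dtw_metric(x1, x2, w=None, tr: float | None = None, normalize_by_length=False) -> MetricValue:
    """DTW distance on z-scored inputs (inputs are z-scored here if needed)."""
    v1, v2 = _values(x1), _values(x2)
    for v in (v1, v2):
        if v.std() == 0:
            raise DegenerateInputError("DTW metric undefined for a constant series")
    if not (abs(v1.mean()) < 1e-8 and abs(v1.std() - 1) < 1e-8):
        v1 = zscore(v1)
    if not (abs(v2.mean()) < 1e-8 and abs(v2.std() - 1) < 1e-8):
        v2 = zscore(v2)
    d = dtw_distance(v1, v2, w, normalize_by_length=normalize_by_length)
    return MetricValue("dtw", d)


def to_similarity(distances, unit: str = "map") -> SimilaritySet:
    """Turn DTW distances into zero-mean similarities: ``mean(d) - d_i``.

    The map is order-reversing (smallest distance becomes largest
    similarity) and affine, so under the no-connection null the similarities
    scatter symmetrically around zero.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need at least two distances to demean")
    s = d.mean() - d
    return SimilaritySet(raw_distances=d, similarities=s, unit=unit)


def compute_metric(
    name: str, x1, x2, *, w=None, max_lag=None, tr: float = 1.0
) -> MetricValue:
    """Dispatch a metric by name ('corr' | 'xcorr' | 'dtw') with its parameters."""
    if name == "corr":
        return pearson(x1, x2)
    if name == "xcorr":
        if max_lag is None:
            raise ValueError("xcorr requires max_lag")
        return max_lag_xcorr(x1, x2, max_lag, tr=tr)
    if name == "dtw":
        return dtw_metric(x1, x2, w=w, tr=tr)
    raise ValueError(f"unknown metric {name!r}; expected one of {METRICS}")
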