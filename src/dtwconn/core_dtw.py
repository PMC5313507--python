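"""Banded dynamic time warping: cost matrix, distance, and warping path.

DTW compares two uniformly sampled signals by elastically matching their
samples: sample ``i`` of the first series may be matched to any sample ``j``
of the second with ``|i - j| <= w`` (the Sakoe–Chiba warping window), and the
accumulated cost of the cheapest monotone matching is the squared DTW
distance.  The local cost of matching ``x1(i)`` with ``x2(j)`` is the squared
difference ``(x1(i) - x2(j))**2``; the DTW distance is the square root of the
accumulated cost at the final corner.

In the fMRI setting the window is specified in seconds and converted to
samples with the repetition time (TR); a window of 100 s at TR = 2 s allows
time lags of up to 50 samples between matched points.

Indices in docstrings and in the public path representation are 1-based:
a warping path starts at ``(1, 1)`` and ends at ``(l1, l2)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "TimeSeries",
    "WarpWindow",
    "DtwMatrix",
    "DtwResult",
    "InfeasibleBandError",
    "window_to_samples",
    "dtw_matrix",
    "dtw_distance",
    "warping_path",
    "path_lag_profile",
    "dtw",
]


class InfeasibleBandError(ValueError):
    """The warping band is too narrow to connect (1,1) with (l1,l2)."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values : array-like
        The samples, at least one, all finite.
    tr : float
        Sampling interval (repetition time) in seconds, > 0.
    """

    values: np.ndarray
    tr: float = 1.0

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("TimeSeries requires a nonempty 1-D sample array")
        if not np.all(np.isfinite(vals)):
            raise ValueError("TimeSeries values must be finite")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def length(self) -> int:
        return self.values.size


def _as_values(x) -> np.ndarray:
    if isinstance(x, TimeSeries):
        return x.values
    vals = np.asarray(x, dtype=float)
    if vals.ndim != 1 or vals.size < 1:
        raise ValueError("expected a nonempty 1-D series")
    return vals


def window_to_samples(seconds: float, tr: float) -> int:
    """Convert a warping window (or maximal lag) from seconds to samples.

    Rounds half away from zero, e.g. 100 s at TR 2 s gives 50 samples and
    100 s at TR 1.77 s gives 56 samples (100/1.77 = 56.497).
    """
    if not tr > 0:
        raise ValueError("tr must be positive")
    if seconds < 0:
        raise ValueError("window seconds must be nonnegative")
    return int(np.floor(seconds / tr + 0.5))


@dataclass(frozen=True)
class WarpWindow:
    """Sakoe–Chiba band half-width, in samples (optionally tagged in seconds)."""

    samples: int
    seconds: float | None = None

    def __post_init__(self):
        if self.samples < 0:
            raise ValueError("window samples must be >= 0")

    @classmethod
    def from_seconds(cls, seconds: float, tr: float) -> "WarpWindow":
        return cls(samples=window_to_samples(seconds, tr), seconds=seconds)


def _window_samples(w, l1: int, l2: int) -> int:
    """Resolve a window argument (None = unconstrained) to a sample count."""
    if w is None:
        return max(l1, l2)
    if isinstance(w, WarpWindow):
        w = w.samples
    w = int(w)
    if w < 0:
        raise ValueError("window must be >= 0")
    if w < abs(l1 - l2):
        raise InfeasibleBandError(
            f"band half-width {w} cannot connect series of lengths {l1} and {l2}; "
            f"need w >= |l1 - l2| = {abs(l1 - l2)}"
        )
    return w


@njit(cache=True)
def _accumulate_full(x1, x2, w):  # pragma: no cover - exercised via wrappers
    l1 = x1.size
    l2 = x2.size
    D = np.full((l1, l2), np.inf)
    for i in range(l1):
        jlo = i - w
        if jlo < 0:
            jlo = 0
        jhi = i + w
        if jhi > l2 - 1:
            jhi = l2 - 1
        for j in range(jlo, jhi + 1):
            c = (x1[i] - x2[j]) ** 2
            if i == 0 and j == 0:
                D[i, j] = c
            elif i == 0:
                D[i, j] = c + D[i, j - 1]
            elif j == 0:
                D[i, j] = c + D[i - 1, j]
            else:
                m = D[i - 1, j - 1]
                if D[i - 1, j] < m:
                    m = D[i - 1, j]
                if D[i, j - 1] < m:
                    m = D[i, j - 1]
                D[i, j] = c + m
    return D


@njit(cache=True)
def _banded_corner(x1, x2, w):  # pragma: no cover - exercised via wrappers
    """Accumulated cost at (l1,l2) using two rolling rows (memory ~ 2*l2)."""
    l1 = x1.size
    l2 = x2.size
    prev = np.full(l2, np.inf)
    cur = np.full(l2, np.inf)
    for i in range(l1):
        for j in range(l2):
            cur[j] = np.inf
        jlo = i - w
        if jlo < 0:
            jlo = 0
        jhi = i + w
        if jhi > l2 - 1:
            jhi = l2 - 1
        for j in range(jlo, jhi + 1):
            c = (x1[i] - x2[j]) ** 2
            if i == 0 and j == 0:
                cur[j] = c
            elif i == 0:
                cur[j] = c + cur[j - 1]
            elif j == 0:
                cur[j] = c + prev[j]
            else:
                m = prev[j - 1]
                if prev[j] < m:
                    m = prev[j]
                if j > jlo and cur[j - 1] < m:
                    m = cur[j - 1]
                cur[j] = c + m
        tmp = prev
        prev = cur
        cur = tmp
    return prev[l2 - 1]


@dataclass(frozen=True)
class DtwMatrix:
    """Accumulated-cost matrix; entries outside the band are ``+inf``."""

    entries: np.ndarray
    band: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    @property
    def corner(self) -> float:
        return float(self.entries[-1, -1])


@dataclass(frozen=True)
class DtwResult:
    """DTW distance with its optimal warping path (1-based index pairs)."""

    distance: float
    path: list = field(default_factory=list)
    band: int = 0
    matrix: DtwMatrix | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "distance": self.distance,
                "band": self.band,
                "path": [[int(i), int(j)] for i, j in self.path],
            }
        )


def dtw_matrix(x1, x2, w=None) -> DtwMatrix:
    """Fill the accumulated-cost matrix within the Sakoe–Chiba band.

    ``w`` may be ``None`` (no constraint), an integer sample count, or a
    :class:`WarpWindow`.  Entries more than ``w`` positions from the diagonal
    are left at ``+inf``.
    """
    v1, v2 = _as_values(x1), _as_values(x2)
    ws = _window_samples(w, v1.size, v2.size)
    return DtwMatrix(entries=_accumulate_full(v1, v2, ws), band=ws)


def dtw_distance(x1, x2, w=None, normalize_by_length: bool = False) -> float:
    """Banded DTW distance: square root of the accumulated cost at (l1,l2).

    With ``normalize_by_length`` the distance is divided by the number of
    time points (``max(l1, l2)``), which makes values comparable across
    recordings of different length.
    """
    v1, v2 = _as_values(x1), _as_values(x2)
    ws = _window_samples(w, v1.size, v2.size)
    d = float(np.sqrt(_banded_corner(v1, v2, ws)))
    if normalize_by_length:
        d /= max(v1.size, v2.size)
    return d


def warping_path(m: DtwMatrix) -> list[tuple[int, int]]:
    """Backtrack the optimal warping path from the accumulated-cost matrix.

    Starting at the final corner, repeatedly steps to the predecessor with
    the smallest accumulated cost; ties are broken deterministically in the
    order diagonal, vertical (i-1, j), horizontal (i, j-1).  The path is
    returned in forward order as 1-based ``(i, j)`` pairs.
    """
    D = m.entries
    l1, l2 = D.shape
    if not np.isfinite(D[-1, -1]):
        raise InfeasibleBandError("matrix corner is unreachable within the band")
    i, j = l1 - 1, l2 - 1
    rev = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, vert, horiz = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
            best = min(diag, vert, horiz)
            if diag == best:
                i, j = i - 1, j - 1
            elif vert == best:
                i -= 1
            else:
                j -= 1
        rev.append((i, j))
    return [(i + 1, j + 1) for i, j in reversed(rev)]


def path_lag_profile(path, tr: float = 1.0) -> np.ndarray:
    """Per-step time lag ``(i - j) * tr`` along a warping path, in seconds.

    A diagnostic: the deviation of the path from the main diagonal measures
    the instantaneous delay between the matched series.
    """
    if not path:
        raise ValueError("empty path")
    arr = np.asarray(path, dtype=float)
    return (arr[:, 0] - arr[:, 1]) * tr


def dtw(x1, x2, w=None, keep_matrix: bool = False) -> DtwResult:
    """Convenience wrapper: distance plus warping path (plus matrix if asked)."""
    v1, v2 = _as_values(x1), _as_values(x2)
    m = dtw_matrix(v1, v2, w)
    path = warping_path(m)
    dist = float(np.sqrt(m.corner))
    return DtwResult(
        distance=dist, path=path, band=m.band, matrix=m if keep_matrix else None
    )
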