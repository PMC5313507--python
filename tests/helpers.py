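"""Independent oracles shared by the test modules."""

import numpy as np


def brute_force_dtw(x1, x2, w=None) -> float:
    """Minimum alignment cost by explicit enumeration of monotone paths.

    Walks every monotone path from (0, 0) to (l1-1, l2-1) (steps: down,
    right, diagonal), optionally restricted to |i - j| <= w, and returns the
    square root of the smallest summed squared difference.  Exponential in
    the series length; intended for series of length <= 8.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    l1, l2 = x1.size, x2.size
    best = [np.inf]

    def dfs(i, j, cost):
        if w is not None and abs(i - j) > w:
            return
        cost += (x1[i] - x2[j]) ** 2
        if cost >= best[0]:
            return
        if i == l1 - 1 and j == l2 - 1:
            best[0] = cost
            return
        if i < l1 - 1 and j < l2 - 1:
            dfs(i + 1, j + 1, cost)
        if i < l1 - 1:
            dfs(i + 1, j, cost)
        if j < l2 - 1:
            dfs(i, j + 1, cost)

    dfs(0, 0, 0.0)
    return float(np.sqrt(best[0]))


def bh_stepup(pvals, q) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask, written out longhand."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    sorted_p = p[order]
    below = sorted_p <= q * (np.arange(1, m + 1) / m)
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        mask[order[: k + 1]] = True
    return mask
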