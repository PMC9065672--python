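"""Jenks natural-breaks classification (Fisher's optimal 1-D partition).

Used to bin farm-to-village distances into close / medium / remote classes.
Implemented as the standard O(k n^2) dynamic program over sorted values,
which is exact: it minimizes the total within-class sum of squared
deviations over all partitions of the sorted data into k contiguous classes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["jenks_breaks", "classify_by_breaks"]


def jenks_breaks(values, k: int) -> list[float]:
    """Optimal k-class natural breaks.

    Parameters
    ----------
    values
        1-D data (any iterable of reals).
    k
        Number of classes, ``1 <= k <= number of distinct values``.

    Returns
    -------
    list of float
        The ``k - 1`` break points; break ``i`` is the largest value of
        class ``i``.  Values ``v <= break[0]`` fall in class 0, etc.
    """
    data = np.sort(np.asarray(list(values), dtype=float))
    n = data.size
    if k < 1:
        raise ValueError("k must be >= 1")
    distinct = np.unique(data).size
    if k > distinct:
        raise ValueError(
            f"cannot split {distinct} distinct value(s) into {k} classes"
        )
    if k == 1:
        return []

    # Prefix sums for O(1) within-class SSE of data[i:j].
    csum = np.concatenate([[0.0], np.cumsum(data)])
    csq = np.concatenate([[0.0], np.cumsum(data**2)])

    def sse(i: int, j: int) -> float:
        # Sum of squared deviations of data[i:j] (j exclusive).
        m = j - i
        s = csum[j] - csum[i]
        return float(csq[j] - csq[i] - s * s / m)

    INF = float("inf")
    # cost[c][j]: best total SSE splitting data[:j] into c+1 classes.
    cost = np.full((k, n + 1), INF)
    cut = np.zeros((k, n + 1), dtype=int)
    for j in range(1, n + 1):
        cost[0][j] = sse(0, j)
    for c in range(1, k):
        for j in range(c + 1, n + 1):
            best, arg = INF, c
            for i in range(c, j):
                v = cost[c - 1][i] + sse(i, j)
                # Strict < keeps the earliest feasible cut on ties, which
                # favours putting tied values in the lower class.
                if v < best:
                    best, arg = v, i
            cost[c][j], cut[c][j] = best, arg

    # Recover class boundaries.
    bounds = []
    j = n
    for c in range(k - 1, 0, -1):
        i = cut[c][j]
        bounds.append(i)
        j = i
    bounds.reverse()
    return [float(data[i - 1]) for i in bounds]


def classify_by_breaks(values, breaks) -> np.ndarray:
    """Class index (0-based) of each value given ascending break points."""
    arr = np.asarray(list(values), dtype=float)
    return np.searchsorted(np.asarray(breaks, dtype=float), arr, side="left")
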