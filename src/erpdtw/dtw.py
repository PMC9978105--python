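"""Classic dynamic time warping distances.

A series is a real matrix of shape ``(p, n)`` — ``p`` feature dimensions by
``n`` time points.  1-D arrays are accepted and treated as ``p = 1``.  The
distance is the standard three-neighbour recurrence

    r[i, j] = delta[i, j] + min(r[i, j-1], r[i-1, j], r[i-1, j-1])

over a pairwise cost matrix ``delta`` (squared Euclidean by default, plain
Euclidean selectable).  Epoch-level distance sums independent univariate DTW
distances channel by channel, which is how trial similarity is measured when
building the per-subject distance matrices for SSE averaging.
"""

from __future__ import annotations

import numpy as np
from numba import njit

METRICS = ("sqeuclidean", "euclidean")

_METRIC_CODE = {"sqeuclidean": 0, "euclidean": 1}


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[np.newaxis, :]
    if x.ndim != 2:
        raise ValueError(f"series must be 1-D or 2-D, got shape {x.shape}")
    if x.shape[1] < 1:
        raise ValueError("series must have length >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def _check_pair(x, y):
    x, y = _as_series(x), _as_series(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"series dimension mismatch: x has shape {x.shape}, y has shape {y.shape}"
        )
    return x, y


def _check_metric(metric: str) -> str:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return metric


def pairwise_cost(x, y, metric: str = "sqeuclidean") -> np.ndarray:
    """Cost matrix ``delta[i, j] = d(x_i, y_j)`` of shape ``(n, m)``."""
    x, y = _check_pair(x, y)
    _check_metric(metric)
    diff = x[:, :, None] - y[:, None, :]          # (p, n, m)
    delta = np.einsum("pnm,pnm->nm", diff, diff)
    if metric == "euclidean":
        delta = np.sqrt(delta)
    return delta


@njit(cache=True)
def _dtw_table(delta):
    n, m = delta.shape
    r = np.full((n + 1, m + 1), np.inf)
    r[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = r[i][j - 1]
            if r[i - 1][j] < best:
                best = r[i - 1][j]
            if r[i - 1][j - 1] < best:
                best = r[i - 1][j - 1]
            r[i, j] = delta[i - 1, j - 1] + best
    return r


def alignment_table(x, y, metric: str = "sqeuclidean") -> np.ndarray:
    """Padded ``(n+1, m+1)`` cumulative-cost table of the hard recurrence.

    Row/column 0 is the +inf boundary (with ``r[0, 0] = 0``), so
    ``r[1, 1] == delta[0, 0]`` and ``r[n, m]`` is the DTW distance.
    """
    return _dtw_table(pairwise_cost(x, y, metric))


def dtw_distance(x, y, metric: str = "sqeuclidean") -> float:
    """Classic DTW distance between two series (any lengths, same dimension)."""
    return float(alignment_table(x, y, metric)[-1, -1])


def dtw_path(x, y, metric: str = "sqeuclidean") -> list[tuple[int, int]]:
    """One optimal alignment path as 0-based ``(i, j)`` pairs, by backtracking.

    Ties prefer the diagonal, then the vertical predecessor.
    """
    r = alignment_table(x, y, metric)
    i, j = r.shape[0] - 1, r.shape[1] - 1
    path = [(i - 1, j - 1)]
    while (i, j) != (1, 1):
        cands = [(r[i - 1, j - 1], i - 1, j - 1),
                 (r[i - 1, j], i - 1, j),
                 (r[i, j - 1], i, j - 1)]
        _, i, j = min(cands, key=lambda t: t[0])
        path.append((i - 1, j - 1))
    return path[::-1]


@njit(cache=True)
def _epoch_dtw_sum(a, b, metric_code):
    # a, b: (n_samples, n_channels); per-channel univariate DTW, summed.
    t, c = a.shape
    tb = b.shape[0]
    total = 0.0
    r = np.empty((t + 1, tb + 1))
    for ch in range(c):
        r[:, :] = np.inf
        r[0, 0] = 0.0
        for i in range(1, t + 1):
            ai = a[i - 1, ch]
            for j in range(1, tb + 1):
                d = ai - b[j - 1, ch]
                d = d * d
                if metric_code == 1:
                    d = np.sqrt(d)
                best = r[i][j - 1]
                if r[i - 1][j] < best:
                    best = r[i - 1][j]
                if r[i - 1][j - 1] < best:
                    best = r[i - 1][j - 1]
                r[i, j] = d + best
        total += r[t, tb]
    return total


def epoch_distance(a, b, metric: str = "sqeuclidean") -> float:
    """Summed per-channel DTW distance between two epochs.

    ``a`` and ``b`` are ``(n_samples, n_channels)`` trial matrices; each
    channel column is treated as an independent univariate series.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("epochs must be 2-D (n_samples, n_channels)")
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"channel-count mismatch: {a.shape} vs {b.shape}"
        )
    _check_metric(metric)
    return float(_epoch_dtw_sum(a, b, _METRIC_CODE[metric]))
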