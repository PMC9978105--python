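"""Differentiable Soft-DTW: forward value, alignment table and exact gradient.

Soft-DTW replaces the hard minimum of the DTW recurrence with the smoothed
soft minimum

    softmin_gamma(a) = -gamma * log(sum_i exp(-a_i / gamma)),   gamma > 0,

which makes the resulting discrepancy ``dtw_gamma(x, y)`` differentiable in
``x``.  The gradient is obtained by a reverse dynamic program over the matrix
``E`` with ``e[i, j] = d r[n, m] / d r[i, j]``: starting from
``e[n, m] = 1``, each entry combines its three successors with exponential
weights ``exp((r_succ - r[i, j] - delta_succ) / gamma)``, and the chain rule
through the cost matrix gives ``grad_x``.  Everything is evaluated in
stabilised log-space; for ``gamma = 0`` the forward pass reduces exactly to
classic DTW and the backward pass refuses to run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .dtw import _check_metric, _check_pair, _METRIC_CODE, pairwise_cost


def soft_min(values, gamma: float) -> float:
    """Soft minimum of a list of reals; exact minimum when ``gamma == 0``."""
    a = np.asarray(values, dtype=np.float64)
    if a.size == 0:
        raise ValueError("soft_min of an empty collection")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    lo = float(np.min(a))
    if gamma == 0:
        return lo
    return lo - gamma * float(np.log(np.sum(np.exp(-(a - lo) / gamma))))


@njit(cache=True)
def _soft_table(delta, gamma):
    n, m = delta.shape
    r = np.full((n + 1, m + 1), np.inf)
    r[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            a = r[i, j - 1]
            b = r[i - 1, j]
            c = r[i - 1, j - 1]
            lo = a
            if b < lo:
                lo = b
            if c < lo:
                lo = c
            if gamma == 0.0:
                sm = lo
            else:
                sm = lo - gamma * np.log(
                    np.exp(-(a - lo) / gamma)
                    + np.exp(-(b - lo) / gamma)
                    + np.exp(-(c - lo) / gamma)
                )
            r[i, j] = delta[i - 1, j - 1] + sm
    return r


@njit(cache=True)
def _soft_e_matrix(delta, r, gamma):
    n, m = delta.shape
    d = np.zeros((n + 2, m + 2))
    d[1:n + 1, 1:m + 1] = delta
    big = np.full((n + 2, m + 2), -np.inf)
    big[1:n + 1, 1:m + 1] = r[1:, 1:]
    big[n + 1, m + 1] = r[n, m]
    e = np.zeros((n + 2, m + 2))
    e[n + 1, m + 1] = 1.0
    for j in range(m, 0, -1):
        for i in range(n, 0, -1):
            wa = np.exp((big[i + 1, j] - big[i, j] - d[i + 1, j]) / gamma)
            wb = np.exp((big[i, j + 1] - big[i, j] - d[i, j + 1]) / gamma)
            wc = np.exp((big[i + 1, j + 1] - big[i, j] - d[i + 1, j + 1]) / gamma)
            e[i, j] = e[i + 1, j] * wa + e[i, j + 1] * wb + e[i + 1, j + 1] * wc
    return e[1:n + 1, 1:m + 1]


@njit(cache=True)
def _val_grad_1d(x, y, gamma, metric_code):
    # Fused univariate value+gradient: cost matrix, forward table, reverse
    # E-matrix and chain rule in one jitted call (the SSE hot path).
    n, m = x.shape[0], y.shape[0]
    delta = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            d = x[i] - y[j]
            d = d * d
            if metric_code == 1:
                d = np.sqrt(d)
            delta[i, j] = d
    r = _soft_table(delta, gamma)
    e = _soft_e_matrix(delta, r, gamma)
    grad = np.zeros(n)
    if metric_code == 0:
        for i in range(n):
            s = 0.0
            g = 0.0
            for j in range(m):
                s += e[i, j]
                g += e[i, j] * y[j]
            grad[i] = 2.0 * (x[i] * s - g)
    else:
        for i in range(n):
            g = 0.0
            for j in range(m):
                if delta[i, j] > 0:
                    g += e[i, j] * (x[i] - y[j]) / delta[i, j]
            grad[i] = g
    return r[n, m], grad


@njit(cache=True)
def _bary_val_grad_1d(x, ys, weights, gamma, metric_code):
    # Weighted length-normalised objective over a stack of equal-length
    # univariate target series ys of shape (N, m).
    val = 0.0
    grad = np.zeros(x.shape[0])
    m = ys.shape[1]
    for i in range(ys.shape[0]):
        v, g = _val_grad_1d(x, ys[i], gamma, metric_code)
        c = weights[i] / m
        val += c * v
        grad += c * g
    return val, grad


def soft_dtw_forward(x, y, gamma: float = 1.0, metric: str = "sqeuclidean"):
    """Soft-DTW value and its padded alignment table.

    Returns ``(value, table)`` where ``table`` is the ``(n+1, m+1)``
    cumulative soft-cost matrix and ``value == table[n, m]``.  At
    ``gamma == 0`` this is bit-for-bit the classic DTW table.
    """
    x, y = _check_pair(x, y)
    _check_metric(metric)
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    delta = pairwise_cost(x, y, metric)
    r = _soft_table(delta, float(gamma))
    return float(r[-1, -1]), r


def soft_dtw(x, y, gamma: float = 1.0, metric: str = "sqeuclidean") -> float:
    """Soft-DTW discrepancy ``dtw_gamma(x, y)`` (value only)."""
    return soft_dtw_forward(x, y, gamma, metric)[0]


def soft_dtw_backward(x, y, gamma: float, table: np.ndarray,
                      metric: str = "sqeuclidean"):
    """E-matrix and gradient of ``dtw_gamma`` with respect to ``x``.

    ``table`` must be the alignment table produced by :func:`soft_dtw_forward`
    on the same ``(x, y, gamma, metric)``.  Returns ``(e, grad_x)`` with
    ``e`` of shape ``(n, m)`` (``e[-1, -1] == 1``) and ``grad_x`` of the
    shape of ``x`` as a ``(p, n)`` matrix.
    """
    x, y = _check_pair(x, y)
    _check_metric(metric)
    if gamma <= 0:
        raise ValueError("soft_dtw_backward requires gamma > 0")
    delta = pairwise_cost(x, y, metric)
    e = _soft_e_matrix(delta, table, float(gamma))
    if metric == "sqeuclidean":
        # d delta[i,j] / d x[:, i] = 2 (x_i - y_j)
        grad = 2.0 * (x * e.sum(axis=1)[None, :] - y @ e.T)
    else:
        diff = x[:, :, None] - y[:, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            unit = np.where(delta > 0, diff / delta[None, :, :], 0.0)
        grad = np.einsum("pnm,nm->pn", unit, e)
    return e, grad


def soft_dtw_value_and_grad(x, y, gamma: float = 1.0,
                            metric: str = "sqeuclidean"):
    """Convenience pair ``(value, grad_x)`` for optimisers."""
    value, table = soft_dtw_forward(x, y, gamma, metric)
    _, grad = soft_dtw_backward(x, y, gamma, table, metric)
    return value, grad
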