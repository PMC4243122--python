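"""JIT-compiled inner loops of the majorize-minimize block solver.

Kept free of any package types: plain arrays in, plain arrays out.  The
design is consumed transposed (features x observations) so that the hot
loops over observations run over contiguous memory.  The squared-error loss
is the delta = +inf limit of the Huber loss, so a single kernel serves both
objectives.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["solve_kernel", "path_kernel"]


@njit(cache=True)
def _huber_grad_scalar(theta: float, delta: float) -> float:
    if theta > delta:
        return 2.0 * delta
    if theta < -delta:
        return -2.0 * delta
    return 2.0 * theta


@njit(cache=True)
def _huber_loss_scalar(theta: float, delta: float) -> float:
    a = abs(theta)
    if a <= delta:
        return theta * theta
    return 2.0 * delta * a - delta * delta


@njit(cache=True)
def _objective(r, w, b, p, m, lam, delta) -> float:
    val = 0.0
    for j in range(r.shape[0]):
        val += w[j] * _huber_loss_scalar(r[j], delta)
    for l in range(p):
        s = 0.0
        for c in range(m):
            s += b[l * m + c] * b[l * m + c]
        val += lam * np.sqrt(s)
    return val


@njit(cache=True, fastmath=True)
def _cycle(XT, w, b, r, h, p, m, lam, delta, gammas):
    """One full pass of block updates; returns the max coefficient change.

    XT is the (p*m) x n transposed design; r the current residual vector,
    updated in place along with b; h is scratch of length n; gammas holds
    one majorizer curvature per block.
    """
    n = r.shape[0]
    max_change = 0.0
    v = np.empty(m)
    for l in range(p):
        base = l * m
        gamma = gammas[l]
        for j in range(n):
            h[j] = w[j] * _huber_grad_scalar(r[j], delta)
        vnorm = 0.0
        for c in range(m):
            acc = 4.0 * gamma * b[base + c]
            row = XT[base + c]
            for j in range(n):
                acc += h[j] * row[j]
            v[c] = acc
            vnorm += acc * acc
        vnorm = np.sqrt(vnorm)
        if vnorm <= lam or vnorm == 0.0:
            scale = 0.0
        else:
            scale = (1.0 - lam / vnorm) / (4.0 * gamma)
        for c in range(m):
            new = scale * v[c]
            diff = new - b[base + c]
            if diff != 0.0:
                row = XT[base + c]
                for j in range(n):
                    r[j] -= diff * row[j]
                b[base + c] = new
            if abs(diff) > max_change:
                max_change = abs(diff)
    return max_change


@njit(cache=True)
def solve_kernel(XT, y, w, p, m, lam, delta, gammas, tol, max_iter, b0, track):
    """Cyclic block-coordinate MM descent from b0 at a single penalty.

    Returns (b, n_iter, converged, objective_history) where the history has
    n_iter + 1 entries (initial value included) when track is True, else 0.
    """
    n = y.shape[0]
    b = b0.copy()
    r = y - XT.T @ b
    h = np.empty(n)
    if track:
        hist = np.empty(max_iter + 1)
        hist[0] = _objective(r, w, b, p, m, lam, delta)
    else:
        hist = np.empty(0)
    n_iter = 0
    converged = False
    for it in range(max_iter):
        max_change = _cycle(XT, w, b, r, h, p, m, lam, delta, gammas)
        n_iter = it + 1
        if track:
            hist[n_iter] = _objective(r, w, b, p, m, lam, delta)
        if max_change < tol:
            converged = True
            break
    if track:
        hist = hist[: n_iter + 1]
    return b, n_iter, converged, hist


@njit(cache=True)
def path_kernel(XT, y, w, p, m, lambdas, delta, gammas, tol, max_iter):
    """Warm-started solves along a decreasing penalty grid."""
    L = lambdas.shape[0]
    d = p * m
    B = np.zeros((L, d))
    iters = np.zeros(L, dtype=np.int64)
    conv = np.zeros(L, dtype=np.bool_)
    b = np.zeros(d)
    for i in range(L):
        b, n_iter, ok, _ = solve_kernel(
            XT, y, w, p, m, lambdas[i], delta, gammas, tol, max_iter, b, False
        )
        B[i] = b
        iters[i] = n_iter
        conv[i] = ok
    return B, iters, conv
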