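"""Brute-force vertex enumeration for small envelopment programs.

An independent check on the LP-solver path: the envelopment program is a
linear program over {z >= 0 : A z = b}, so its optimum is attained at a
basic feasible solution.  For tiny panels we can enumerate every square
subsystem (choose as many candidate-nonzero variables as there are
equality rows), solve it directly, keep the feasible ones, and take the
minimum radial factor.  No simplex, no interior point — just linear
solves — so it shares nothing with the production path beyond numpy.

Only intended for n <= ~6 DMUs with m, s <= ~3; the combinatorics explode
beyond that.
"""

from __future__ import annotations

import itertools

import numpy as np

from .exceptions import SolverError


def brute_force_theta(X: np.ndarray, Y: np.ndarray, o: int, model: str = "ccr") -> float:
    """Minimal radial contraction theta for DMU ``o`` by vertex enumeration.

    Builds the equality system of the input-oriented envelopment program
    (variables theta, lambda, S-, S+) and enumerates all basic solutions.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    n, m = X.shape
    s = Y.shape[1]
    n_eq = m + s + (1 if model == "bcc" else 0)
    nv = 1 + n + m + s

    A = np.zeros((n_eq, nv))
    b = np.zeros(n_eq)
    A[:m, 0] = -X[o]
    A[:m, 1 : 1 + n] = X.T
    A[:m, 1 + n : 1 + n + m] = np.eye(m)
    A[m : m + s, 1 : 1 + n] = Y.T
    A[m : m + s, 1 + n + m :] = -np.eye(s)
    b[m : m + s] = Y[o]
    if model == "bcc":
        A[-1, 1 : 1 + n] = 1.0
        b[-1] = 1.0

    best = np.inf
    for basis in itertools.combinations(range(nv), n_eq):
        sub = A[:, basis]
        if np.linalg.matrix_rank(sub) < n_eq:
            continue
        z, *_ = np.linalg.lstsq(sub, b, rcond=None)
        if np.max(np.abs(sub @ z - b)) > 1e-8:
            continue
        if np.min(z) < -1e-9:
            continue
        theta = z[list(basis).index(0)] if 0 in basis else 0.0
        # theta = 0 with positive outputs is infeasible for positive data;
        # it only appears when theta is non-basic, which cannot satisfy
        # the input rows -- guard anyway.
        full = np.zeros(nv)
        full[list(basis)] = z
        if np.max(np.abs(A @ full - b)) > 1e-8:
            continue
        if theta < best:
            best = float(theta)
    if not np.isfinite(best):
        raise SolverError("vertex enumeration found no feasible basic solution")
    return best
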