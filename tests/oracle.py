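"""Independent brute-force solver for small penalized least-squares problems.

Solves  (1/2n)||yc - X b||^2 + lam * (f ||b||_1 + (1-f)/2 ||b||_2^2)
by enumerating all 3^p sign patterns, solving each sign-restricted
(ridge-adjusted) normal-equation system, keeping the sign-consistent
candidates that satisfy the inactive-coordinate KKT bound, and returning the
lowest-objective solution.  Completely independent of the coordinate-descent
path the package uses.
"""

import itertools

import numpy as np


def objective(X, yc, b, lam, f):
    n = X.shape[0]
    resid = yc - X @ b
    return (resid @ resid) / (2 * n) + lam * (
        f * np.abs(b).sum() + (1 - f) / 2 * (b @ b)
    )


def kkt_violation(X, yc, b, lam, f):
    """Max violation of the subgradient optimality conditions at b."""
    n = X.shape[0]
    grad = -X.T @ (yc - X @ b) / n + lam * (1 - f) * b
    viol = 0.0
    for j in range(X.shape[1]):
        if b[j] != 0:
            viol = max(viol, abs(grad[j] + lam * f * np.sign(b[j])))
        else:
            viol = max(viol, max(0.0, abs(grad[j]) - lam * f))
    return viol


def brute_force_enet(X, y, lam, f=1.0, tol=1e-9):
    """Exact minimizer by sign-pattern enumeration (p <= ~6)."""
    X = np.asarray(X, dtype=float)
    yc = np.asarray(y, dtype=float)
    yc = yc - yc.mean()
    n, p = X.shape
    best_b, best_obj = np.zeros(p), objective(X, yc, np.zeros(p), lam, f)
    for signs in itertools.product((-1, 0, 1), repeat=p):
        s = np.array(signs, dtype=float)
        active = np.flatnonzero(s)
        if active.size == 0:
            continue
        XA = X[:, active]
        A = XA.T @ XA / n + lam * (1 - f) * np.eye(active.size)
        rhs = XA.T @ yc / n - lam * f * s[active]
        try:
            bA = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            continue
        if np.any(bA * s[active] <= 0):
            continue
        b = np.zeros(p)
        b[active] = bA
        if kkt_violation(X, yc, b, lam, f) > tol:
            continue
        obj = objective(X, yc, b, lam, f)
        if obj < best_obj - 1e-15:
            best_b, best_obj = b, obj
    return best_b
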