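"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths (and sklearn): statistics
are definition-level Python loops, and the soft-margin SVM dual is solved by
exhaustive KKT active-set enumeration, which is exact for tiny instances.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- statistics

def loop_mean(xs):
    return sum(xs) / len(xs)


def loop_rms(xs):
    return math.sqrt(sum(x * x for x in xs) / len(xs))


def loop_variance(xs):
    m = loop_mean(xs)
    return sum((x - m) ** 2 for x in xs) / len(xs)


def loop_std(xs):
    return math.sqrt(loop_variance(xs))


def loop_skewness(xs):
    m = loop_mean(xs)
    m2 = sum((x - m) ** 2 for x in xs) / len(xs)
    if m2 == 0:
        return 0.0
    m3 = sum((x - m) ** 3 for x in xs) / len(xs)
    return m3 / m2**1.5


def loop_quantile(xs, q):
    """Linear-interpolation quantile, computed from first principles."""
    s = sorted(xs)
    pos = q * (len(s) - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def loop_iqr(xs):
    return loop_quantile(xs, 0.75) - loop_quantile(xs, 0.25)


# ------------------------------------------------------------------ SVM dual

def svm_dual_oracle(X, y, C=1.0, tol=1e-8):
    """Exact soft-margin linear-SVM dual solution for tiny problems.

    Enumerates every assignment of training points to the three KKT groups
    (alpha = 0, alpha = C, 0 < alpha < C), solves the resulting linear
    system for the free multipliers and the offset b, keeps feasible
    solutions and returns the one with the largest dual objective.

    Parameters: X (n, d), y in {-1, +1}, penalty C.
    Returns (alpha, b, w) with w the primal weight vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    K = X @ X.T
    best = None

    for assignment in itertools.product((0, 1, 2), repeat=n):
        free = [k for k, a in enumerate(assignment) if a == 2]
        upper = [k for k, a in enumerate(assignment) if a == 1]
        zero = [k for k, a in enumerate(assignment) if a == 0]
        if not free:
            continue  # generic optima have at least one free support vector

        # unknowns: alpha_free, b
        m = len(free)
        A = np.zeros((m + 1, m + 1))
        rhs = np.zeros(m + 1)
        for r, k in enumerate(free):
            for c, j in enumerate(free):
                A[r, c] = y[j] * K[k, j]
            A[r, m] = 1.0
            rhs[r] = y[k] - sum(C * y[j] * K[k, j] for j in upper)
        for c, j in enumerate(free):
            A[m, c] = y[j]
        rhs[m] = -sum(C * y[j] for j in upper)

        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        if not np.all(np.isfinite(sol)) or np.linalg.norm(A @ sol - rhs) > 1e-7:
            continue
        alpha_free, b = sol[:m], sol[m]
        # strictly interior: solutions with alpha at a bound are covered by
        # the assignments that place the point in the 0 / C group, and
        # admitting them here would fabricate a "free" b where the true
        # offset is only interval-determined
        if np.any(alpha_free < tol) or np.any(alpha_free > C - tol):
            continue

        alpha = np.zeros(n)
        alpha[free] = np.clip(alpha_free, 0.0, C)
        alpha[upper] = C
        f = (alpha * y) @ K + b
        if any(y[k] * f[k] < 1 - 1e-6 for k in zero):
            continue
        if any(y[k] * f[k] > 1 + 1e-6 for k in upper):
            continue

        obj = alpha.sum() - 0.5 * (alpha * y) @ K @ (alpha * y)
        if best is None or obj > best[0]:
            best = (obj, alpha, float(b))

    if best is None:
        raise RuntimeError("no feasible KKT assignment found (degenerate instance)")
    _, alpha, b = best
    w = (alpha * y) @ X
    return alpha, b, w
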