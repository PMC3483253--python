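"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: the PLS oracle is a plain
NIPALS PLS2 loop written from the textbook definition, and the stability
oracle assesses oscillation of the Goodwin demo chain by linearising the
vector field at its fixed point.
"""

import numpy as np
from scipy.optimize import brentq


def nipals_pls2(X: np.ndarray, Y: np.ndarray, A: int):
    """Textbook NIPALS PLS2: returns (T, W, P, C) with X-deflation by the
    loading p_a = X't_a/t_a't_a and Y-deflation by c_a = Y't_a/t_a't_a.

    Initial u is the Y column with the largest sum of squares; weight
    iteration runs to convergence of t.
    """
    X, Y = X.copy(), Y.copy()
    n = X.shape[0]
    T = np.empty((n, A)); W = np.empty((X.shape[1], A))
    P = np.empty((X.shape[1], A)); C = np.empty((Y.shape[1], A))
    for a in range(A):
        u = Y[:, np.argmax((Y ** 2).sum(axis=0))]
        t = np.zeros(n)
        for _ in range(500):
            w = X.T @ u
            w /= np.linalg.norm(w)
            t_new = X @ w
            q = Y.T @ t_new
            q /= np.linalg.norm(q)
            u = Y @ q
            if np.linalg.norm(t_new - t) <= 1e-10 * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        p = X.T @ t / (t @ t)
        c = Y.T @ t / (t @ t)
        X -= np.outer(t, p)
        Y -= np.outer(t, c)
        T[:, a], W[:, a], P[:, a], C[:, a] = t, w, p, c
    return T, W, P, C


def goodwin_oscillates(v: float = 1.0, d: float = 0.1, h: float = 10.0) -> bool:
    """Linear-stability oracle for the symmetric 3-stage Goodwin loop.

    Finds the fixed point of dx1 = v/(1+x3^h) - d x1 (with x1 = x2 = x3 at
    equal rates v, d) and checks whether the Jacobian has eigenvalues with
    positive real part (unstable focus -> sustained oscillation).
    """
    # fixed point: d^3/v^2 * x = v/(1+x^h)  with x = x3
    f = lambda x: d ** 3 * x * (1 + x ** h) - v ** 3
    x3 = brentq(f, 1e-9, 1e6)
    slope = -v * h * x3 ** (h - 1) / (1 + x3 ** h) ** 2    # d(rhs1)/dx3
    J = np.array([
        [-d, 0.0, slope],
        [v, -d, 0.0],
        [0.0, v, -d],
    ])
    return bool(np.real(np.linalg.eigvals(J)).max() > 0)
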