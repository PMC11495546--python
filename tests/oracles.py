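"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the PCHIP oracle
evaluates explicit cubic Hermite basis polynomials with independently
recomputed monotone slopes, and the edge-fit oracle is a two-stage grid
search over (sigma, center) with the linear parameters solved exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf


def pchip_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Monotone (Fritsch-Carlson/Butland) endpoint-aware slope rule."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    h = np.diff(x)
    m = np.diff(y) / h
    n = len(x)
    d = np.zeros(n)
    if n == 2:
        return np.array([m[0], m[0]])
    # interior: weighted harmonic mean when slopes share a sign, else 0
    for k in range(1, n - 1):
        if m[k - 1] == 0 or m[k] == 0 or np.sign(m[k - 1]) != np.sign(m[k]):
            d[k] = 0.0
        else:
            w1 = 2 * h[k] + h[k - 1]
            w2 = h[k] + 2 * h[k - 1]
            d[k] = (w1 + w2) / (w1 / m[k - 1] + w2 / m[k])

    def one_sided(h0, h1, m0, m1):
        val = ((2 * h0 + h1) * m0 - h0 * m1) / (h0 + h1)
        if np.sign(val) != np.sign(m0):
            return 0.0
        if np.sign(m0) != np.sign(m1) and abs(val) > 3 * abs(m0):
            return 3 * m0
        return val

    d[0] = one_sided(h[0], h[1], m[0], m[1])
    d[-1] = one_sided(h[-1], h[-2], m[-1], m[-2])
    return d


def hermite_eval(x: np.ndarray, y: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Cubic Hermite evaluation via the explicit basis polynomials."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    q = np.atleast_1d(np.asarray(q, float))
    d = pchip_slopes(x, y)
    out = np.empty_like(q)
    for i, xi in enumerate(q):
        k = min(max(int(np.searchsorted(x, xi, side="right")) - 1, 0), len(x) - 2)
        h = x[k + 1] - x[k]
        t = (xi - x[k]) / h
        h00 = 2 * t**3 - 3 * t**2 + 1
        h10 = t**3 - 2 * t**2 + t
        h01 = -2 * t**3 + 3 * t**2
        h11 = t**3 - t**2
        out[i] = (h00 * y[k] + h10 * h * d[k]
                  + h01 * y[k + 1] + h11 * h * d[k + 1])
    return out


def erf_edge(x: np.ndarray, a: float, x0: float, sigma: float, b: float
             ) -> np.ndarray:
    return a / 2.0 * (1.0 + erf((x - x0) / (sigma * np.sqrt(2.0)))) + b


def grid_search_edge_fit(x: np.ndarray, y: np.ndarray,
                         n_grid: int = 60) -> tuple[float, float]:
    """Best (sigma, center) by exhaustive search; (a, b) solved linearly.

    Two refinement stages: a coarse scan over the whole plausible range,
    then a fine scan around the coarse optimum.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    span = x[-1] - x[0]
    dx = float(np.median(np.diff(x)))

    def scan(sigmas, centers):
        best = (np.inf, None, None)
        for s in sigmas:
            for c in centers:
                basis = erf(((x - c) / (s * np.sqrt(2.0))))
                A = np.column_stack([basis, np.ones_like(x)])
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                resid = y - A @ coef
                sse = float(resid @ resid)
                if sse < best[0]:
                    best = (sse, s, c)
        return best

    _, s1, c1 = scan(np.linspace(0.25 * dx, span / 2.0, n_grid),
                     np.linspace(x[0], x[-1], n_grid))
    _, s2, c2 = scan(np.linspace(max(0.2 * dx, 0.7 * s1), 1.4 * s1, n_grid),
                     np.linspace(c1 - 2 * dx, c1 + 2 * dx, n_grid))
    return float(s2), float(c2)
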