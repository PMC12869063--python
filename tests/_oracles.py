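"""Independent reference computations used to check the package.

Everything here is deliberately written from first principles (exact
rational arithmetic, brute-force enumeration, direct likelihood formulas)
and shares no code with the implementation under test.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def hwe_enumeration(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p-value by full enumeration with rational arithmetic.

    Conditional on n diploids and the minor allele count, enumerates every
    attainable heterozygote count b with probability
    C(n; a,b,c) * 2^b * nA! * na! / (2n)!  and sums those with
    probability <= that of the observed count.
    """
    n = n_aa + n_ab + n_bb
    n_alt = 2 * n_bb + n_ab
    n_minor = min(n_alt, 2 * n - n_alt)
    probs: dict[int, Fraction] = {}
    for b in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        a_minor = (n_minor - b) // 2
        a_major = n - b - a_minor
        weight = (
            Fraction(math.factorial(n), math.factorial(a_minor)
                     * math.factorial(b) * math.factorial(a_major))
            * 2**b
        )
        probs[b] = weight
    total = sum(probs.values())
    probs = {b: w / total for b, w in probs.items()}
    assert sum(probs.values()) == 1
    p_obs = probs[n_ab]
    return float(sum(w for w in probs.values() if w <= p_obs))


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation from explicit sums (no numpy.corrcoef)."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = (sxy - sx * sy / n) ** 2
    den = (sxx - sx * sx / n) * (syy - sy * sy / n)
    return num / den


def grid_search_decay_rate(dist, r2, lo=1e-9, hi=1.0, rounds=8, width=50):
    """Least-squares decay rate for r2 = 1/(1+p x) by iterative grid zoom."""
    dist = np.asarray(dist, dtype=float)
    r2 = np.asarray(r2, dtype=float)

    def rss(p):
        return float(np.sum((r2 - 1.0 / (1.0 + p * dist)) ** 2))

    for _ in range(rounds):
        grid = np.geomspace(lo, hi, width)
        best = grid[int(np.argmin([rss(p) for p in grid]))]
        lo, hi = best / (grid[1] / grid[0]), best * (grid[1] / grid[0])
    return float(best)


def restricted_loglik(theta, comps, X, y) -> float:
    """REML log-likelihood -(log|V| + log|X'V^-1 X| + y'Py)/2, directly."""
    V = sum(t * C for t, C in zip(theta, comps))
    Vinv = np.linalg.inv(V)
    sign_v, logdet_v = np.linalg.slogdet(V)
    XtVX = X.T @ Vinv @ X
    sign_x, logdet_x = np.linalg.slogdet(XtVX)
    if sign_v <= 0 or sign_x <= 0:
        return -np.inf
    P = Vinv - Vinv @ X @ np.linalg.inv(XtVX) @ X.T @ Vinv
    return -0.5 * (logdet_v + logdet_x + float(y @ P @ y))


def single_variance_gblup_reml(y, X, G):
    """REML for y = Xb + g + e with g ~ N(0, G sg2), e ~ N(0, I se2).

    Works in the eigenbasis of G so each likelihood evaluation is O(n),
    and maximises over (sg2, se2) by nested grid refinement.
    """
    vals, vecs = np.linalg.eigh(G)
    ys = vecs.T @ y
    Xs = vecs.T @ X

    def ll(sg2, se2):
        d = sg2 * vals + se2
        if np.any(d <= 0):
            return -np.inf
        Vinv_y = ys / d
        XtVX = Xs.T @ (Xs / d[:, None])
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XtVX, Xs.T @ Vinv_y)
        resid = ys - Xs @ beta
        quad = float(resid @ (resid / d))
        return -0.5 * (float(np.sum(np.log(d))) + logdet_x + quad)

    vy = float(np.var(y, ddof=1))
    lo_g, hi_g = vy * 1e-4, vy * 4
    lo_e, hi_e = vy * 1e-4, vy * 4
    best = (vy / 2, vy / 2)
    for _ in range(10):
        gs = np.geomspace(lo_g, hi_g, 25)
        es = np.geomspace(lo_e, hi_e, 25)
        lls = [[ll(a, b) for b in es] for a in gs]
        i, j = np.unravel_index(int(np.argmax(lls)), (25, 25))
        best = (gs[i], es[j])
        step_g, step_e = gs[1] / gs[0], es[1] / es[0]
        lo_g, hi_g = best[0] / step_g, best[0] * step_g
        lo_e, hi_e = best[1] / step_e, best[1] * step_e
    return best[0], best[1], ll(*best), ll
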