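"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the change-point oracle
refits both segments from scratch in a different parameterization, the
Mann–Whitney oracle enumerates rank assignments, and the Fisher oracle sums
hypergeometric point probabilities directly.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, inf

import numpy as np


def hinge_oracle(v: np.ndarray, p: np.ndarray, min_seg: int = 3) -> tuple[int, float]:
    """Brute-force continuous two-segment fit: refit at every candidate knot.

    Parameterized by (hinge pressure, left slope, right slope) — a different
    basis from any incremental implementation.  Returns (best knot index,
    SSE), ties to the lower knot.
    """
    n = len(v)
    best_k, best_sse = -1, inf
    for k in range(min_seg - 1, n - min_seg + 1):
        vk = v[k]
        A = np.zeros((n, 3))
        A[:, 0] = 1.0
        left = v <= vk
        A[left, 1] = v[left] - vk
        A[~left, 2] = v[~left] - vk
        beta, *_ = np.linalg.lstsq(A, p, rcond=None)
        resid = p - A @ beta
        sse = float(resid @ resid)
        if best_k < 0 or sse < best_sse - 1e-12 * max(1.0, best_sse):
            best_k, best_sse = k, sse
    return best_k, best_sse


def mw_exact_two_sided_p(x, y) -> float:
    """Two-sided Mann–Whitney p by exhaustive rank-assignment enumeration.

    Assumes no ties.  The null distribution of U is built by enumerating all
    C(nx+ny, nx) placements of the first sample among the combined ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    u_obs = int(sum(xi > yj for xi in x for yj in y))
    u_big = max(u_obs, nx * ny - u_obs)
    total = 0
    extreme = 0
    for pos in combinations(range(nx + ny), nx):
        # U = (sum of 0-based positions of x) minus its minimum arrangement
        u = sum(pos) - nx * (nx - 1) // 2
        total += 1
        if max(u, nx * ny - u) >= u_big:
            extreme += 1
    return min(1.0, extreme / total)


def fisher_two_sided_p(table) -> float:
    """Two-sided Fisher p: sum of hypergeometric point probabilities not
    exceeding the observed table's (point-probability method)."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, c1, n = a + b, a + c, a + b + c + d
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    denom = comb(n, r1)
    probs = {k: comb(c1, k) * comb(n - c1, r1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))
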