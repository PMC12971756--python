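"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity with the most literal algorithm
available (exhaustive enumeration, flood fill, direct formula) so the
production implementations can be checked against code that shares
nothing with them.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def floodfill_label(grid: np.ndarray, neighbourhood: int = 8) -> np.ndarray:
    """Connected-component labels by explicit stack-based flood fill,
    in row-major first-seen order."""
    if neighbourhood == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    nrow, ncol = grid.shape
    labels = np.zeros((nrow, ncol), dtype=int)
    nxt = 0
    for r in range(nrow):
        for c in range(ncol):
            if grid[r, c] and not labels[r, c]:
                nxt += 1
                stack = [(r, c)]
                labels[r, c] = nxt
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in steps:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < nrow and 0 <= c2 < ncol:
                            if grid[r2, c2] and not labels[r2, c2]:
                                labels[r2, c2] = nxt
                                stack.append((r2, c2))
    return labels


def exhaustive_gap_distance(labels: np.ndarray, a: int, b: int, cell: float) -> float:
    """Edge-to-edge gap by checking every pixel pair of the two patches."""
    pa = np.argwhere(labels == a)
    pb = np.argwhere(labels == b)
    dmin = math.inf
    for r1, c1 in pa:
        for r2, c2 in pb:
            d = math.hypot(r1 - r2, c1 - c2) * cell
            dmin = min(dmin, d)
    return max(0.0, dmin - cell)


def enumerate_min_summed_gap(nodes: list[int], edges: dict, focal: int) -> dict[int, float]:
    """d_k by enumerating every simple path from the focal patch (<= 6 nodes)."""

    def gap(a, b):
        if a == b:
            return 0.0
        return edges[(a, b) if a < b else (b, a)]

    best = {p: math.inf for p in nodes}
    best[focal] = 0.0
    others = [p for p in nodes if p != focal]
    for target in others:
        intermediates = [p for p in others if p != target]
        for r in range(len(intermediates) + 1):
            for mid in itertools.permutations(intermediates, r):
                path = [focal, *mid, target]
                total = sum(gap(path[i], path[i + 1]) for i in range(len(path) - 1))
                best[target] = min(best[target], total)
    return best


def reachable_within_threshold(nodes: list[int], edges: dict, focal: int, thr: float) -> set[int]:
    """Transitive closure of the gap <= thr relation, by repeated passes."""

    def gap(a, b):
        if a == b:
            return 0.0
        return edges[(a, b) if a < b else (b, a)]

    comp = {focal}
    changed = True
    while changed:
        changed = False
        for p in nodes:
            if p not in comp and any(gap(p, q) <= thr for q in comp):
                comp.add(p)
                changed = True
    return comp


def softmax_weights(aicc_values) -> np.ndarray:
    """Akaike weights by direct evaluation of the defining formula."""
    arr = np.asarray(aicc_values, dtype=float)
    delta = arr - arr.min()
    e = np.exp(-delta / 2.0)
    return e / e.sum()


def normal_equation_ols(x: np.ndarray, y: np.ndarray):
    """Simple regression by solving the normal equations directly.

    Returns (slope, slope SE, R^2, Gaussian log-likelihood with ML
    variance), mirroring the production fit's contract.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    sigma2 = rss / (n - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = math.sqrt(cov[1, 1])
    ml_var = rss / n
    llf = -0.5 * n * (math.log(2 * math.pi * ml_var) + 1.0)
    return float(beta[1]), se, r2, llf


def pair_mismatch_probability(alleles: list[str]) -> float:
    """1 - sum p^2 by counting ordered draws with replacement."""
    n = len(alleles)
    same = sum(1 for a in alleles for b in alleles if a == b)
    return 1.0 - same / (n * n)
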