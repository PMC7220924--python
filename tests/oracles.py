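"""Independent brute-force oracles used to cross-check the package.

These deliberately re-derive results from first principles (exhaustive window
scans, raw normal equations, full rank-permutation enumeration, direct pixel
counting) without calling the implementation they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_dry_spells(dry: np.ndarray, min_length: int = 5) -> list[tuple[int, int]]:
    """Every (start, end) index window that is dry, maximal and long enough.

    Vectorized exhaustive scan over all O(n^2) windows via prefix sums.
    """
    dry = np.asarray(dry, dtype=bool)
    n = dry.size
    csum = np.concatenate(([0], np.cumsum(dry.astype(int))))
    out = []
    for s in range(n):
        for e in range(s + min_length - 1, n):
            if csum[e + 1] - csum[s] != e - s + 1:
                break  # window contains a wet day; longer windows will too
            left_ok = s == 0 or not dry[s - 1]
            right_ok = e == n - 1 or not dry[e + 1]
            if left_ok and right_ok:
                out.append((s, e))
    return out


def brute_force_subset_weights(
    y: np.ndarray, x: np.ndarray, names: list[str],
    include_null: bool = True, threshold: float = 0.95,
) -> tuple[dict[tuple[str, ...], float], dict[str, float]]:
    """Akaike weights and RVI from raw normal equations.

    Independent of the package: lstsq fits, AIC = n ln(RSS/n) + 2(k+2),
    weights normalized over the enumeration, best subset = shortest AIC-sorted
    prefix with cumulative weight > threshold, RVI = summed weights of
    best-subset models containing the variable.
    """
    n = y.size
    subsets: list[tuple[str, ...]] = []
    start = 0 if include_null else 1
    for r in range(start, len(names) + 1):
        subsets.extend(combinations(names, r))
    aics = []
    for sub in subsets:
        cols = [names.index(v) for v in sub]
        design = np.column_stack([np.ones(n)] + [x[:, j] for j in cols])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ beta) ** 2))
        aics.append(n * np.log(max(rss, 1e-300) / n) + 2 * (len(sub) + 2))
    order = sorted(range(len(subsets)),
                   key=lambda i: (aics[i], len(subsets[i]), subsets[i]))
    aic_sorted = np.array([aics[i] for i in order])
    w = np.exp(-0.5 * (aic_sorted - aic_sorted[0]))
    w /= w.sum()
    weights = {subsets[i]: float(wi) for i, wi in zip(order, w)}
    cum = np.cumsum(w)
    n_best = int(np.argmax(cum > threshold)) + 1
    rvi = {
        name: float(sum(w[j] for j in range(n_best)
                        if name in subsets[order[j]]))
        for name in names
    }
    return weights, rvi


def exact_rank_sum_p(a: list[float], b: list[float]) -> float:
    """Two-sided Mann-Whitney p by enumerating every rank assignment."""
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n_a = len(a)
    idx = {v: i for i, v in enumerate(pooled)}

    def u_stat(group_a: tuple[int, ...]) -> float:
        ranks = [i + 1 for i in group_a]
        r_a = sum(ranks)
        return r_a - n_a * (n_a + 1) / 2

    u_obs = u_stat(tuple(idx[v] for v in a))
    n_tot = len(pooled)
    us = [u_stat(c) for c in combinations(range(n_tot), n_a)]
    mean_u = n_a * (n_tot - n_a) / 2
    extreme = sum(abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12 for u in us)
    return extreme / len(us)


def count_ring_pixels(mask: np.ndarray, width: int, inside: bool) -> int:
    """Count pixels within Chebyshev distance ``width`` of the opposite zone."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    count = 0
    for i in range(rows):
        for j in range(cols):
            if mask[i, j] != inside:
                continue
            near_other = False
            for di in range(-width, width + 1):
                for dj in range(-width, width + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < rows and 0 <= jj < cols \
                            and mask[ii, jj] != inside:
                        near_other = True
            if near_other:
                count += 1
    return count


def pearson_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r from the raw covariance/sigma formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return cov / (x.std() * y.std())
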