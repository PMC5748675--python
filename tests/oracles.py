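"""Independent brute-force oracles used by the test suite.

Each oracle is written in the most transparent form available (pure-python
enumeration, exact rational arithmetic, triple loops) and shares no code
with the implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def nb_logpmf(k: int, mean: float, phi: float) -> float:
    """Pure-python NB(mean, phi) log pmf via lgamma (size r = 1/phi)."""
    r = 1.0 / phi
    p = r / (r + mean)
    return (
        math.lgamma(k + r)
        - math.lgamma(r)
        - math.lgamma(k + 1)
        + r * math.log(p)
        + k * math.log(1.0 - p)
    )


def binom_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1.0 - p) ** (n - k)


def exact_nb_pvalue(group_a, group_b, phi: float) -> float:
    """Brute-force conditional exact NB p-value (minimum-likelihood region).

    Enumerates the full conditional distribution of the group-A sum given
    the two-group total and sums all outcomes no more likely than observed.
    """
    n_a, n_b = len(group_a), len(group_b)
    y_a, y_b = int(sum(group_a)), int(sum(group_b))
    t = y_a + y_b
    if t == 0:
        return 1.0
    if phi == 0.0:
        q = n_a / (n_a + n_b)
        probs = [binom_pmf(k, t, q) for k in range(t + 1)]
    else:
        mu = t / (n_a + n_b)
        lp = [
            nb_logpmf(k, n_a * mu, phi / n_a) + nb_logpmf(t - k, n_b * mu, phi / n_b)
            for k in range(t + 1)
        ]
        mx = max(lp)
        w = [math.exp(v - mx) for v in lp]
        z = sum(w)
        probs = [v / z for v in w]
    obs = probs[y_a]
    p = sum(pr for pr in probs if pr <= obs * (1.0 + 1e-9))
    return min(p, 1.0)


def bh_direct(pvalues) -> np.ndarray:
    """Direct-formula BH: adj_(k) = min_{j >= k} min(1, m p_(j) / j)."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj_sorted = [min(1.0, m * p[order[j]] / (j + 1)) for j in range(m)]
    for j in range(m - 2, -1, -1):
        adj_sorted[j] = min(adj_sorted[j], adj_sorted[j + 1])
    out = [0.0] * m
    for j, i in enumerate(order):
        out[i] = adj_sorted[j]
    return np.array(out)


def tom_tripleloop(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap for a symmetric unit-diagonal adjacency."""
    n = a.shape[0]
    k = [sum(a[i, j] for j in range(n) if j != i) for i in range(n)]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def hypergeom_exact(x: int, n: int, K: int, N: int) -> Fraction:
    """Exact-rational upper-tail hypergeometric probability."""
    total = math.comb(N, n)
    return Fraction(
        sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(x, min(n, K) + 1)),
        total,
    )


def median_of_ratios(mat: np.ndarray) -> np.ndarray:
    """Plain median-of-ratios size factors, rescaled to geometric mean 1."""
    keep = [g for g in range(mat.shape[0]) if all(mat[g] > 0)]
    geo = [math.exp(sum(math.log(v) for v in mat[g]) / mat.shape[1]) for g in keep]
    s = np.array(
        [float(np.median([mat[g, j] / geo[gi] for gi, g in enumerate(keep)])) for j in range(mat.shape[1])]
    )
    return s / math.exp(np.mean(np.log(s)))


def simulate_block_expression(
    n_samples: int, block_sizes, n_background: int, cor: float, seed: int
):
    """Gaussian planted-module expression: within-block correlation ``cor``."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b, size in enumerate(block_sizes):
        z = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(np.sqrt(cor) * z + np.sqrt(1.0 - cor) * rng.normal(size=n_samples))
            labels.append(b)
    for _ in range(n_background):
        rows.append(rng.normal(size=n_samples))
        labels.append(-1)
    expr = pd.DataFrame(
        rows,
        index=[f"g{i:04d}" for i in range(len(rows))],
        columns=[f"s{j:02d}" for j in range(n_samples)],
    )
    return expr, np.array(labels)
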