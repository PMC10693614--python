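"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: the posterior oracle
is 2-D quadrature with direct latent-count summation, the likelihood oracle
is a plain-Python double loop, and the furthest-pair oracle is exhaustive
pairwise search without a convex hull.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special, stats


def grid_posterior_oracle(
    counts,
    lam_upper: float = 100.0,
    K: int = 60,
    n_lam: int = 1000,
    n_psi: int = 400,
):
    """Posterior means of (psi, lambda, N_total) by midpoint quadrature over
    (lambda, psi) with the latent counts enumerated to ``K`` per site."""
    n = np.asarray(counts)
    R = n.shape[0]
    lam_g = (np.arange(n_lam) + 0.5) * lam_upper / n_lam
    psi_g = (np.arange(n_psi) + 0.5) / n_psi
    grid = np.arange(K + 1)
    site_binom = []
    for j in range(R):
        lb = np.zeros((n_psi, K + 1))
        for t in range(n.shape[1]):
            lb += stats.binom.logpmf(n[j, t], grid[None, :], psi_g[:, None])
        site_binom.append(lb)
    logpost = np.zeros((n_lam, n_psi))
    en_total = np.zeros((n_lam, n_psi))
    for li, lam in enumerate(lam_g):
        lp = stats.poisson.logpmf(grid, lam)
        for j in range(R):
            a = lp[None, :] + site_binom[j]
            m = special.logsumexp(a, axis=1)
            logpost[li] += m
            en_total[li] += (np.exp(a - m[:, None]) * grid).sum(axis=1)
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    return (
        float((w * psi_g[None, :]).sum()),
        float((w * lam_g[:, None]).sum()),
        float((w * en_total).sum()),
    )


def direct_marginal_loglik(counts, lam: float, psi: float, K: int) -> float:
    """Plain-Python site-wise sum_N Poisson * prod_t Binomial, log scale."""
    n = np.asarray(counts)
    total = 0.0
    for j in range(n.shape[0]):
        site = 0.0
        for N in range(K + 1):
            term = math.exp(-lam) * lam**N / math.factorial(N)
            for t in range(n.shape[1]):
                c = n[j, t]
                if c > N:
                    term = 0.0
                    break
                term *= math.comb(N, c) * psi**c * (1 - psi) ** (N - c)
            site += term
        total += math.log(site)
    return total


def brute_force_furthest(vertices: np.ndarray):
    """Exhaustive O(n^2) furthest pair, lowest index pair on ties."""
    v = np.asarray(vertices, dtype=float)
    best = (-1.0, None)
    n = len(v)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(v[i] - v[j])))
            if d > best[0] + 1e-12 * max(best[0], 1.0):
                best = (d, (i, j))
    return best[1][0], best[1][1], best[0]


def random_simple_polygon(rng: np.random.Generator, n: int = 30) -> np.ndarray:
    """Star-shaped (hence simple) polygon with jittered radii."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    radii = rng.uniform(0.5, 2.0, n)
    return np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])


def regular_polygon_smooth_radius(n: int, r: float, bandwidth: float) -> float:
    """Kernel-weighted cosine-sum prediction for the smoothed radius of a
    regular n-gon: by symmetry every smoothed vertex lies at radius
    sum_k w_k cos(2 pi k / n) * r / sum_k w_k with periodic arc distances."""
    side = 2 * r * math.sin(math.pi / n)
    k = np.arange(n)
    arc = np.minimum(k, n - k) * side
    w = np.exp(-0.5 * (arc / bandwidth) ** 2)
    return float(r * np.sum(w * np.cos(2 * np.pi * k / n)) / np.sum(w))
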