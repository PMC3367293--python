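"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain double loops over the definitions, on
purpose: these functions must stay independent of the vectorised library
code paths they verify.
"""

import numpy as np


def distances_double_loop(coords):
    n = len(coords)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.sqrt(
                (coords[i][0] - coords[j][0]) ** 2 + (coords[i][1] - coords[j][1]) ** 2
            )
    return d


def dense_weight_matrix(coords, threshold):
    d = distances_double_loop(coords)
    n = len(coords)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and d[i, j] <= threshold:
                w[i, j] = 1.0
    return w


def weight_sums_dense(w):
    """(S0, S1, S2) from an explicit dense weight matrix."""
    s0 = w.sum()
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    return s0, s1, s2


def moran_double_sum(x, w):
    """Global Moran's I as the explicit double sum."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * z[i] * z[j]
    return n / w.sum() * num / (z**2).sum()


def moran_variance_normality(n, s0, s1, s2):
    """Var[I] under the normality assumption (textbook moment formula)."""
    ei = -1.0 / (n - 1)
    e_i2 = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1))
    return e_i2 - ei * ei


def variogram_pair_loop(coords, values, active_lag, n_bins):
    """Empirical variogram via an explicit all-pairs loop."""
    values = np.asarray(values, dtype=float)
    n = len(coords)
    edges = np.linspace(0.0, active_lag, n_bins + 1)
    sums = np.zeros(n_bins)
    dsum = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            h = np.sqrt(
                (coords[i][0] - coords[j][0]) ** 2 + (coords[i][1] - coords[j][1]) ** 2
            )
            if h > active_lag or h <= 0:
                continue
            b = min(int(np.searchsorted(edges, h, side="left")) - 1, n_bins - 1)
            b = max(b, 0)
            sums[b] += (values[i] - values[j]) ** 2
            dsum[b] += h
            counts[b] += 1
    keep = counts > 0
    return dsum[keep] / counts[keep], sums[keep] / (2 * counts[keep]), counts[keep]


def ok_system_solve(target, neighbors, gamma_fn):
    """Assemble and solve the ordinary kriging system independently."""
    neighbors = np.asarray(neighbors, dtype=float)
    k = len(neighbors)
    A = np.zeros((k + 1, k + 1))
    for i in range(k):
        for j in range(k):
            h = np.linalg.norm(neighbors[i] - neighbors[j])
            A[i, j] = gamma_fn(h)
        A[i, k] = 1.0
        A[k, i] = 1.0
    b = np.zeros(k + 1)
    for i in range(k):
        b[i] = gamma_fn(np.linalg.norm(neighbors[i] - np.asarray(target, dtype=float)))
    b[k] = 1.0
    sol = np.linalg.solve(A, b)
    lam, mu = sol[:k], sol[k]
    variance = float(lam @ b[:k] + mu)
    return lam, mu, variance
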