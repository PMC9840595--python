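"""Independent brute-force oracles used to validate the graph metrics.

Each oracle recomputes a quantity by direct enumeration or an unrelated
numerical route, never by calling the implementation under test.
"""

import itertools
import math

import numpy as np
from scipy import integrate
from scipy.special import gammaln


def clustering_by_triple_enumeration(m: np.ndarray) -> float:
    """Mean Onnela clustering by explicit enumeration of node triples."""
    n = m.shape[0]
    wmax = m.max()
    if wmax == 0:
        return 0.0
    w = m / wmax
    coeffs = []
    for i in range(n):
        nbrs = [j for j in range(n) if m[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            coeffs.append(0.0)
            continue
        s = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            if m[j, h] > 0:
                s += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        coeffs.append(2.0 * s / (k * (k - 1)))
    return float(np.mean(coeffs))


def path_length_by_enumeration(m: np.ndarray) -> float:
    """Mean shortest path (lengths 1/w) by enumerating all simple paths."""
    n = m.shape[0]
    best = np.full((n, n), np.inf)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            for k in range(0, n - 1):
                for mid in itertools.permutations(
                    [v for v in range(n) if v not in (s, t)], k
                ):
                    path = (s, *mid, t)
                    ok = all(m[a, b] > 0 for a, b in zip(path, path[1:]))
                    if ok:
                        d = sum(1.0 / m[a, b] for a, b in zip(path, path[1:]))
                        best[s, t] = min(best[s, t], d)
    finite = best[np.isfinite(best)]
    return float(finite.mean())


def path_length_by_relaxation(m: np.ndarray) -> float:
    """Mean shortest path via hand-rolled Floyd-Warshall relaxation."""
    n = m.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and m[i, j] > 0:
                d[i, j] = 1.0 / m[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    off = ~np.eye(n, dtype=bool)
    vals = d[off & np.isfinite(d)]
    return float(vals.mean())


def assortativity_by_edge_list(
    m: np.ndarray, edges=None, mode="out-in", endpoint_strengths="full"
) -> float:
    """Weighted endpoint-strength correlation via numpy's weighted cov."""
    if edges is None:
        edges = [(i, j) for i in range(m.shape[0]) for j in range(m.shape[0])
                 if i != j and m[i, j] != 0]
    edges = [(i, j) for i, j in edges if m[i, j] != 0]
    sm = m
    if endpoint_strengths == "subset":
        sm = np.zeros_like(m)
        for i, j in edges:
            sm[i, j] = m[i, j]
    in_s = sm.sum(axis=1)
    out_s = sm.sum(axis=0)
    pick = {"out-in": (out_s, in_s), "out-out": (out_s, out_s), "in-in": (in_s, in_s)}
    sv, tv = pick[mode]
    x = np.array([sv[j] for _, j in edges])
    y = np.array([tv[i] for i, _ in edges])
    w = np.array([m[i, j] for i, j in edges])
    c = np.cov(np.vstack([x, y]), aweights=w, bias=True)
    return float(c[0, 1] / math.sqrt(c[0, 0] * c[1, 1]))


def t_test_p_by_integration(x: np.ndarray) -> tuple[float, float]:
    """Two-sided one-sample t p-value by integrating the t density."""
    x = np.asarray(x, float)
    n = x.size
    t = x.mean() / (x.std(ddof=1) / math.sqrt(n))
    df = n - 1

    def pdf(u):
        logc = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * math.log(df * math.pi)
        return math.exp(logc - (df + 1) / 2 * math.log1p(u * u / df))

    tail, _ = integrate.quad(pdf, abs(t), np.inf, epsabs=1e-14, epsrel=1e-13)
    return t, 2.0 * tail
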