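"""Brain-level weighted graph metrics.

Global characterization of the connectivity graphs:

* total strength S = sum of the undirected matrix entries,
* weighted clustering coefficient (Onnela geometric-mean form) and
  characteristic path length on inverse-weight distances,
* deterministic lattice and seeded random null models that preserve the
  weight multiset, combined into the small-world propensity
  SWP = 1 - sqrt((dC^2 + dL^2)/2),
* weighted assortativity (edge-weighted Pearson correlation between
  endpoint strengths),
* the reciprocal-balance statistic: -log10 p of a one-sample t-test that
  the directed coupling differences w_ij - w_ji average to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import shortest_path

from .graph_construction import WDCM, WUCM, all_pairs

#: Floor applied to p-values so -log10(p) stays finite.
P_VALUE_FLOOR = 1e-16


class UndefinedMetricError(ValueError):
    """A metric has no defined value on this input (e.g. zero variance)."""


@dataclass(frozen=True)
class StrengthResult:
    s: float
    mode: str  # ordered_sum | pair_sum


@dataclass(frozen=True)
class SwpResult:
    swp_mean: float
    swp_sd: float
    dC: float
    dL: float
    n_null: int
    n_dropped: int
    seed: int


@dataclass(frozen=True)
class BalanceResult:
    mean_diff: float
    t_stat: float
    p_value: float
    neg_log10_p: float
    n_pairs: int
    degenerate: bool = False


def _as_array(u) -> np.ndarray:
    return u.matrix if isinstance(u, (WDCM, WUCM)) else np.asarray(u, dtype=float)


# ---------------------------------------------------------------------------
# Strength


def total_strength(u: WUCM | np.ndarray, mode: str = "ordered_sum") -> StrengthResult:
    """Total connection strength S of the undirected matrix.

    ``ordered_sum`` sums over all ordered (i, j) as the formula
    S = sum_ij WUCM_ij reads; ``pair_sum`` sums each unordered pair once
    (exactly half of the ordered sum on symmetric input).
    """
    m = _as_array(u)
    if mode == "ordered_sum":
        return StrengthResult(float(m.sum()), mode)
    if mode == "pair_sum":
        return StrengthResult(float(np.triu(m, 1).sum()), mode)
    raise ValueError(f"unknown strength mode {mode!r}")


# ---------------------------------------------------------------------------
# Clustering and path length


def weighted_clustering(u: WUCM | np.ndarray) -> float:
    """Mean Onnela weighted clustering coefficient.

    Weights are normalized by the maximum weight; each node's coefficient
    is the geometric mean of triangle edge weights summed over triangles
    through the node, divided by k(k-1); nodes with degree < 2 contribute
    0 to the mean over all nodes.
    """
    m = _as_array(u)
    n = m.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    wmax = m.max()
    if wmax == 0:
        return 0.0
    w = np.cbrt(m / wmax)
    tri = np.diagonal(w @ w @ w)  # 2x the geometric-mean triangle count per node
    k = (m > 0).sum(axis=1)
    coeffs = np.zeros(n)
    mask = k >= 2
    coeffs[mask] = tri[mask] / (k[mask] * (k[mask] - 1))
    return float(coeffs.mean())


def characteristic_path_length(
    u: WUCM | np.ndarray, on_disconnected: str = "warn"
) -> float:
    """Mean shortest-path length with edge length 1/weight.

    Strong couplings are short hops. The mean is over connected ordered
    node pairs; disconnected pairs are excluded (with a warning unless
    ``on_disconnected='ignore'``). Raises on an edgeless graph.
    """
    m = _as_array(u)
    n = m.shape[0]
    if not np.any(m > 0):
        raise ValueError("graph has no edges")
    with np.errstate(divide="ignore"):
        lengths = np.where(m > 0, 1.0 / np.where(m > 0, m, 1.0), 0.0)
    d = shortest_path(lengths, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_disc = int(off.sum() - finite.sum())
    if n_disc and on_disconnected == "warn":
        warnings.warn(
            f"{n_disc} ordered node pairs are disconnected and excluded "
            "from the characteristic path length",
            stacklevel=2,
        )
    return float(d[finite].mean())


# ---------------------------------------------------------------------------
# Null models


def _ring_distance(n: int, i: int, j: int) -> int:
    d = abs(i - j)
    return min(d, n - d)


def _pair_slots_by_ring_distance(n: int) -> list[tuple[int, int]]:
    slots = all_pairs(n)
    slots.sort(key=lambda ij: (_ring_distance(n, *ij), ij[0], ij[1]))
    return slots


def lattice_null(u: WUCM) -> WUCM:
    """Deterministic ring-lattice surrogate preserving the weight multiset.

    Weights are reassigned so the largest weights occupy the pair slots
    with the smallest ring distance |i-j| mod n. Ties break by weight
    order then row-major slot index, making the operation a fixed point
    on its own output.
    """
    m = u.matrix
    n = m.shape[0]
    weights = np.sort(m[np.triu_indices(n, 1)])[::-1]
    out = np.zeros_like(m)
    for wgt, (i, j) in zip(weights, _pair_slots_by_ring_distance(n)):
        out[i, j] = out[j, i] = wgt
    return WUCM(out, u.labels, group_tag=u.group_tag)


def random_null(u: WUCM, seed: int | np.random.Generator) -> WUCM:
    """Random surrogate: weights permuted uniformly over pair slots."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = u.matrix
    n = m.shape[0]
    iu = np.triu_indices(n, 1)
    weights = rng.permutation(m[iu])
    out = np.zeros_like(m)
    out[iu] = weights
    out += out.T
    return WUCM(out, u.labels, group_tag=u.group_tag)


def small_world_propensity(
    u: WUCM, n_null: int = 1000, seed: int = 0
) -> SwpResult:
    """Small-world propensity against lattice and random nulls.

    Per random-null realization r:

        dC_r = clip((C_latt - C_obs) / (C_latt - C_rand_r), 0, 1)
        dL_r = clip((L_obs - L_rand_r) / (L_latt - L_rand_r), 0, 1)
        SWP_r = 1 - sqrt((dC_r^2 + dL_r^2) / 2)

    The lattice null is deterministic; realizations with a degenerate
    denominator are dropped and counted. Reports the mean and sd of SWP
    and the mean dC, dL over the surviving realizations.
    """
    c_obs = weighted_clustering(u)
    l_obs = characteristic_path_length(u, on_disconnected="ignore")
    latt = lattice_null(u)
    c_latt = weighted_clustering(latt)
    l_latt = characteristic_path_length(latt, on_disconnected="ignore")

    rng = np.random.default_rng(seed)
    swp, dc, dl, dropped = [], [], [], 0
    for _ in range(n_null):
        rand = random_null(u, rng)
        c_rand = weighted_clustering(rand)
        l_rand = characteristic_path_length(rand, on_disconnected="ignore")
        den_c = c_latt - c_rand
        den_l = l_latt - l_rand
        if den_c == 0 or den_l == 0:
            dropped += 1
            continue
        dc_r = float(np.clip((c_latt - c_obs) / den_c, 0.0, 1.0))
        dl_r = float(np.clip((l_obs - l_rand) / den_l, 0.0, 1.0))
        swp.append(1.0 - np.sqrt((dc_r**2 + dl_r**2) / 2.0))
        dc.append(dc_r)
        dl.append(dl_r)
    if not swp:
        raise UndefinedMetricError("all null realizations were degenerate")
    return SwpResult(
        swp_mean=float(np.mean(swp)),
        swp_sd=float(np.std(swp, ddof=1)) if len(swp) > 1 else 0.0,
        dC=float(np.mean(dc)),
        dL=float(np.mean(dl)),
        n_null=n_null,
        n_dropped=dropped,
        seed=seed if isinstance(seed, int) else -1,
    )


# ---------------------------------------------------------------------------
# Assortativity


def weighted_assortativity(
    w: WDCM | WUCM | np.ndarray,
    edges: list[tuple[int, int]] | None = None,
    mode: str = "out-in",
    endpoint_strengths: str = "full",
) -> float:
    """Edge-weighted Pearson correlation between endpoint strengths.

    Each directed matrix slot (i, j) — target row i, source column j —
    contributes one observation weighted by its coupling strength: the
    source node's out-strength against the target node's in-strength
    (``mode`` selects out-in, out-out or in-in endpoint values). On a
    symmetric matrix in- and out-strength coincide with node strength, so
    every mode reduces to the classic undirected weighted assortativity.

    ``edges`` restricts the correlation to a subset of directed slots;
    ``endpoint_strengths`` chooses whether strengths come from the full
    matrix (default) or from the subset-induced matrix.
    """
    m = _as_array(w)
    if edges is None:
        ii, jj = np.nonzero(m)
        edges = [(i, j) for i, j in zip(ii, jj) if i != j]
    edges = [(i, j) for (i, j) in edges if m[i, j] != 0]
    if len(edges) < 2:
        raise UndefinedMetricError("need at least 2 nonzero edges")

    if endpoint_strengths == "subset":
        sub = np.zeros_like(m)
        for i, j in edges:
            sub[i, j] = m[i, j]
        sm = sub
    elif endpoint_strengths == "full":
        sm = m
    else:
        raise ValueError(f"unknown endpoint_strengths {endpoint_strengths!r}")

    in_strength = sm.sum(axis=1)  # row sums: total input to each target
    out_strength = sm.sum(axis=0)  # column sums: total output of each source
    src = {"out-in": out_strength, "out-out": out_strength, "in-in": in_strength}
    tgt = {"out-in": in_strength, "out-out": out_strength, "in-in": in_strength}
    try:
        xs = np.array([src[mode][j] for _, j in edges])
        ys = np.array([tgt[mode][i] for i, _ in edges])
    except KeyError:
        raise ValueError(f"unknown assortativity mode {mode!r}") from None
    ws = np.array([m[i, j] for i, j in edges])

    wsum = ws.sum()
    xm = (ws * xs).sum() / wsum
    ym = (ws * ys).sum() / wsum
    cov = (ws * (xs - xm) * (ys - ym)).sum() / wsum
    vx = (ws * (xs - xm) ** 2).sum() / wsum
    vy = (ws * (ys - ym) ** 2).sum() / wsum
    if vx <= 0 or vy <= 0:
        raise UndefinedMetricError(
            "endpoint strengths have zero variance (regular graph)"
        )
    return float(cov / np.sqrt(vx * vy))


# ---------------------------------------------------------------------------
# Balance


def balance_test(diffs: np.ndarray) -> BalanceResult:
    """Two-sided one-sample t-test of reciprocal differences against zero.

    Large -log10(p) marks systematically asymmetric coupling. All-zero
    input gives p = 1; zero variance around a nonzero mean is degenerate
    and reported at the p-value floor.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 reciprocal pairs")
    mean = float(d.mean())
    if float(d.std(ddof=1)) == 0.0:
        if mean == 0.0:
            return BalanceResult(0.0, 0.0, 1.0, 0.0, d.size)
        return BalanceResult(
            mean, np.inf, P_VALUE_FLOOR, -np.log10(P_VALUE_FLOOR), d.size, True
        )
    t, p = stats.ttest_1samp(d, 0.0)
    p = max(float(p), P_VALUE_FLOOR)
    return BalanceResult(mean, float(t), p, float(-np.log10(p)), d.size)
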