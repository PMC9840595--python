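"""RSN-level block metrics and regional screening of group differences.

The 36 regions partition into 7 resting-state networks; every global
metric is recomputed per network block to give a 7x7 matrix whose
diagonal holds within-network values and whose off-diagonal holds
between-network values. The group-difference matrix is screened
per region: incident increases and decreases are averaged separately
and the extreme tails flagged by sample quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model_io import AtlasError, DiffMatrix, RegionAtlas
from .graph_construction import WDCM, reciprocal_differences
from .network_metrics import (
    BalanceResult,
    UndefinedMetricError,
    balance_test,
    weighted_assortativity,
)

RSN_METRICS = ("strength", "assortativity", "balance")


@dataclass(frozen=True)
class RsnMetricMatrix:
    networks: tuple[str, ...]
    values: np.ndarray  # 7x7; NaN marks undefined cells
    metric: str


@dataclass(frozen=True)
class BlockSummary:
    metric: str
    within_mean: float
    within_max: float
    within_min: float
    inter_mean: float
    inter_max: float
    inter_min: float


@dataclass(frozen=True)
class RegionalDiff:
    region: str
    network: str
    avg_increase: float  # Hz, >= 0; mean of strictly positive incident entries
    avg_decrease: float  # Hz, <= 0; mean of strictly negative incident entries
    n_pos: int
    n_neg: int
    flags: set = field(default_factory=set)


def block_pairs(
    atlas: RegionAtlas, net_a: str, net_b: str
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Unordered pair and directed edge-slot subsets for a network block.

    Within-network blocks (net_a == net_b) take all unordered pairs inside
    the network; between-network blocks take all pairs with one endpoint
    in each. Directed slots are both orientations of every pair.
    """
    ia = atlas.network_indices(net_a)
    ib = atlas.network_indices(net_b)
    if net_a == net_b:
        pairs = [(i, j) for k, i in enumerate(ia) for j in ia[k + 1 :]]
    else:
        pairs = [(min(i, j), max(i, j)) for i in ia for j in ib]
    edges = [(i, j) for i, j in pairs] + [(j, i) for i, j in pairs]
    return pairs, edges


def rsn_metric_matrix(
    w: WDCM,
    atlas: RegionAtlas,
    metric: str,
    assort_mode: str = "out-in",
    assort_strengths: str = "subset",
) -> RsnMetricMatrix:
    """Aggregate one global metric into a 7x7 network-block matrix.

    strength: sum of directed couplings over the block's directed slots.
    assortativity: weighted assortativity restricted to the block's
    directed edges (endpoint strengths from the block-induced subgraph by
    default); undefined blocks are recorded as NaN, never as zero.
    balance: -log10 p of the reciprocal balance test on the block's pairs.
    """
    if metric not in RSN_METRICS:
        raise ValueError(f"unknown RSN metric {metric!r}")
    nets = atlas.networks
    k = len(nets)
    vals = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(a, k):
            pairs, edges = block_pairs(atlas, nets[a], nets[b])
            if metric == "strength":
                v = float(sum(w.matrix[i, j] for i, j in edges))
            elif metric == "assortativity":
                try:
                    v = weighted_assortativity(
                        w, edges=edges, mode=assort_mode,
                        endpoint_strengths=assort_strengths,
                    )
                except UndefinedMetricError:
                    v = np.nan
            else:  # balance
                diffs = reciprocal_differences(w, pairs)
                if diffs.size < 2:
                    # a 2-region network has a single reciprocal pair:
                    # no t-test is possible, the cell is missing
                    v = np.nan
                else:
                    v = balance_test(diffs).neg_log10_p
            vals[a, b] = vals[b, a] = v
    return RsnMetricMatrix(nets, vals, metric)


def block_summary(m: RsnMetricMatrix) -> BlockSummary:
    """Mean/max/min over within- (diagonal) and inter-network (off) cells."""
    diag = np.diag(m.values)
    iu = np.triu_indices(m.values.shape[0], 1)
    inter = m.values[iu]
    within = diag[~np.isnan(diag)]
    inter = inter[~np.isnan(inter)]
    if within.size == 0 and inter.size == 0:
        raise UndefinedMetricError("all block cells are undefined")

    def _stats(x: np.ndarray) -> tuple[float, float, float]:
        if x.size == 0:
            return (np.nan, np.nan, np.nan)
        return (float(x.mean()), float(x.max()), float(x.min()))

    wm, wmax, wmin = _stats(within)
    im, imax, imin = _stats(inter)
    return BlockSummary(m.metric, wm, wmax, wmin, im, imax, imin)


def regional_diff(d: DiffMatrix, atlas: RegionAtlas) -> list[RegionalDiff]:
    """Average incident increase and decrease per region, separately.

    A region's incident entries are its row plus its column of the
    difference matrix, excluding the diagonal (2(n-1) values): every
    directed connection the region takes part in, afferent or efferent.
    Positive entries (stronger in the contrast's first group) and
    negative entries are averaged separately; an empty side averages 0.
    """
    m = d.matrix
    n = d.n
    out = []
    for i in range(n):
        incident = np.concatenate([np.delete(m[i, :], i), np.delete(m[:, i], i)])
        pos = incident[incident > 0]
        neg = incident[incident < 0]
        out.append(
            RegionalDiff(
                region=d.labels[i],
                network=atlas.network_of(d.labels[i]),
                avg_increase=float(pos.mean()) if pos.size else 0.0,
                avg_decrease=float(neg.mean()) if neg.size else 0.0,
                n_pos=int(pos.size),
                n_neg=int(neg.size),
            )
        )
    return out


def flag_regions(
    records: list[RegionalDiff], q: float = 0.05
) -> tuple[set[str], set[str]]:
    """Flag the extreme tails of the regional averages.

    ``high_increase``: regions strictly above the (1-q) linear-
    interpolation sample quantile of the avg_increase values;
    ``high_decrease``: regions strictly below the q quantile of the
    (signed) avg_decrease values. Flags are also written back onto the
    records. Returns (high_increase, high_decrease).
    """
    if not 0 < q < 0.5:
        raise ValueError(f"quantile level must be in (0, 0.5), got {q}")
    inc = np.array([r.avg_increase for r in records])
    dec = np.array([r.avg_decrease for r in records])
    hi_thr = float(np.quantile(inc, 1 - q))
    lo_thr = float(np.quantile(dec, q))
    high_increase = {r.region for r in records if r.avg_increase > hi_thr}
    high_decrease = {r.region for r in records if r.avg_decrease < lo_thr}
    for r in records:
        if r.region in high_increase:
            r.flags.add("high_increase")
        if r.region in high_decrease:
            r.flags.add("high_decrease")
    return high_increase, high_decrease
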