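"""Synthetic connectivity generators and a forward neuronal simulator.

Desk-scale stand-ins for the upstream Bayesian pipeline that produces
group effective-connectivity matrices, so every analysis stage can be
exercised with known ground truth:

* Watts-Strogatz weighted ring graphs spanning regular (p=0) to random
  (p=1) topology, for small-world calibration;
* atlas-conforming group matrices with Gaussian block-structured weights,
  a fraction of couplings negative, model-reduction-style exact zeros,
  and Gaussian log-scaling diagonals;
* subject cohorts as group + noise (noise only on surviving couplings, so
  the pruning pattern is preserved by averaging);
* planted group differences on chosen directed edges with exact truth;
* Euler-Maruyama integration of the linear neuronal-state model
  dx/dt = A x + v.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data_model_io import ECM, DiffMatrix, RegionAtlas
from .graph_construction import WUCM

# Default weight scales: couplings of a few hundredths of a Hz with
# stronger within-network blocks, ~6% of couplings pruned to exact zero,
# diagonal log-scaling parameters around 0.2.
DEFAULT_WITHIN_MEAN_HZ = 0.05
DEFAULT_WITHIN_SD_HZ = 0.015
DEFAULT_BETWEEN_MEAN_HZ = 0.02
DEFAULT_BETWEEN_SD_HZ = 0.01
DEFAULT_NEGATIVE_FRACTION = 0.3
DEFAULT_DENSITY = 0.94
DEFAULT_DIAG_MEAN = 0.2
DEFAULT_DIAG_SD = 0.1
DEFAULT_SUBJECT_SD_HZ = 0.05


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the group-matrix generator."""

    atlas: RegionAtlas
    within_mean: float = DEFAULT_WITHIN_MEAN_HZ
    within_sd: float = DEFAULT_WITHIN_SD_HZ
    between_mean: float = DEFAULT_BETWEEN_MEAN_HZ
    between_sd: float = DEFAULT_BETWEEN_SD_HZ
    negative_fraction: float = DEFAULT_NEGATIVE_FRACTION
    density: float = DEFAULT_DENSITY
    diag_mean: float = DEFAULT_DIAG_MEAN
    diag_sd: float = DEFAULT_DIAG_SD
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_sd", "between_sd", "diag_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("negative_fraction", "density"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class PlantedDifference:
    """Ground-truth group difference: delta added on chosen directed slots."""

    edges: tuple[tuple[int, int], ...]  # (target row, source column)
    delta: float
    truth_regions: frozenset = field(default=frozenset())

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError("planted edges must be off-diagonal")


@dataclass(frozen=True)
class DynamicsSpec:
    """Linear stochastic neuronal-state model dx/dt = A x + v."""

    a_hz: np.ndarray
    duration: float = 100.0
    dt: float = 0.01
    noise_sd: float = 0.0
    seed: int = 0
    x0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    def is_stable(self) -> bool:
        return bool(np.all(np.linalg.eigvals(self.a_hz).real < 0))


def ws_weighted_graph(
    n: int,
    k: int,
    p: float,
    weight_law: tuple = ("uniform", 0.5, 1.5),
    seed: int = 0,
) -> WUCM:
    """Weighted Watts-Strogatz graph as an undirected connectivity matrix.

    Nodes sit on a ring with k neighbours each; every edge is rewired
    with probability p, sweeping regular (p=0) through random (p=1)
    topology. Weights are drawn i.i.d. from ``weight_law``:
    ("uniform", lo, hi) or ("lognormal", mu, sigma).
    """
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    if k % 2:
        raise ValueError(f"k={k} must be even")
    g = nx.watts_strogatz_graph(n, k, p, seed=int(seed))
    rng = np.random.default_rng(seed)
    law, *args = weight_law
    m = np.zeros((n, n))
    for i, j in sorted(g.edges()):
        if law == "uniform":
            w = rng.uniform(*args)
        elif law == "lognormal":
            w = rng.lognormal(*args)
        else:
            raise ValueError(f"unknown weight law {law!r}")
        m[i, j] = m[j, i] = w
    labels = tuple(f"g{idx:02d}" for idx in range(n))
    return WUCM(m, labels, group_tag=f"ws(n={n},k={k},p={p},seed={seed})")


def sample_group_ecm(spec: SyntheticSpec, group_tag: str = "synthetic") -> ECM:
    """Sample a group-level connectivity matrix with planted block structure.

    Each off-diagonal slot survives pruning with probability ``density``;
    surviving couplings draw from the within- or between-network normal
    law by block membership and flip sign with probability
    ``negative_fraction``. Pruned slots are exact zeros, emulating
    model-reduction output. Diagonal ~ N(diag_mean, diag_sd).
    """
    rng = np.random.default_rng(spec.seed)
    atlas = spec.atlas
    n = len(atlas)
    nets = [r.network for r in atlas.regions]
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                m[i, i] = rng.normal(spec.diag_mean, spec.diag_sd)
                continue
            if rng.random() >= spec.density:
                continue
            if nets[i] == nets[j]:
                v = rng.normal(spec.within_mean, spec.within_sd)
            else:
                v = rng.normal(spec.between_mean, spec.between_sd)
            if rng.random() < spec.negative_fraction:
                v = -v
            m[i, j] = v
    return ECM(m, atlas.labels, group_tag=group_tag)


def sample_cohort(
    group: ECM, n_subjects: int, subject_sd: float = DEFAULT_SUBJECT_SD_HZ,
    seed: int = 0,
) -> list[ECM]:
    """Subject matrices: group plus i.i.d. Gaussian noise on nonzero slots.

    Noise is confined to surviving couplings so exact zeros (the pruning
    pattern) pass through cohort averaging untouched.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    mask = group.matrix != 0
    cohort = []
    for s in range(n_subjects):
        noise = rng.normal(0.0, subject_sd, group.matrix.shape) * mask
        cohort.append(
            ECM(group.matrix + noise, group.labels, group_tag=f"{group.group_tag}/s{s}")
        )
    return cohort


def plant_difference(
    base: ECM, planted: PlantedDifference, group_tag: str = "synthetic-alt"
) -> tuple[ECM, DiffMatrix]:
    """Add delta on the planted directed slots; return the altered matrix
    and the exact element-wise difference (altered minus base)."""
    m = base.matrix.copy()
    for i, j in planted.edges:
        m[i, j] += planted.delta
    alt = ECM(m, base.labels, group_tag=group_tag)
    diff = DiffMatrix(
        alt.matrix - base.matrix, base.labels,
        tag=f"{group_tag} minus {base.group_tag}",
    )
    return alt, diff


def planted_on_region(
    atlas: RegionAtlas, region: str, delta: float, n_edges: int = 6, seed: int = 0
) -> PlantedDifference:
    """Plant ``n_edges`` incident directed edges of size delta on a region."""
    rng = np.random.default_rng(seed)
    i = atlas.index_of(region)
    others = rng.choice([j for j in range(len(atlas)) if j != i], n_edges, replace=False)
    edges = tuple(
        (i, int(j)) if k % 2 == 0 else (int(j), i) for k, j in enumerate(others)
    )
    return PlantedDifference(edges, delta, frozenset({region}))


def simulate_neuronal(spec: DynamicsSpec, force: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Integrate dx/dt = A x + v by Euler-Maruyama.

    Returns (times, states) with states shaped (n, n_steps+1) including
    the initial condition. Raises on an unstable coupling matrix (any
    eigenvalue with nonnegative real part) unless ``force`` is set.
    """
    a = np.asarray(spec.a_hz, dtype=float)
    n = a.shape[0]
    if not spec.is_stable() and not force:
        raise ValueError(
            "coupling matrix is unstable (eigenvalue with real part >= 0); "
            "pass force=True to integrate anyway"
        )
    rng = np.random.default_rng(spec.seed)
    n_steps = int(round(spec.duration / spec.dt))
    x = np.zeros(n) if spec.x0 is None else np.asarray(spec.x0, dtype=float).copy()
    states = np.empty((n, n_steps + 1))
    states[:, 0] = x
    sqdt = np.sqrt(spec.dt)
    for t in range(n_steps):
        drift = a @ x * spec.dt
        noise = rng.normal(0.0, spec.noise_sd, n) * sqdt if spec.noise_sd > 0 else 0.0
        x = x + drift + noise
        states[:, t + 1] = x
    times = np.arange(n_steps + 1) * spec.dt
    return times, states
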