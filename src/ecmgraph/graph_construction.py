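"""Matrix transformations from effective connectivity to analysis graphs.

The signed, directed coupling matrix with meaningful diagonal is reduced
to two graph representations: a weighted *directed* connectivity matrix
(WDCM: absolute off-diagonal values, zero diagonal) for balance and
assortativity, and a weighted *undirected* connectivity matrix (WUCM:
reciprocal pair sums) for strength and small-world analysis. Diagonal
self-inhibition parameters are summarized separately because loops
distort degree and path-length computations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_model_io import ECM, _validate_square

#: Default regional self-inhibition rate scaled by exp(diagonal) (Hz).
SELF_INHIBITION_BASE_HZ = -0.5


@dataclass(frozen=True)
class WDCM:
    """Nonnegative directed connectivity matrix (Hz), zero diagonal."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    group_tag: str = ""

    def __post_init__(self) -> None:
        m = _validate_square(self.matrix, self.labels)
        if np.any(m < 0):
            raise ValueError("WDCM entries must be nonnegative")
        if np.any(np.diag(m) != 0):
            raise ValueError("WDCM diagonal must be zero")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class WUCM:
    """Symmetric nonnegative connectivity matrix (Hz), zero diagonal."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    group_tag: str = ""

    def __post_init__(self) -> None:
        m = _validate_square(self.matrix, self.labels)
        if np.any(m < 0):
            raise ValueError("WUCM entries must be nonnegative")
        if np.any(np.diag(m) != 0):
            raise ValueError("WUCM diagonal must be zero")
        if not np.array_equal(m, m.T):
            raise ValueError("WUCM must be symmetric")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class SelfInhibitionSummary:
    """Diagonal log-scaling summary: dimensionless mean and per-region Hz."""

    s_diag: float
    s_diag_sum: float
    per_region_hz: np.ndarray
    labels: tuple[str, ...]


def ecm_to_wdcm(e: ECM) -> WDCM:
    """Drop the diagonal and rectify signs: entry (i,j) -> |e(i,j)|, 0 on i=i.

    Negative couplings are inhibitory, but the energetic cost of
    inhibition scales with magnitude, so the graph keeps |weight|.
    """
    m = np.abs(e.matrix.copy())
    np.fill_diagonal(m, 0.0)
    return WDCM(m, e.labels, group_tag=e.group_tag)


def wdcm_to_wucm(w: WDCM) -> WUCM:
    """Symmetrize by summing reciprocal connection strengths."""
    return WUCM(w.matrix + w.matrix.T, w.labels, group_tag=w.group_tag)


def self_inhibition_summary(e: ECM) -> SelfInhibitionSummary:
    """Summarize diagonal self-inhibition log-scaling parameters.

    ``s_diag`` is the mean of the diagonal (a log-scaling value of zero
    corresponds to the default -0.5 Hz self-inhibition); ``per_region_hz``
    converts each parameter z to the effective rate -0.5*exp(z) Hz, which
    is strictly negative for any finite z.
    """
    d = np.diag(e.matrix)
    return SelfInhibitionSummary(
        s_diag=float(np.mean(d)),
        s_diag_sum=float(np.sum(d)),
        per_region_hz=SELF_INHIBITION_BASE_HZ * np.exp(d),
        labels=e.labels,
    )


def all_pairs(n: int) -> list[tuple[int, int]]:
    """All unordered index pairs (i < j) in canonical order."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def reciprocal_differences(
    w: WDCM, pairs: Sequence[tuple[int, int]] | None = None
) -> np.ndarray:
    """Upper-minus-lower reciprocal coupling differences w(i,j) - w(j,i).

    For each unordered pair {i, j} taken with i < j in atlas order. The
    sign therefore depends on the canonical ordering; the default pair
    set is all n(n-1)/2 pairs.
    """
    if pairs is None:
        pairs = all_pairs(w.n)
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        if i == j:
            raise ValueError(f"pair ({i},{j}) is a self-pair")
        a, b = (i, j) if i < j else (j, i)
        out[k] = w.matrix[a, b] - w.matrix[b, a]
    return out
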