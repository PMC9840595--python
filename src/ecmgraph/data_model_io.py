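"""Data model and plain-text I/O for effective-connectivity matrices.

An effective connectivity matrix (ECM) is a signed, weighted, directed
n x n matrix over a fixed region atlas. Off-diagonal entries are coupling
rates in Hz with the convention that columns are sources and rows are
targets: entry (i, j) is the influence of region j on region i. Diagonal
entries are dimensionless log-scaling parameters of each region's
self-inhibition (the effective self-connection is -0.5*exp(z) Hz).

A difference matrix (dECM) holds element-wise group differences of such
couplings; it is *not* itself a connectivity matrix and is kept as a
distinct type so it cannot be fed into the graph-construction chain.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

#: The seven resting-state networks, in canonical (atlas) block order.
RSN_ORDER = ("DMN", "DAN", "CEN", "SN", "SMN", "VN", "AN")

#: Expected number of regions per network in the bundled 36-region atlas.
RSN_SIZES = {"DMN": 9, "DAN": 8, "CEN": 5, "SN": 7, "SMN": 3, "VN": 2, "AN": 2}

_BUILTIN_ATLAS = "atlas36"


class AtlasError(ValueError):
    """Raised when an atlas file violates the atlas invariants."""


class MatrixFormatError(ValueError):
    """Raised when a matrix file cannot be interpreted against an atlas."""


@dataclass(frozen=True)
class Region:
    abbrev: str
    name: str
    network: str
    mni: tuple[int, int, int]


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered region list defining the canonical matrix row/column order.

    The canonical order groups regions by resting-state network
    (DMN block first, AN last); all block logic downstream assumes it.
    """

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        seen = set()
        for r in self.regions:
            if r.abbrev in seen:
                raise AtlasError(f"duplicate region abbreviation {r.abbrev!r}")
            seen.add(r.abbrev)
            if r.network not in RSN_ORDER:
                raise AtlasError(
                    f"unknown network {r.network!r} for region {r.abbrev!r}; "
                    f"expected one of {RSN_ORDER}"
                )

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.abbrev for r in self.regions)

    @property
    def networks(self) -> tuple[str, ...]:
        """Networks present, in canonical order."""
        present = {r.network for r in self.regions}
        return tuple(n for n in RSN_ORDER if n in present)

    def network_of(self, abbrev: str) -> str:
        return self._by_abbrev()[abbrev].network

    def index_of(self, abbrev: str) -> int:
        try:
            return self.labels.index(abbrev)
        except ValueError:
            raise AtlasError(f"unknown region {abbrev!r}") from None

    def network_indices(self, network: str) -> tuple[int, ...]:
        if network not in RSN_ORDER:
            raise AtlasError(f"unknown network {network!r}")
        return tuple(i for i, r in enumerate(self.regions) if r.network == network)

    def _by_abbrev(self) -> dict[str, Region]:
        return {r.abbrev: r for r in self.regions}


def _validate_square(matrix: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise MatrixFormatError(f"matrix must be square, got shape {m.shape}")
    if m.shape[0] != len(labels):
        raise MatrixFormatError(
            f"matrix size {m.shape[0]} does not match {len(labels)} labels"
        )
    if not np.all(np.isfinite(m)):
        raise MatrixFormatError("matrix contains non-finite values")
    return m


@dataclass(frozen=True)
class ECM:
    """Group-level effective connectivity matrix in atlas order."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    group_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", _validate_square(self.matrix, self.labels))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class DiffMatrix:
    """Element-wise group difference of effective connectivity (Hz).

    Positive entries mean stronger coupling in the first-named group of
    the contrast recorded in ``tag``; the diagonal carries no meaning
    and is ignored by all consumers.
    """

    matrix: np.ndarray
    labels: tuple[str, ...]
    tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", _validate_square(self.matrix, self.labels))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# Atlas I/O


def _parse_atlas_rows(rows: list[dict[str, str]], source: str) -> RegionAtlas:
    regions = []
    for row in rows:
        try:
            regions.append(
                Region(
                    abbrev=row["abbrev"].strip(),
                    name=row["name"].strip(),
                    network=row["network"].strip(),
                    mni=(int(row["x"]), int(row["y"]), int(row["z"])),
                )
            )
        except (KeyError, ValueError) as exc:
            raise AtlasError(f"malformed atlas row in {source}: {row!r}") from exc
    return RegionAtlas(tuple(regions))


def load_region_atlas(path: str | Path = _BUILTIN_ATLAS) -> RegionAtlas:
    """Load a region atlas from a TSV file or the builtin 36-region fixture.

    The builtin fixture (``"atlas36"``) is the 36-region, 7-network
    resting-state parcellation with MNI152 centre coordinates; it defines
    the canonical ordering used by every matrix in the package.
    """
    if path == _BUILTIN_ATLAS:
        text = resources.files(__package__).joinpath("atlas36.tsv").read_text("utf-8")
        source = "builtin atlas36"
    else:
        text = Path(path).read_text("utf-8")
        source = str(path)
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    atlas = _parse_atlas_rows(list(reader), source)
    if path == _BUILTIN_ATLAS:
        if len(atlas) != 36:
            raise AtlasError(f"builtin atlas has {len(atlas)} regions, expected 36")
        counts = {n: len(atlas.network_indices(n)) for n in RSN_ORDER}
        if counts != RSN_SIZES:
            raise AtlasError(f"builtin atlas network sizes {counts} != {RSN_SIZES}")
    return atlas


# ---------------------------------------------------------------------------
# Matrix I/O


def _sniff_delimiter(text: str) -> str:
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    for d in ("\t", ";", ","):
        if d in first:
            return d
    return ","


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_matrix(
    path: str | Path,
    atlas: RegionAtlas,
    kind: str = "ecm",
    group_tag: str = "",
    transpose: bool = False,
) -> ECM | DiffMatrix:
    """Read a connectivity or difference matrix and align it to atlas order.

    Accepts comma-, tab- or semicolon-delimited text with an optional
    header row and label column. When labels are present they must be a
    permutation of the atlas abbreviations and the matrix is reordered to
    canonical order (rows and columns simultaneously); unlabeled files
    are assumed already in atlas order and a warning is emitted.

    ``transpose`` flips the orientation for files written with rows as
    sources instead of the canonical column=source convention.
    """
    if kind not in ("ecm", "diff"):
        raise ValueError(f"kind must be 'ecm' or 'diff', got {kind!r}")
    text = Path(path).read_text("utf-8")
    delim = _sniff_delimiter(text)
    rows = [r for r in csv.reader(io.StringIO(text), delimiter=delim) if any(c.strip() for c in r)]
    if not rows:
        raise MatrixFormatError(f"{path}: empty file")

    has_header = not all(_is_number(c) for c in rows[0][1:] if c.strip()) or not _is_number(rows[0][-1])
    has_label_col = not _is_number(rows[-1][0])

    col_labels: list[str] | None = None
    row_labels: list[str] | None = None
    if has_header:
        header = [c.strip() for c in rows[0]]
        body_rows = rows[1:]
        col_labels = header[1:] if has_label_col else header
    else:
        body_rows = rows
    if has_label_col:
        row_labels = [r[0].strip() for r in body_rows]
        body = [r[1:] for r in body_rows]
    else:
        body = body_rows

    try:
        values = [[float(c) for c in r] for r in body]
        m = np.array(values, dtype=float)
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: malformed numeric body ({exc})") from exc
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise MatrixFormatError(f"{path}: body is not square, shape {m.shape}")
    if m.shape[0] != len(atlas):
        raise MatrixFormatError(
            f"{path}: {m.shape[0]}x{m.shape[1]} body does not match "
            f"{len(atlas)}-region atlas"
        )

    labels = row_labels or col_labels
    if labels is not None:
        if sorted(labels) != sorted(atlas.labels):
            raise MatrixFormatError(
                f"{path}: labels are not a permutation of the atlas abbreviations"
            )
        if row_labels is not None and col_labels is not None and row_labels != col_labels:
            raise MatrixFormatError(f"{path}: row and column label orders differ")
        perm = [labels.index(a) for a in atlas.labels]
        m = m[np.ix_(perm, perm)]
    else:
        warnings.warn(
            f"{path}: no labels found; assuming rows/columns already in atlas order",
            stacklevel=2,
        )

    if transpose:
        m = m.T
    if kind == "ecm":
        return ECM(m, atlas.labels, group_tag=group_tag)
    return DiffMatrix(m, atlas.labels, tag=group_tag)


def write_matrix(m: ECM | DiffMatrix, path: str | Path) -> Path:
    """Write a labeled CSV (first row/column = abbreviations, 12 sig. digits).

    Round-trips through :func:`read_matrix` to full printed precision.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["", *m.labels])
        for label, row in zip(m.labels, m.matrix):
            w.writerow([label, *(f"{v:.12g}" for v in row)])
    return path
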