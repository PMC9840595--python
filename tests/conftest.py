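import numpy as np
import pytest

from ecmgraph import (
    ECM,
    RegionAtlas,
    SyntheticSpec,
    WDCM,
    WUCM,
    load_region_atlas,
)


@pytest.fixture(scope="session")
def atlas() -> RegionAtlas:
    return load_region_atlas()


@pytest.fixture(scope="session")
def default_spec(atlas) -> SyntheticSpec:
    return SyntheticSpec(atlas, seed=1)


def random_wucm(n: int, rng: np.random.Generator, density: float = 1.0) -> WUCM:
    """Dense-ish random symmetric nonnegative matrix with zero diagonal."""
    m = rng.uniform(0.1, 1.0, (n, n))
    m *= rng.random((n, n)) < density
    m = np.triu(m, 1)
    m = m + m.T
    return WUCM(m, tuple(f"n{i}" for i in range(n)))


def random_wdcm(n: int, rng: np.random.Generator, density: float = 1.0) -> WDCM:
    m = rng.uniform(0.1, 1.0, (n, n))
    m *= rng.random((n, n)) < density
    np.fill_diagonal(m, 0.0)
    return WDCM(m, tuple(f"n{i}" for i in range(n)))


def random_ecm(atlas: RegionAtlas, rng: np.random.Generator) -> ECM:
    n = len(atlas)
    m = rng.normal(0.0, 0.05, (n, n))
    np.fill_diagonal(m, rng.normal(0.2, 0.1, n))
    return ECM(m, atlas.labels, group_tag="random")
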