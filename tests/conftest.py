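import numpy as np
import pytest

from scaffold_degrade import (
    DegradationCoefficients,
    ScaffoldField,
    StentFieldSpec,
    generate_stent_field,
)


@pytest.fixture(scope="session")
def coeffs() -> DegradationCoefficients:
    """Published-fit degradation constants."""
    return DegradationCoefficients()


def make_field(strains, volumes=None, edges=(), ids=None) -> ScaffoldField:
    """Small hand-built scaffold field for unit tests.

    ``edges`` are (id, id) pairs; adjacency is symmetrised here.
    """
    strains = np.asarray(strains, dtype=float)
    n = strains.size
    ids = np.arange(n) if ids is None else np.asarray(ids)
    volumes = np.ones(n) if volumes is None else np.asarray(volumes, dtype=float)
    index = {int(e): i for i, e in enumerate(ids)}
    nbrs = [set() for _ in range(n)]
    for u, v in edges:
        nbrs[index[u]].add(int(v))
        nbrs[index[v]].add(int(u))
    return ScaffoldField(ids, volumes, strains, [frozenset(s) for s in nbrs])


@pytest.fixture()
def path_field() -> ScaffoldField:
    """Five equal elements in a path: 0-1-2-3-4."""
    return make_field([0.1] * 5, edges=[(i, i + 1) for i in range(4)])


@pytest.fixture()
def ring_field() -> ScaffoldField:
    """Eight equal elements in a ring."""
    return make_field([0.1] * 8, edges=[(i, (i + 1) % 8) for i in range(8)])


@pytest.fixture(scope="session")
def synthetic_field() -> ScaffoldField:
    """Default two-ring synthetic stent field, fixed seed."""
    return generate_stent_field(StentFieldSpec(seed=42))
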