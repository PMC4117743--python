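import numpy as np
import pytest

from csac import DEFAULT_PARAMS, grow_ensemble
from csac.growth import grow_chain


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def small_confined_ensemble():
    """60 confined chains of 120 units, shared across read-only tests."""
    return grow_ensemble(60, 120, 1.5, seed=4242)


@pytest.fixture(scope="session")
def small_free_ensemble():
    return grow_ensemble(60, 120, None, seed=2424)


@pytest.fixture(scope="session")
def one_confined_chain():
    conf, rec = grow_chain(200, 1.5, seed=77)
    assert conf is not None
    return conf


def brute_force_overlaps(coords, d_min, tol=1e-6):
    """O(n^2) all-pairs excluded-volume oracle: violating non-bonded pairs."""
    bad = []
    n = len(coords)
    for i in range(n):
        d = np.linalg.norm(coords[i + 2:] - coords[i], axis=1)
        for k in np.flatnonzero(d < d_min - tol):
            bad.append((i, i + 2 + int(k)))
    return bad
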