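import numpy as np
import pytest

from celliq.systems import AtomicSystem


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_open_system(rng, n=6, species=(11, 17), total_charge=0.0,
                       min_dist=1.4, box=6.0):
    """Random non-overlapping cluster of the fictitious A/B species."""
    for _ in range(200):
        pos = rng.uniform(0, box, (n, 3))
        d = np.linalg.norm(pos[None] - pos[:, None], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() >= min_dist:
            break
    else:
        raise RuntimeError("could not draw a non-overlapping cluster")
    z = np.array([species[k % len(species)] for k in range(n)])
    return AtomicSystem(species=z, positions=pos, total_charge=total_charge)


@pytest.fixture
def small_cluster(rng):
    return random_open_system(rng, n=5)


@pytest.fixture(scope="session")
def reference_model():
    from celliq.synthetic import default_reference
    return default_reference()
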