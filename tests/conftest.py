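import numpy as np
import pytest

from endstate import ToySpec, make_toy_complex


@pytest.fixture
def toy():
    """Small charged two-chain complex (3+2 residues, 2 atoms each)."""
    return make_toy_complex(ToySpec(seed=7))


@pytest.fixture
def toy_with_waters():
    return make_toy_complex(ToySpec(n_waters=6, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_system(rng, n, spread=8.0, min_sep=1.0):
    """Random non-overlapping coordinates with random charges/LJ params."""
    coords = []
    while len(coords) < n:
        p = rng.uniform(-spread, spread, size=3)
        if all(np.linalg.norm(p - c) > min_sep for c in coords):
            coords.append(p)
    coords = np.array(coords)
    charges = rng.uniform(-0.5, 0.5, size=n)
    rmin_half = rng.uniform(1.5, 2.2, size=n)
    eps = rng.uniform(0.05, 0.3, size=n)
    return coords, charges, rmin_half, eps
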