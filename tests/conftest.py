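import numpy as np
import pytest

import ivimdrift as iv
from ivimdrift.containers import IVIMMaps


@pytest.fixture(scope="session")
def phantom():
    return iv.synthdata.make_phantom((32, 32, 8), seed=1)


@pytest.fixture(scope="session")
def diffusive_scheme():
    return iv.scheme.protocol_preset("diffusive")


@pytest.fixture(scope="session")
def sivim_scheme():
    return iv.scheme.protocol_preset("sivim")


@pytest.fixture(scope="session")
def ballistic_schemes():
    return iv.scheme.protocol_preset("ballistic")


@pytest.fixture(scope="session")
def drifted_diffusive(phantom, diffusive_scheme):
    """Noiseless diffusive-protocol series under antisymmetric ±5 %/5 min
    drift, with the generating model and the clean series."""
    clean = iv.synthdata.forward_signal(phantom.maps, diffusive_scheme,
                                        "diffusive", phantom.mask)
    model = iv.synthdata.make_drift_model({"frontal": -5.0, "inferior": 5.0},
                                          phantom, diffusive_scheme)
    drifted = iv.synthdata.apply_drift(clean, model)
    return clean, drifted, model


def voxel_line_maps(n, seed=None, S0=1000.0):
    """n voxels on an (n,1,1) grid with parameters spanning the brain-like
    ranges (evenly spaced, or uniform random when seeded)."""
    if seed is None:
        g = np.linspace(0.0, 1.0, n)
    else:
        g = np.random.default_rng(seed).uniform(0.0, 1.0, n)
    shape = (n, 1, 1)
    return IVIMMaps(
        D=(0.6 + 0.4 * g).reshape(shape),
        f=(0.01 + 0.05 * g).reshape(shape),
        Dstar=(5.0 + 25.0 * g).reshape(shape),
        v_d=(0.5 + 2.5 * g).reshape(shape),
        S0=np.full(shape, S0),
    )
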