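import numpy as np
import pytest

from fwbio.phantom import RegionSpec, make_dwi_phantom
from fwbio.protocol import default_protocol


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def noiseless_phantom(protocol):
    """Small three-region noiseless phantom with anisotropic tissue."""
    regions = [
        RegionSpec(1, (0.05, 0.15), (1.5e-3, 0.4e-3, 0.4e-3), "x", "a"),
        RegionSpec(2, (0.25, 0.45), (1.5e-3, 0.4e-3, 0.4e-3), "y", "b"),
        RegionSpec(3, (0.55, 0.75), (1.7e-3, 0.3e-3, 0.3e-3), "random", "c"),
    ]
    return make_dwi_phantom(shape=(6, 4, 3), regions=regions,
                            protocol=protocol, snr=np.inf, seed=11)


def grid_search_f(signals, protocol, d_water=3.0e-3, n_grid=1000):
    """Independent 1-D grid-search oracle for the free-water fraction.

    For each candidate f the tissue tensor has a closed-form log-linear
    solution on the f-corrected attenuations; the best f minimises the
    reconstruction error of the full bi-tensor signal.  Never calls the
    package's optimiser.
    """
    from fwbio.dti import design_matrix, tensor_from_lower

    signals = np.asarray(signals, dtype=float)
    b = protocol.bvals
    g = protocol.bvecs
    s0 = signals[protocol.b0_mask].mean()
    attn = np.clip(signals / s0, 1e-8, None)
    e_w = np.exp(-b * d_water)
    X = design_matrix(protocol)
    pinv = np.linalg.pinv(X)

    best = (np.inf, None, None)
    for f in np.linspace(0.0, 0.999, n_grid):
        attn_t = np.clip((attn - f * e_w) / (1.0 - f), 1e-8, None)
        beta = pinv @ np.log(attn_t)
        D = tensor_from_lower(beta[1:])
        q = np.einsum("ki,ij,kj->k", g, D, g)
        model = (1.0 - f) * np.exp(-b * q) + f * e_w
        cost = float(np.sum((model - attn) ** 2))
        if cost < best[0]:
            best = (cost, f, D)
    return best[1], best[2]
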