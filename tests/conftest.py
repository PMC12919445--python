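import numpy as np
import pytest

from epipoint.encoder import EncoderConfig
from epipoint.finetune import DecoderConfig
from epipoint.rhem import RhemConfig
from epipoint.synthetic import SyntheticSpec, generate_complex


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(antigen_residues=(25, 40), antibody_residues=(15, 25))


@pytest.fixture(scope="session")
def small_sample(small_spec):
    return generate_complex(small_spec, np.random.default_rng(7), "fixture")


@pytest.fixture
def tiny_rhem_cfg():
    return RhemConfig(atom_mlp_widths=(11, 8, 12), d_model=16, dropout=0.0,
                      max_residues=256)


@pytest.fixture
def tiny_enc_cfg():
    return EncoderConfig(n_blocks=2, d_model=16, n_heads=2, dropout=0.0)


@pytest.fixture
def tiny_dec_cfg():
    return DecoderConfig(n_heads=2, d_model=16, dropout=0.0, site_hidden=8)


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    grad = np.zeros_like(x, dtype=np.float64)
    flat = x.ravel()
    gflat = grad.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f()
        flat[i] = orig - eps
        fm = f()
        flat[i] = orig
        gflat[i] = (fp - fm) / (2.0 * eps)
    return grad
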