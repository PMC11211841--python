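import numpy as np
import pytest
from hypothesis import settings

import ribodesign as rd
from ribodesign.synthetic import ToyGeometryRule

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_rule():
    return ToyGeometryRule()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_backbone():
    """A 24-nt noiseless helical backbone shared by read-only tests."""
    rule = ToyGeometryRule(noise_sd=0.0)
    return rd.make_helix_backbone("ACGUACGUACGUGGCCAAUUACGU", rule,
                                  np.random.default_rng(7))


@pytest.fixture(scope="session")
def tiny_model():
    """A deliberately small denoiser for wiring/invariance tests."""
    cfg = rd.DenoiserConfig(n_gvp_layers=2, n_transformer_layers=2,
                            hidden_scalar_dim=32, hidden_vector_dim=4,
                            n_heads=4, ffn_dim=64)
    feat = rd.FeatureConfig(k=8, n_rbf=16, n_posenc=8)
    return rd.Denoiser(cfg, feat, seed=3)


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation vector."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.standard_normal(3) * 10.0
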