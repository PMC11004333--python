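import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from painfusion.spatial import SpatialConfig, SpatialEncoder
from painfusion.synthetic import EffectConfig, ProtocolSpec

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

# Reduced architectures for forward/training tests; the full-size defaults are
# exercised where only instantiation or a single forward pass is needed.
TINY_SPATIAL = SpatialConfig(embed_dim=16, inner_dim=8, inner_heads=2,
                             outer_heads=2, depth=1, fcn_inner_hidden=16,
                             fcn_outer_hidden=32)
TINY_TEMPORAL = dict(internal_dim=32, n_latents=8, self_heads=4,
                     fcn_hidden=64, fourier_bands=8)


@pytest.fixture(scope="session")
def tiny_spatial() -> SpatialEncoder:
    return SpatialEncoder(TINY_SPATIAL, seed=0)


@pytest.fixture(scope="session")
def toy_spec() -> ProtocolSpec:
    """Short sessions (2 s at 2 fps / 256 Hz) for end-to-end tests."""
    return ProtocolSpec(n_subjects=2, reps_per_level=1, n_baseline=1,
                        window_s=2.0, fps=2.0, fs=256.0, seed=7)


@pytest.fixture(scope="session")
def strong_effects() -> EffectConfig:
    """Large injected effect sizes for separability-oriented smoke tests."""
    return EffectConfig(bpm_per_level=6.0, deform_px_per_level=6.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
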