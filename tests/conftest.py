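import numpy as np
import pytest

from cineseg.cine_io import normalize_intensity
from cineseg.phantom import PhantomConfig, generate_phantom, random_phantom_config


@pytest.fixture(scope="session")
def small_phantom():
    """One 24^3 phantom subject with full ground truth (raw intensities)."""
    cfg = random_phantom_config(7, grid_size=24)
    series, labels = generate_phantom(cfg)
    return cfg, series, labels


@pytest.fixture(scope="session")
def small_phantom_normalized(small_phantom):
    cfg, series, labels = small_phantom
    return cfg, normalize_intensity(series), labels


@pytest.fixture(scope="session")
def static_phantom():
    """Zero-motion phantom: all frames share identical anatomy."""
    from dataclasses import replace

    base = PhantomConfig(grid_size=24, seed=3)
    frozen = [replace(s, amplitude=0.0) for s in base.structures]
    cfg = PhantomConfig(grid_size=24, seed=3, structures=frozen,
                        noise_sigma=6.0, bias_amplitude=0.02)
    series, labels = generate_phantom(cfg)
    return cfg, series, labels


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
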