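import numpy as np
import pytest

from iedwaves import ArrayGeometry, IEDSimSpec, synth_ied_recording


@pytest.fixture(scope="session")
def geometry():
    return ArrayGeometry()


@pytest.fixture(scope="session")
def planted_recording(geometry):
    """Moderate-noise segment with 20 planted traveling IEDs (shared)."""
    spec = IEDSimSpec(n_ieds=20)
    rec, truth = synth_ied_recording(geometry, spec, seed=1234)
    return rec, truth


@pytest.fixture(scope="session")
def noiseless_recording(geometry):
    """Zero-noise segment: planted delays are exact."""
    spec = IEDSimSpec(n_ieds=5, noise_sd_uv=0.0, mua_jitter_ms=0.0,
                      mua_background_hz=0.0, fs_hz=2000.0)
    rec, truth = synth_ied_recording(geometry, spec, duration_s=40.0, seed=99)
    return rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
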