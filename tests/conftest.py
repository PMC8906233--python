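import numpy as np
import pytest

from ndtsurf import CaptureSpec, PhantomSpec, generate_torso_surface, \
    simulate_capture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def torso_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def torso_base(torso_spec):
    """A ~5000-point sample of the phantom's upper surface."""
    return generate_torso_surface(torso_spec, seed=1)


@pytest.fixture(scope="session")
def reference_clean(torso_base):
    """Noiseless reference capture (ceiling-camera visibility culling only)."""
    return simulate_capture(torso_base, CaptureSpec(noise_sigma=0.0, seed=2))


@pytest.fixture(scope="session")
def reference_noisy(torso_base):
    """Reference capture with the default 0.5 mm per-point noise."""
    return simulate_capture(torso_base, CaptureSpec(noise_sigma=0.5, seed=2))
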