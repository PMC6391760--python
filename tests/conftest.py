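import numpy as np
import pytest

from volecall.profiles import CallSpec, default_profiles


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture
def make_spec():
    """Factory for call specs with sensible defaults for unit tests."""

    def _make(structure="harmonic", noise_fraction=0.0, duration_s=0.08,
              f0max_hz=2500.0, modulation_range_hz=800.0, n_harmonics=6,
              q50_target_hz=4000.0, entropy_target=0.5, **kw):
        return CallSpec(duration_s=duration_s, f0max_hz=f0max_hz,
                        modulation_range_hz=modulation_range_hz,
                        n_harmonics=n_harmonics, structure=structure,
                        noise_fraction=noise_fraction,
                        q50_target_hz=q50_target_hz,
                        entropy_target=entropy_target, **kw)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
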