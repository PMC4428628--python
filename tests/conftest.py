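import numpy as np
import pytest

from epiflim import EpitheliumGeometry, SyntheticConfig, reduced_config


@pytest.fixture
def desk_config() -> SyntheticConfig:
    """Small, fast configuration with full lifetime physics."""
    return reduced_config(48, 48)


@pytest.fixture
def flat_band() -> EpitheliumGeometry:
    """Horizontal 100-row band: membrane at y=100.25, surface at y=0.25.

    Pixel-center rows 1..100 lie inside; each of 10 equal layers holds
    exactly 10 rows.
    """
    x = np.arange(120, dtype=float)
    membrane = np.column_stack([x, np.full_like(x, 100.25)])
    surface = np.column_stack([x, np.full_like(x, 0.25)])
    return EpitheliumGeometry(membrane, surface)


@pytest.fixture
def noiseless_config() -> SyntheticConfig:
    """Deterministic profile: no sample noise, no pixel jitter."""
    return reduced_config(48, 48, sample_rsd=0.0, pixel_noise_sd=0.0)
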