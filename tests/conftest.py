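import pytest

from wardwatch import SimConfig, default_icu_layout
from wardwatch.simulator import NoiseConfig


@pytest.fixture(scope="session")
def layout():
    return default_icu_layout()


@pytest.fixture()
def noiseless_cfg():
    """Short two-nurse shift with sensing noise disabled — fast unit fixture."""
    return SimConfig(
        n_nurses_per_shift=2, shift_hours=2.0, seed=42, noise=NoiseConfig.off()
    )
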