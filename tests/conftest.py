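import numpy as np
import pytest

from teamoist.io import SpectraTable, WavelengthGrid
from teamoist.synthetic import DryingCurveConfig, SpectraSimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """5-sample, 6-channel reflectance table with moisture labels."""
    wl = WavelengthGrid(np.array([1000.0, 1100, 1200, 1300, 1400, 1500]))
    values = rng.uniform(0.2, 0.9, size=(5, 6))
    moisture = np.array([0.2, 0.3, 0.4, 0.5, 0.6])
    return SpectraTable([f"s{i}" for i in range(5)], wl, values, moisture)


@pytest.fixture(scope="session")
def tiny_campaign():
    """Small, cheap synthetic campaign shared by pipeline-level tests."""
    curve = DryingCurveConfig(replicates=6)
    spectra_cfg = SpectraSimConfig(step_nm=8.0)
    return curve, spectra_cfg, generate_dataset(curve, spectra_cfg, seed=7)
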