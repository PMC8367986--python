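import numpy as np
import pytest

from vasnorm import simulate as sim


@pytest.fixture(scope="session")
def section_and_truth():
    """One shared synthetic section: 20 tubes, half with pericytes."""
    params = sim.VesselSimParams(
        image_shape=(512, 512),
        n_vessels=20,
        pericyte_fraction=0.5,
        seed=42,
    )
    return sim.generate_vessel_image(params)


@pytest.fixture(scope="session")
def noiseless_dce():
    """Noise-free DCE series over a small grid with known amplitudes."""
    params = sim.DceSimParams(grid_shape=(5, 4, 3), noise_sd=0.0, seed=7)
    amplitudes = np.random.default_rng(7).uniform(0.1, 1.0, (5, 4, 3))
    series = sim.generate_dce_series(params, amplitudes)
    return series, amplitudes, params
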