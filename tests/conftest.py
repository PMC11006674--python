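import numpy as np
import pytest

from aorpe.sim import MosaicSpec, generate_mosaic, simulate_acquisition


@pytest.fixture(scope="session")
def small_mosaic():
    """Jitter-free 200x200 mosaic with 14 px spacing (session-cached)."""
    return generate_mosaic(MosaicSpec(200, 200, 1.0, 14.0, 0.0, 0.8, rng_seed=0))


@pytest.fixture(scope="session")
def jittered_mosaic():
    return generate_mosaic(MosaicSpec(200, 200, 1.0, 14.0, 0.1, 0.8, rng_seed=1))


@pytest.fixture(scope="session")
def small_stack():
    """Motion-free 12-frame stack of a 128 px mosaic (session-cached)."""
    spec = MosaicSpec(128, 128, 1.0, 14.0, 0.08, 0.8, rng_seed=2)
    return simulate_acquisition(spec, n_frames=12, seed=3)


@pytest.fixture(scope="session")
def moving_stack():
    """16-frame stack with drift and saccades (session-cached)."""
    spec = MosaicSpec(160, 160, 1.0, 14.0, 0.08, 0.8, rng_seed=5)
    return simulate_acquisition(
        spec, n_frames=16, drift_sd_px_per_row=0.01,
        saccade_rate_per_frame=0.3, saccade_amp_px=6.0, seed=7,
    )


@pytest.fixture(scope="session")
def stack120():
    """Motion-free 120-frame acquisition, the paper-scale averaging regime."""
    spec = MosaicSpec(128, 128, 1.0, 14.0, 0.08, 0.8, rng_seed=2)
    return simulate_acquisition(spec, n_frames=120, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
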