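import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lfpspike as lp

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def utah_map():
    return lp.build_array_map(n_channels=96)


@pytest.fixture(scope="session")
def small_session():
    """Desk-scale synthetic session shared across tests: 12 channels, 20 s."""
    cfg = lp.SimulationConfig.desk(n_channels=12, duration_s=20.0, seed=7)
    amap = lp.grid_for_channels(12)
    raw, truth = lp.synthesize_raw_recording(cfg, amap)
    return cfg, amap, raw, truth


@pytest.fixture(scope="session")
def small_derived(small_session):
    """LFP/ESA signals and feature/target matrices for the shared session."""
    cfg, amap, raw, truth = small_session
    lfp = lp.extract_lfp(raw)
    esa = lp.extract_esa(raw)
    grid = lp.sliding_window_grid(lfp.duration_s)
    X = lp.lfp_feature_matrix(lfp, grid)
    sua = truth.sua_trains()
    keep = lp.select_active_units([t for *_, t in sua], cfg.duration_s)
    Y = lp.spiking_target_matrix(
        grid,
        esa=esa,
        sua_trains=[sua[i] for i in keep],
        mua_trains=truth.mua_trains(cfg.mua_amplitude_cutoff),
    )
    return lfp, esa, grid, X, Y


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
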