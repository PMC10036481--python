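"""Shared fixtures: small simulations reused across test modules."""

import pytest

from cableflock import geometry, synthdata


@pytest.fixture(scope="session")
def flock_run():
    """Default-parameter flock simulation (smallish) with annotations."""
    cfg = synthdata.default_flock_config(seed=42, n_frames=150)
    tracks, trace = synthdata.simulate_flock(cfg)
    obs = geometry.annotate_observations(tracks, trace)
    return cfg, tracks, trace, obs


@pytest.fixture(scope="session")
def uniform_run():
    """Unbiased run (no attraction, no boost) against a full-height filament:
    cell positions are uniform, so distance to the filament is U(0, W/2)."""
    cfg = synthdata.default_flock_config(
        seed=7,
        attraction_strength=0.0,
        speed_boost_factor=1.0,
        n_cells=1500,
        filament_vertices=((100.0, 0.0), (100.0, 200.0)),
        n_frames=150,
        burn_in_s=20.0,
    )
    tracks, trace = synthdata.simulate_flock(cfg)
    return cfg, tracks, trace


@pytest.fixture(scope="session")
def rendered_scene():
    """Small rendered scene with ground truth, for detection/linking tests."""
    cfg = synthdata.default_scene_config(seed=3, n_frames=40)
    tracks, trace = synthdata.simulate_flock(cfg)
    params = synthdata.RenderParams()
    stack = synthdata.render_stack(tracks, trace, params, seed=4)
    truth = tracks.translate(params.pad_um, params.pad_um)
    trace_img = trace.translate(params.pad_um, params.pad_um)
    return cfg, truth, trace_img, stack
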