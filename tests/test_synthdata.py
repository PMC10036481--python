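"""Simulator ground truth: determinism, occupancy laws, rendering, spectra."""

import numpy as np
import pytest
from scipy import stats

from cableflock import geometry, raman, synthdata
from cableflock.synthdata import RenderParams, SimConfig, render_stack, simulate_cut, simulate_flock, synth_raman_pair


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"n_cells": 0},
            {"frame_interval": -0.1},
            {"base_speed_mean": 0.0},
            {"attraction_strength": -1.0},
            {"tumble_rate": 0.0},
        ],
    )
    def test_nonpositive_parameters_rejected(self, overrides):
        with pytest.raises(ValueError):
            synthdata.default_flock_config(**overrides)

    def test_filament_outside_arena_rejected(self):
        with pytest.raises(ValueError):
            synthdata.default_flock_config(filament_vertices=((10.0, 10.0), (250.0, 10.0)))

    def test_cut_time_outside_run_rejected(self):
        with pytest.raises(ValueError):
            synthdata.default_cut_config(cut_time=9999.0)
        with pytest.raises(ValueError):
            simulate_cut(synthdata.default_flock_config())  # no cut_time set

    def test_config_dict_roundtrip(self):
        cfg = synthdata.default_cut_config(seed=5)
        assert SimConfig.from_dict(cfg.to_dict()) == cfg


class TestDynamics:
    def test_same_seed_bit_identical(self):
        a, _ = simulate_flock(synthdata.default_flock_config(seed=3, n_frames=40))
        b, _ = simulate_flock(synthdata.default_flock_config(seed=3, n_frames=40))
        assert a.data.equals(b.data)

    def test_mean_distance_monotone_in_attraction(self):
        means = []
        for a in (0.0, 5.0, 15.0, 30.0):
            cfg = synthdata.default_flock_config(seed=7, attraction_strength=a, n_frames=150)
            tracks, trace = simulate_flock(cfg)
            means.append(geometry.annotate_observations(tracks, trace).distance_um.mean())
        assert all(np.diff(means) < 0)

    def test_attraction_reduces_mean_distance(self, flock_run, uniform_run):
        _, _, _, obs = flock_run
        ucfg, utracks, utrace = uniform_run
        uobs = geometry.annotate_observations(utracks, utrace)
        assert obs.distance_um.mean() < uobs.distance_um.mean()

    def test_unbiased_occupancy_uniform_ks(self, uniform_run):
        """No attraction, no boost: distance to a full-height filament ~ U(0, W/2)."""
        cfg, tracks, _ = uniform_run
        final = tracks.data[tracks.data.frame == tracks.data.frame.max()]
        d = np.abs(final.x_um.to_numpy() - cfg.arena_width / 2)
        p = stats.kstest(d, stats.uniform(0, cfg.arena_width / 2).cdf).pvalue
        assert p > 0.01

    def test_unbiased_occupancy_chi2_pooled(self, uniform_run):
        """Chi-squared flatness of radial occupancy on >= 1e5 pooled observations."""
        cfg, tracks, _ = uniform_run
        sub = tracks.data[tracks.data.frame % 2 == 0]
        d = np.abs(sub.x_um.to_numpy() - cfg.arena_width / 2)
        assert len(d) >= 100_000
        h, _ = np.histogram(d, bins=20, range=(0, cfg.arena_width / 2))
        exp = len(d) / 20
        chi2 = ((h - exp) ** 2 / exp).sum()
        # pooled frames are autocorrelated (~3 s mixing time); test on an
        # effective sample size scaled down accordingly
        n_eff_scale = 0.05
        chi2_eff = chi2 * n_eff_scale
        assert stats.chi2.sf(chi2_eff, 19) > 0.01

    def test_density_profile_peaks_within_20um_and_elevated_to_50(self, flock_run):
        cfg, _, trace, obs = flock_run
        prof = geometry.distance_histogram(obs, bin_width=2.0, max_distance=100.0)
        modal = prof.bin_edges[np.argmax(prof.counts)]
        assert modal < 20.0
        # area-normalized density at 40-50 um exceeds the far field (>70 um)
        length = 100.0  # filament length of the default scene
        dens = geometry.distance_histogram(
            obs, bin_width=10.0, max_distance=100.0, normalize_area=True, filament_length=length
        ).density
        assert dens[4] > 1.2 * dens[7:].mean()

    def test_speed_boost_visible_in_near_zone(self, flock_run):
        _, _, _, obs = flock_run
        near = obs.speed_um_s[obs.distance_um <= 20].mean()
        far = obs.speed_um_s[obs.distance_um > 20].mean()
        assert near > 1.2 * far

    def test_cells_never_cross_filament_surface(self, flock_run):
        cfg, tracks, trace, _ = flock_run
        d, _ = geometry.nearest_on_polyline(
            tracks.data[["x_um", "y_um"]].to_numpy(), trace.keyframes[0]
        )
        assert d.min() >= cfg.filament_radius - 1e-9

    def test_filament_wobble_produces_moving_keyframes(self):
        cfg = synthdata.default_flock_config(seed=1, n_frames=120, filament_wobble_sd=1.0)
        _, trace = simulate_flock(cfg)
        k = list(trace.keyframes.values())
        assert not np.allclose(k[0], k[1])


class TestCut:
    def test_post_cut_density_relaxes_to_area_weighted_uniform(self):
        cfg = synthdata.default_cut_config(seed=2)
        tracks, trace, cut = simulate_cut(cfg)
        obs = geometry.annotate_observations(tracks, trace)
        cut_frame = cut / cfg.frame_interval
        near = obs.distance_um <= 15.0
        pre_rate = (near & (obs.frame < cut_frame)).sum() / cut
        post_window = obs.frame > (cut + 20.0) / cfg.frame_interval  # well after relaxation
        post_rate = (near & post_window).sum() / (cfg.duration - cut - 20.0)
        # uniform occupancy expectation for the 15 um zone around the filament
        zone = 2 * 15.0 * 60.0 + np.pi * 15.0**2
        p_zone = zone / (cfg.arena_width * cfg.arena_height)
        uniform_rate = cfg.n_cells * p_zone / cfg.frame_interval
        assert post_rate < 0.5 * pre_rate          # flock gone
        assert post_rate == pytest.approx(uniform_rate, rel=0.35)

    def test_pre_cut_identical_to_uncut_run(self):
        cut_cfg = synthdata.default_cut_config(seed=4)
        from dataclasses import replace

        uncut_cfg = replace(cut_cfg, cut_time=None)
        a, _, _ = simulate_cut(cut_cfg)
        b, _ = simulate_flock(uncut_cfg)
        cut_frame = int(cut_cfg.cut_time / cut_cfg.frame_interval)
        pre = a.data[a.data.frame <= cut_frame].reset_index(drop=True)
        pre_b = b.data[b.data.frame <= cut_frame].reset_index(drop=True)
        assert pre.equals(pre_b)


class TestRender:
    def test_zero_noise_static_cell_gives_identical_frames(self):
        import pandas as pd

        from cableflock.tracking import TrackSet

        df = pd.DataFrame({"track_id": 0, "frame": [0, 1, 2], "x_um": 30.0, "y_um": 30.0})
        df.attrs["arena"] = (60.0, 60.0)
        tracks = TrackSet(df, frame_interval=0.088)
        trace = geometry.FilamentTrace({0: [(10.0, 5.0), (10.0, 55.0)]})
        stack = render_stack(tracks, trace, RenderParams(noise_sd=0.0))
        assert np.array_equal(stack.frames[0], stack.frames[1])
        assert np.array_equal(stack.frames[1], stack.frames[2])

    def test_empty_trackset_renders_background_and_filament(self):
        import pandas as pd

        from cableflock.tracking import TrackSet

        df = pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"])
        tracks = TrackSet(df, frame_interval=0.088)
        trace = geometry.FilamentTrace({0: [(30.0, 5.0), (30.0, 55.0)]})
        params = RenderParams(noise_sd=0.0)
        stack = render_stack(tracks, trace, params, arena=(60.0, 60.0))
        assert stack.frames.max() == params.background_level
        assert stack.frames.min() == params.background_level - params.filament_dark_level

    def test_render_deterministic_given_seed(self, rendered_scene):
        cfg, truth, _trace, stack = rendered_scene
        assert stack.frames.dtype == np.float32

    def test_warns_when_cells_subpixel(self):
        import pandas as pd

        from cableflock.tracking import TrackSet

        df = pd.DataFrame({"track_id": 0, "frame": [0], "x_um": 10.0, "y_um": 10.0})
        tracks = TrackSet(df, frame_interval=0.1)
        trace = geometry.FilamentTrace({0: [(1.0, 1.0), (1.0, 19.0)]})
        with pytest.warns(UserWarning):
            render_stack(tracks, trace, RenderParams(pixel_size=1.0), arena=(20.0, 20.0))


class TestRamanPairs:
    def test_redox_zero_gives_zero_band_at_zero_noise(self):
        pair = synth_raman_pair(0.0, 0.0, noise_sd=0.0, seed=1)
        assert raman.band_intensity_750(pair.near) == pytest.approx(0.0, abs=1e-9)

    def test_band_monotone_in_redox(self):
        pair = synth_raman_pair(0.2, 0.9, noise_sd=0.0, seed=1)
        assert raman.band_intensity_750(pair.near) < raman.band_intensity_750(pair.far)

    def test_band_linear_in_redox(self):
        vals = [
            raman.band_intensity_750(synth_raman_pair(r, r, noise_sd=0.0, seed=1).near)
            for r in (0.25, 0.5, 1.0)
        ]
        assert vals[1] == pytest.approx(2 * vals[0], rel=1e-9)
        assert vals[2] == pytest.approx(4 * vals[0], rel=1e-9)

    def test_redox_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            synth_raman_pair(-0.1, 0.5)
        with pytest.raises(ValueError):
            synth_raman_pair(0.5, 1.2)

    def test_shared_envelope_passes_qc_independent_fails_more(self):
        shared = [raman.pair_qc(synth_raman_pair(0.3, 0.7, 2.0, seed=s)).passed for s in range(20)]
        assert all(shared)
        indep = [
            raman.pair_qc(synth_raman_pair(0.3, 0.7, 2.0, seed=s, independent_ch=True)).correlation
            for s in range(20)
        ]
        assert np.mean(indep) < np.mean([1.0] * 20)

    def test_paired_test_power_eight_pairs(self):
        hits = 0
        n_seeds = 60
        for s in range(n_seeds):
            pairs = [
                synth_raman_pair(0.3, 0.7, noise_sd=4.0, seed=9000 + 10 * s + i, cell_id=str(i))
                for i in range(8)
            ]
            res = raman.redox_shift_test(raman.apply_qc(pairs))
            hits += res.p_value < 0.05
        assert hits / n_seeds >= 0.9
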