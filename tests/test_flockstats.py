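"""Welch tests, speed grouping, dispersal, sizes and fraction comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cableflock import flockstats, geometry, synthdata, tracking
from cableflock.flockstats import (
    dispersal_time,
    flock_to_cable_ratio,
    fraction_compare,
    size_distribution,
    speed_by_distance,
    welch_t_test,
)


def welch_oracle(a, b):
    """Textbook Welch formula, independent of the implementation path."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_worked_example(self):
        res = welch_t_test([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.22474, abs=1e-5)
        assert res.degrees_of_freedom == pytest.approx(4.0)
        assert res.p_value == pytest.approx(0.28786, abs=1e-5)

    def test_matches_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), rng.integers(3, 40))
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), rng.integers(3, 40))
            res = welch_t_test(a, b)
            t, df, p = welch_oracle(a, b)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.degrees_of_freedom == pytest.approx(df, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_zero_variance_equal_means_p_one(self):
        res = welch_t_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0


class TestSpeedByDistance:
    def _obs(self, seed=0):
        cfg = synthdata.default_flock_config(seed=seed, n_frames=120)
        tracks, trace = synthdata.simulate_flock(cfg)
        return geometry.annotate_observations(tracks, trace)

    def test_near_group_faster_under_boost(self):
        groups, res = speed_by_distance(self._obs())
        assert groups["near"].mean() > groups["far"].mean()
        assert res.p_value < 0.01

    def test_all_three_units_agree_on_direction(self):
        obs = self._obs(seed=1)
        for unit in ("per_cell", "per_cell_exclusive", "per_observation"):
            groups, _ = speed_by_distance(obs, unit=unit)
            assert groups["near"].mean() > groups["far"].mean()

    def test_empty_group_is_informative_error(self):
        obs = pd.DataFrame(
            {"track_id": [0] * 10, "distance_um": np.full(10, 50.0),
             "speed_um_s": np.random.default_rng(0).uniform(10, 20, 10)}
        )
        with pytest.raises(ValueError, match="distance group"):
            speed_by_distance(obs)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            speed_by_distance(self._obs(), unit="per_video")


class TestCalibration:
    def test_type_one_error_calibrated(self):
        """Sharp-null generator: Welch rejection rate stays near alpha."""
        out = flockstats.speed_test_calibration(60, base_seed=7000, boost=1.0)
        assert 0.0 <= out["rejection_rate"] <= 0.12

    def test_power_under_boost(self):
        out = flockstats.speed_test_calibration(15, base_seed=8000, boost=1.4, alpha=0.01)
        assert out["rejection_rate"] >= 0.95


class TestDispersal:
    def _cut_run(self, seed=0, **kw):
        cfg = synthdata.default_cut_config(seed=seed, **kw)
        tracks, trace, cut = synthdata.simulate_cut(cfg)
        return tracking.filter_valid(tracks), trace, cut

    def test_default_run_has_finite_dispersal(self):
        valid, trace, cut = self._cut_run(seed=1)
        res = dispersal_time(valid, trace, cut)
        assert res.defined and 0.0 <= res.dispersal_time < 45.0

    def test_already_clear_zone_gives_zero(self):
        # all cells far from the filament, no attraction: zone clear at cut
        valid, trace, cut = self._cut_run(
            seed=3, attraction_strength=0.001, n_cells=3, burn_in_s=0.0,
            filament_vertices=((150.0, 148.0), (150.0, 152.0)),
        )
        res = dispersal_time(valid, trace, cut, radius=2.0)
        assert res.defined and res.dispersal_time == 0.0

    def test_no_cut_control_is_undefined(self):
        cfg = synthdata.default_cut_config(seed=5)
        from dataclasses import replace

        tracks, trace = synthdata.simulate_flock(replace(cfg, cut_time=None))
        res = dispersal_time(tracking.filter_valid(tracks), trace, cut_time=10.0)
        assert not res.defined and res.dispersal_time is None

    def test_faster_post_cut_motility_disperses_sooner(self):
        """Monotone in post-cut diffusivity on matched seeds."""
        means = []
        for speed in (15.0, 25.0, 40.0):
            ts = []
            for seed in range(4):
                valid, trace, cut = self._cut_run(seed=seed, base_speed_mean=speed)
                r = dispersal_time(valid, trace, cut)
                ts.append(r.dispersal_time if r.defined else 45.0)
            means.append(np.mean(ts))
        assert means[0] > means[1] > means[2]

    def test_no_observations_after_cut_flagged(self):
        df = pd.DataFrame({"track_id": [0, 0], "frame": [0, 1], "x_um": [0.0, 5.0], "y_um": [0.0, 0.0]})
        ts = tracking.TrackSet(df, frame_interval=0.088)
        trace = geometry.FilamentTrace({0: [(0, 10), (10, 10)]})
        res = dispersal_time(ts, trace, cut_time=0.0, sustain_window=1.0)
        assert not res.defined  # recording too short to certify a sustained window


class TestRatioAndSizes:
    def test_ratio_examples(self):
        assert flock_to_cable_ratio(22, 10) == 2.2
        assert flock_to_cable_ratio(7, 7) == 1.0

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            flock_to_cable_ratio(10, 0)

    def test_degenerate_sizes_point_mass(self):
        df = pd.DataFrame({
            "track_id": np.repeat([0, 1], 3), "frame": np.tile([0, 1, 2], 2),
            "x_um": 0.0, "y_um": 0.0, "major_um": 2.0, "minor_um": 1.0,
        })
        ts = tracking.TrackSet(df, frame_interval=0.1)
        with pytest.warns(UserWarning):
            dens = size_distribution(ts)
        assert dens.mode == pytest.approx(1.5)

    def test_simulated_sizes_mode_in_one_to_two_um(self, flock_run):
        _, tracks, _, _ = flock_run
        dens = size_distribution(tracks)
        assert 1.0 <= dens.mode <= 2.0
        np.testing.assert_allclose(np.trapezoid(dens.density, dens.grid), 1.0, atol=0.02)

    def test_bimodal_mixture_recovered(self):
        rng = np.random.default_rng(2)
        sizes = np.r_[rng.normal(1.0, 0.05, 40), rng.normal(2.0, 0.05, 40)]
        rows = []
        for tid, s in enumerate(sizes):
            rows.append({"track_id": tid, "frame": 0, "x_um": 0.0, "y_um": 0.0,
                         "major_um": 1.5 * s, "minor_um": 0.5 * s})
            rows.append({"track_id": tid, "frame": 1, "x_um": 1.0, "y_um": 0.0,
                         "major_um": 1.5 * s, "minor_um": 0.5 * s})
        ts = tracking.TrackSet(pd.DataFrame(rows), frame_interval=0.1)
        modes = size_distribution(ts).modes(min_prominence=0.1)
        assert len(modes) == 2
        assert abs(modes[0] - 1.0) < 0.2 and abs(modes[1] - 2.0) < 0.2


class TestFractionCompare:
    def test_identical_fractions_p_one(self):
        res = fraction_compare([(9, 10), (9, 10)], [(9, 10), (9, 10)])
        assert res.p_value == 1.0

    def test_separated_fractions_significant(self):
        res = fraction_compare([(90, 100), (85, 100), (95, 100)], [(50, 100), (55, 100), (45, 100)])
        assert res.p_value < 0.05

    def test_zero_total_field_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            res = fraction_compare([(9, 10), (8, 10), (0, 0)], [(2, 10), (3, 10)])
        assert res.group_ns == (2, 2)

    def test_single_field_rejected(self):
        with pytest.raises(ValueError):
            fraction_compare([(9, 10)], [(2, 10), (3, 10)])
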