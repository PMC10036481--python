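"""Simulate the default flocking scene and quantify the flock.

Reproduces the core observational analysis on synthetic ground truth:
cells concentrate around the filament (modal distance bin inside 20 µm,
densities still elevated at 40-50 µm) and swim significantly faster
within 20 µm of it (Welch's two-sample t-test). Writes the distance
histogram, the speed comparison and the size density under results/flock/.
"""

import json
from pathlib import Path

import numpy as np

from cableflock import flockstats, geometry, io, synthdata

OUT = Path("results/flock")
OUT.mkdir(parents=True, exist_ok=True)

cfg = synthdata.default_flock_config(seed=1)
tracks, trace = synthdata.simulate_flock(cfg)
obs = geometry.annotate_observations(tracks, trace)
io.write_tracks(OUT / "tracks_truth.csv", tracks)
io.write_keyframes(OUT / "filament_keyframes.csv", trace)
obs.to_csv(OUT / "observations.csv", index=False)

profile = geometry.distance_histogram(obs, bin_width=2.0, max_distance=100.0)
groups, welch = flockstats.speed_by_distance(obs)
sizes = flockstats.size_distribution(tracks)

report = {
    "n_cells": cfg.n_cells,
    "n_observations": int(len(obs)),
    "mean_distance_um": float(obs.distance_um.mean()),
    "modal_bin_um": float(profile.bin_edges[int(np.argmax(profile.counts))]),
    "near_mean_speed_um_s": float(groups["near"].mean()),
    "far_mean_speed_um_s": float(groups["far"].mean()),
    "welch_t": welch.statistic,
    "welch_p": welch.p_value,
    "size_mode_um": sizes.mode,
}
(OUT / "report.json").write_text(json.dumps(report, indent=2))

print(f"flock of {cfg.n_cells} cells, {report['n_observations']} observations")
print(f"  mean distance to filament: {report['mean_distance_um']:.2f} um "
      f"(modal bin starts at {report['modal_bin_um']:.0f} um)")
print(f"  speed within 20 um: {report['near_mean_speed_um_s']:.1f} um/s; "
      f"beyond: {report['far_mean_speed_um_s']:.1f} um/s "
      f"(Welch t = {report['welch_t']:.1f}, p = {report['welch_p']:.2e})")
print(f"  cell-size density mode: {report['size_mode_um']:.2f} um")
print(f"wrote {OUT}/")
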