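"""End-to-end analyses: flock quantification and the cut experiment.

``run_flock_analysis`` chains the stages of the video workflow —
background subtraction, thresholding, particle detection, linking,
track splitting/filtering, filament-distance annotation — and emits the
distance histogram, the near/far speed comparison, and the cell-size
density. ``run_cut_analysis`` runs the same pipeline on a recording with
a cut event and measures the dispersal time. Both are deterministic given
the configuration and seed, write CSV/JSON (and optionally PNG) outputs
into ``config.output_dir``, and embed the config hash for provenance.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, flockstats, geometry, imageproc, io, synthdata, tracking

__all__ = ["run_flock_analysis", "run_cut_analysis"]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _test_result_dict(res: flockstats.TestResult) -> dict:
    return {
        "test": res.test_name,
        "statistic": res.statistic,
        "df": res.degrees_of_freedom,
        "p_value": res.p_value,
        "group_means": list(res.group_means),
        "group_ns": list(res.group_ns),
        "mean_difference": res.mean_difference,
    }


def _acquire(config: io.RunConfig):
    """Produce (tracks, trace, ground_truth_tracks or None) per the config.

    Synthetic runs simulate a scene; with ``render`` the scene is rasterized
    and re-detected through the image pipeline, otherwise ground-truth
    tracks feed the downstream stages directly. File-based runs read the
    stack and keyframes from disk.
    """
    gates = imageproc.DetectionGates(**config.gates)
    link_params = tracking.LinkParams(**config.link)

    if config.simulate:
        sim_cfg = synthdata.default_scene_config(seed=config.seed)
        if config.cut_time is not None:
            sim_cfg = synthdata.default_cut_config(seed=config.seed, cut_time=config.cut_time)
        if config.sim:
            sim_cfg = replace(sim_cfg, **config.sim)
        truth, trace = synthdata.simulate_flock(sim_cfg)
        if not config.render:
            return truth, trace, truth, sim_cfg
        params = synthdata.RenderParams(**config.render_params)
        stack = synthdata.render_stack(truth, trace, params, seed=config.seed + 1)
        # detections live in image coordinates (arena + pad); shift the
        # ground truth and the filament trace to match
        truth = truth.translate(params.pad_um, params.pad_um)
        trace = trace.translate(params.pad_um, params.pad_um)
    else:
        if not config.stack_path or not config.keyframes_path:
            raise ValueError("need stack_path and keyframes_path (or simulate: true)")
        stack = io.read_stack(config.stack_path, config.pixel_size, config.frame_interval)
        trace = io.read_keyframes(config.keyframes_path)
        truth, sim_cfg = None, None

    detections = imageproc.detect_stack(
        stack, gates,
        threshold_method=config.threshold_method,
        manual_threshold=config.manual_threshold,
    )
    linked = tracking.link(detections, link_params, stack.frame_interval, stack.pixel_size)
    linked = tracking.split_tracks(linked, link_params)
    return linked, trace, truth, sim_cfg


def run_flock_analysis(config: io.RunConfig) -> dict:
    """Run the full flock quantification; returns (and writes) the report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracks, trace, truth, sim_cfg = _acquire(config)

    valid = tracking.filter_valid(
        tracks,
        min_span_px=config.min_span_px,
        min_duration_s=config.min_duration_s,
        max_size_dev=config.max_size_dev,
    )
    report: dict = {
        "analysis": "flock",
        "version": __version__,
        "config_hash": config.config_hash,
        "n_tracks_linked": int(tracks.n_tracks),
        "filter": vars(valid.filter_report),
    }
    io.write_tracks(out / "tracks_valid.csv", valid)
    io.write_keyframes(out / "filament_keyframes.csv", trace)

    if valid.n_tracks == 0:
        report["empty_stats"] = True
        (out / "report.json").write_text(json.dumps(_jsonify(report), indent=2))
        return report

    obs = geometry.annotate_observations(valid, trace, config.near_threshold_um)
    obs.to_csv(out / "observations.csv", index=False)

    profile = geometry.distance_histogram(
        obs, bin_width=config.bin_width_um, max_distance=config.max_distance_um
    )
    report["distances"] = {
        "n_observations": int(len(obs)),
        "mean_um": float(obs["distance_um"].mean()),
        "modal_bin_um": [
            float(profile.bin_edges[int(np.argmax(profile.counts))]),
            float(profile.bin_edges[int(np.argmax(profile.counts)) + 1]),
        ],
        "bin_width_um": config.bin_width_um,
        "counts": profile.counts.tolist(),
    }

    speed_tests = {}
    for unit in ("per_cell", "per_observation"):
        try:
            _groups, res = flockstats.speed_by_distance(
                obs, config.near_threshold_um, unit=unit, min_obs=config.min_obs_per_group
            )
            speed_tests[unit] = _test_result_dict(res)
        except ValueError as err:
            speed_tests[unit] = {"error": str(err)}
    report["speed_by_distance"] = speed_tests

    if valid.has_sizes():
        density = flockstats.size_distribution(valid)
        report["size_mode_um"] = float(density.mode)
    else:
        density = None

    if truth is not None:
        truth_obs = geometry.annotate_observations(truth, trace, config.near_threshold_um)
        truth_groups, truth_res = flockstats.speed_by_distance(
            truth_obs, config.near_threshold_um, unit="per_cell", min_obs=config.min_obs_per_group
        )
        report["ground_truth"] = {
            "mean_distance_um": float(truth_obs["distance_um"].mean()),
            "near_far_speed_ratio": float(
                truth_groups["near"].mean() / truth_groups["far"].mean()
            ),
            "n_cells": int(truth.n_tracks),
        }

    if config.make_plots:
        _flock_plots(out, profile, obs, density, config)
    (out / "report.json").write_text(json.dumps(_jsonify(report), indent=2))
    return report


def run_cut_analysis(config: io.RunConfig) -> dict:
    """Run the cut experiment: pre/post-cut windows plus dispersal time."""
    if config.cut_time is None:
        raise ValueError("cut analysis needs cut_time (seconds from recording start)")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracks, trace, truth, sim_cfg = _acquire(config)

    valid = tracking.filter_valid(
        tracks,
        min_span_px=config.min_span_px,
        min_duration_s=config.min_duration_s,
        max_size_dev=config.max_size_dev,
    )
    io.write_tracks(out / "tracks_valid.csv", valid)
    report: dict = {
        "analysis": "cut",
        "version": __version__,
        "config_hash": config.config_hash,
        "cut_time_s": config.cut_time,
        "filter": vars(valid.filter_report),
    }
    if valid.n_tracks == 0:
        report["empty_stats"] = True
        (out / "report.json").write_text(json.dumps(_jsonify(report), indent=2))
        return report

    obs = geometry.annotate_observations(valid, trace, config.near_threshold_um)
    obs.to_csv(out / "observations.csv", index=False)

    cut_frame = config.cut_time / valid.frame_interval
    near = obs["distance_um"] <= config.dispersal_radius_um
    pre = obs["frame"] < cut_frame
    pre_s = max(config.cut_time, 1e-9)
    post_s = max((obs["frame"].max() - cut_frame) * valid.frame_interval, 1e-9)
    report["near_zone"] = {
        "radius_um": config.dispersal_radius_um,
        "pre_count": int((near & pre).sum()),
        "post_count": int((near & ~pre).sum()),
        "pre_rate_per_s": float((near & pre).sum() / pre_s),
        "post_rate_per_s": float((near & ~pre).sum() / post_s),
    }

    disp = flockstats.dispersal_time(
        valid, trace, config.cut_time,
        radius=config.dispersal_radius_um,
        sustain_window=config.sustain_window_s,
        observations=obs,
    )
    report["dispersal"] = {
        "defined": disp.defined,
        "dispersal_time_s": disp.dispersal_time,
        "radius_um": disp.radius,
        "sustain_window_s": disp.sustain_window,
    }
    if config.make_plots:
        _overlay_plot(out, valid, trace, config)
    (out / "report.json").write_text(json.dumps(_jsonify(report), indent=2))
    return report


def _flock_plots(out: Path, profile, obs: pd.DataFrame, density, config) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(profile.bin_centers, profile.counts, width=np.diff(profile.bin_edges), color="#4878a8")
    ax.set_xlabel("distance to filament (µm)")
    ax.set_ylabel("observations")
    fig.tight_layout()
    fig.savefig(out / "distance_histogram.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.2))
    bins = np.arange(0, config.max_distance_um + config.bin_width_um, 2 * config.bin_width_um)
    mid = 0.5 * (bins[:-1] + bins[1:])
    idx = np.digitize(obs["distance_um"], bins) - 1
    means = [
        obs["speed_um_s"][idx == k].mean() if (idx == k).any() else np.nan
        for k in range(len(mid))
    ]
    ax.plot(mid, means, "o-", color="#a85148")
    ax.axvline(config.near_threshold_um, ls="--", c="gray")
    ax.set_xlabel("distance to filament (µm)")
    ax.set_ylabel("mean speed (µm/s)")
    fig.tight_layout()
    fig.savefig(out / "speed_vs_distance.png", dpi=120)
    plt.close(fig)

    if density is not None:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(density.grid, density.density, color="#487a54")
        ax.set_xlabel("mean cell size (µm)")
        ax.set_ylabel("density")
        fig.tight_layout()
        fig.savefig(out / "size_density.png", dpi=120)
        plt.close(fig)


def _overlay_plot(out: Path, tracks, trace, config) -> None:
    """Track overlay in the style of the cut-experiment figure: red swimming
    tracks, black filament polylines every keyframe."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cut_frame = config.cut_time / tracks.frame_interval
    fig, axes = plt.subplots(1, 2, figsize=(9, 4.2), sharex=True, sharey=True)
    for ax, (label, sel) in zip(
        axes,
        [
            ("before cut", tracks.data["frame"] < cut_frame),
            ("after cut", tracks.data["frame"] >= cut_frame),
        ],
    ):
        sub = tracks.data[sel]
        for _, grp in sub.groupby("track_id"):
            ax.plot(grp["x_um"], grp["y_um"], color="red", lw=0.5, alpha=0.6)
        for f in trace.frames:
            poly = trace.keyframes[int(f)]
            ax.plot(poly[:, 0], poly[:, 1], "k.-", lw=1.0, ms=2)
        ax.set_title(label)
        ax.set_aspect("equal")
        ax.set_xlabel("x (µm)")
    axes[0].set_ylabel("y (µm)")
    fig.tight_layout()
    fig.savefig(out / "track_overlay.png", dpi=120)
    plt.close(fig)
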