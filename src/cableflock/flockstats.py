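"""Statistical analyses of the flock: speed vs distance, sizes, dispersal.

The headline comparison is the swimming speed of cells within 20 µm of the
filament versus farther away (Welch's two-sample t-test, two-sided). Speeds
can be aggregated per cell (each track contributes its mean speed to every
distance group in which it has enough observations — the default), per cell
with exclusive majority-group assignment (independent units; used for
calibration experiments), or pooled per observation.

Dispersal time after a laser cut is the elapsed time until no motile
bacterium — i.e. no point of a valid, filtered track — is observed within
15 µm of the filament for a sustained window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry
from .geometry import FilamentTrace
from .tracking import TrackSet

__all__ = [
    "TestResult",
    "DispersalResult",
    "SizeDensity",
    "welch_t_test",
    "speed_by_distance",
    "dispersal_time",
    "flock_to_cable_ratio",
    "size_distribution",
    "fraction_compare",
]


@dataclass
class TestResult:
    """Outcome of a two-group or paired test."""

    statistic: float
    degrees_of_freedom: float
    p_value: float
    group_means: tuple[float, float]
    group_ns: tuple[int, int]
    test_name: str
    mean_difference: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")


def welch_t_test(sample_a, sample_b, name: str = "Welch two-sample t-test (two-sided)") -> TestResult:
    """Welch's two-sample t-test, two-sided.

    ``t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with
    Welch-Satterthwaite degrees of freedom. Each sample needs n >= 2.
    Zero variance in both samples with equal means yields t = 0, p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            return TestResult(0.0, float(a.size + b.size - 2), 1.0,
                              (float(a.mean()), float(b.mean())), (a.size, b.size), name)
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
        group_ns=(int(a.size), int(b.size)),
        test_name=name,
        mean_difference=float(a.mean() - b.mean()),
    )


def speed_by_distance(
    observations: pd.DataFrame,
    threshold_um: float = 20.0,
    unit: str = "per_cell",
    min_obs: int = 5,
) -> tuple[dict[str, np.ndarray], TestResult]:
    """Group speeds by distance to the filament and run the Welch test.

    Parameters
    ----------
    observations
        Annotated observation table (``distance_um``, ``speed_um_s``,
        ``track_id``).
    threshold_um
        Near/far boundary (20 µm: the distance within which cell densities
        and speeds are elevated).
    unit
        ``per_cell`` (default): every track contributes its mean speed to
        each group in which it has at least ``min_obs`` observations, so one
        track may appear in both groups. ``per_cell_exclusive``: each track
        is assigned only to the group holding the majority of its
        observations (independent units across groups). ``per_observation``:
        every observation contributes individually.

    Returns
    -------
    ``({"near": values, "far": values}, TestResult)``; error if either group
    is empty.
    """
    near_mask = observations["distance_um"].to_numpy() <= threshold_um
    speeds = observations["speed_um_s"].to_numpy()
    if unit == "per_observation":
        near = speeds[near_mask]
        far = speeds[~near_mask]
    elif unit in ("per_cell", "per_cell_exclusive"):
        df = observations[["track_id", "speed_um_s"]].copy()
        df["near"] = near_mask
        g = df.groupby(["track_id", "near"])["speed_um_s"].agg(["mean", "size"]).reset_index()
        if unit == "per_cell":
            g = g[g["size"] >= min_obs]
            near = g.loc[g["near"], "mean"].to_numpy()
            far = g.loc[~g["near"], "mean"].to_numpy()
        else:
            # majority assignment: one group per track, ties go to near
            pivot = g.pivot(index="track_id", columns="near", values="size").fillna(0)
            pivot_mean = g.pivot(index="track_id", columns="near", values="mean")
            n_near = pivot.get(True, pd.Series(0, index=pivot.index))
            n_far = pivot.get(False, pd.Series(0, index=pivot.index))
            enough = (n_near + n_far) >= min_obs
            is_near = (n_near >= n_far) & enough
            is_far = (n_far > n_near) & enough
            near = pivot_mean.loc[is_near, True].to_numpy() if True in pivot_mean else np.array([])
            far = pivot_mean.loc[is_far, False].to_numpy() if False in pivot_mean else np.array([])
    else:
        raise ValueError(f"unknown unit {unit!r}")
    if len(near) < 2 or len(far) < 2:
        raise ValueError(
            f"need >= 2 values per distance group, got near={len(near)}, far={len(far)} "
            f"(threshold {threshold_um} um, unit {unit!r})"
        )
    result = welch_t_test(
        near, far, name=f"Welch two-sample t-test (two-sided), speed <= vs > {threshold_um:g} um [{unit}]"
    )
    return {"near": np.asarray(near), "far": np.asarray(far)}, result


@dataclass
class DispersalResult:
    """Dispersal of the flock after a cut.

    ``dispersal_time`` is seconds from the cut until no valid-track
    observation lies within ``radius`` µm of the filament for a whole
    ``sustain_window``; ``None`` (with ``defined=False``) if that never
    happens within the recording.
    """

    cut_time: float
    dispersal_time: float | None
    radius: float = 15.0
    sustain_window: float = 1.0
    defined: bool = True


def dispersal_time(
    tracks: TrackSet,
    trace: FilamentTrace,
    cut_time: float,
    radius: float = 15.0,
    sustain_window: float = 1.0,
    observations: pd.DataFrame | None = None,
) -> DispersalResult:
    """Time after the cut until the flock has dispersed.

    Motility is operationalized as membership in a (filtered) track, so pass
    tracks through the validity filters first; stationary or jittering cells
    then never hold the clock. The first time ``t >= cut_time`` such that no
    observation lies within ``radius`` of the filament throughout
    ``[t, t + sustain_window)`` defines ``dispersal_time = t - cut_time``
    (0 if the zone is already clear at the cut). Only windows fully inside
    the recording count; if none qualifies the result is undefined.
    """
    fi = tracks.frame_interval
    obs = observations if observations is not None else geometry.annotate_observations(tracks, trace)
    if obs.empty:
        return DispersalResult(cut_time, None, radius, sustain_window, defined=False)
    cut_frame = int(np.ceil(cut_time / fi))
    last_frame = int(obs["frame"].max())
    if not (0 <= cut_frame <= last_frame):
        raise ValueError("cut_time outside the observed interval")
    w = max(1, int(np.ceil(sustain_window / fi)))
    near_frames = obs.loc[obs["distance_um"] <= radius, "frame"].to_numpy(dtype=int)
    frames = np.arange(cut_frame, last_frame + 1)
    occupied = np.zeros(frames.size, dtype=bool)
    sel = near_frames[near_frames >= cut_frame]
    occupied[sel - cut_frame] = True
    # first index where the next w frames are all clear
    clear = ~occupied
    if clear.size >= w:
        run = np.convolve(clear.astype(int), np.ones(w, dtype=int), mode="valid")
        hits = np.flatnonzero(run == w)
        if hits.size:
            # elapsed frames from the first frame at/after the cut, so a zone
            # already clear at the cut reports exactly 0
            return DispersalResult(cut_time, int(hits[0]) * fi, radius, sustain_window)
    return DispersalResult(cut_time, None, radius, sustain_window, defined=False)


def flock_to_cable_ratio(n_flock_cells: int, n_cable_cells: int) -> float:
    """Ratio of flocking cells to adjacent cable bacterium cells, 1 decimal."""
    if n_flock_cells <= 0 or n_cable_cells <= 0:
        raise ValueError("counts must be positive")
    return round(n_flock_cells / n_cable_cells, 1)


@dataclass
class SizeDensity:
    """Kernel density estimate of per-track mean cell size."""

    sizes: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    mode: float
    method: str = "kde-silverman"

    def modes(self, min_prominence: float = 0.05) -> np.ndarray:
        """Local maxima of the density above ``min_prominence`` x peak."""
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(self.density, prominence=min_prominence * self.density.max())
        return self.grid[peaks]


def size_distribution(tracks: TrackSet, grid_points: int = 512) -> SizeDensity:
    """Density of per-track mean cell size (mean of major and minor axes).

    Gaussian KDE with Silverman bandwidth; the density integrates to one.
    Fewer than 3 tracks, or degenerate all-equal sizes, fall back to a
    near-point-mass representation with a warning.
    """
    if not tracks.has_sizes():
        raise ValueError("tracks carry no size data")
    sizes = tracks.per_track()["mean_size_um"].to_numpy(dtype=float)
    if sizes.size == 0:
        raise ValueError("no tracks")
    if sizes.size < 3 or np.ptp(sizes) == 0:
        warnings.warn("too few / degenerate sizes: point-mass fallback", stacklevel=2)
        center = float(np.mean(sizes))
        width = max(0.01, 0.01 * center)
        grid = np.linspace(center - 5 * width, center + 5 * width, grid_points)
        dens = stats.norm.pdf(grid, center, width)
        return SizeDensity(sizes, grid, dens, mode=center, method="point-mass fallback")
    kde = stats.gaussian_kde(sizes, bw_method="silverman")
    pad = 3.0 * sizes.std()
    grid = np.linspace(sizes.min() - pad, sizes.max() + pad, grid_points)
    dens = kde(grid)
    return SizeDensity(sizes, grid, dens, mode=float(grid[np.argmax(dens)]))


def fraction_compare(
    counts_near: list[tuple[int, int]],
    counts_far: list[tuple[int, int]],
) -> TestResult:
    """Compare detected fractions per microscope field between two conditions.

    Each entry is ``(detected, total)`` for one field; per-field fractions
    are compared with Welch's t-test (as the hybridization counts were).
    Fields with ``total == 0`` are excluded with a warning; at least two
    usable fields per condition are required.
    """
    def fractions(counts, label):
        out = []
        for det, tot in counts:
            if tot == 0:
                warnings.warn(f"{label}: field with zero total excluded", stacklevel=3)
                continue
            out.append(det / tot)
        return np.array(out)

    near = fractions(counts_near, "near")
    far = fractions(counts_far, "far")
    if near.size < 2 or far.size < 2:
        raise ValueError("need at least 2 usable fields per condition")
    return welch_t_test(near, far, name="Welch two-sample t-test (two-sided), detected fraction near vs far")


def speed_test_replicate(
    seed: int,
    boost: float = 1.0,
    n_cells: int | None = None,
    unit: str = "per_cell",
    edge_margin_um: float = 5.0,
    threshold_um: float = 20.0,
) -> TestResult:
    """One replicate of the speed-test calibration experiment.

    Simulates the calibration scenario (sharp-null generator with the given
    ``boost``; see :func:`cableflock.synthdata.null_calibration_config`),
    annotates observations, excludes those within ``edge_margin_um`` of the
    arena boundary (the field-of-view edge, where measured step lengths are
    unreliable), and runs the Welch speed test.
    """
    from . import synthdata

    overrides = {"speed_boost_factor": boost}
    if n_cells is not None:
        overrides["n_cells"] = n_cells
    cfg = synthdata.null_calibration_config(seed=seed, **overrides)
    tracks, trace = synthdata.simulate_flock(cfg)
    obs = geometry.annotate_observations(tracks, trace, threshold_um)
    m = (
        (obs["x_um"] > edge_margin_um)
        & (obs["x_um"] < cfg.arena_width - edge_margin_um)
        & (obs["y_um"] > edge_margin_um)
        & (obs["y_um"] < cfg.arena_height - edge_margin_um)
    )
    _groups, result = speed_by_distance(obs[m], threshold_um, unit=unit)
    return result


def speed_test_calibration(
    n_runs: int,
    base_seed: int = 0,
    boost: float = 1.0,
    n_cells: int | None = None,
    alpha: float = 0.05,
    unit: str = "per_cell",
) -> dict:
    """Empirical rejection rate of the speed test over replicate simulations.

    With ``boost = 1`` this measures the type-I error (should sit near
    ``alpha``); with ``boost > 1`` it measures power. Seeds are
    ``base_seed .. base_seed + n_runs - 1``.
    """
    rejections = 0
    for i in range(n_runs):
        res = speed_test_replicate(base_seed + i, boost=boost, n_cells=n_cells, unit=unit)
        rejections += res.p_value < alpha
    return {
        "n_runs": n_runs,
        "alpha": alpha,
        "boost": boost,
        "unit": unit,
        "rejection_rate": rejections / n_runs,
    }
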