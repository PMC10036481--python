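"""Detection linking and track validity filtering.

Detections are linked frame-to-frame by greedy mutual-nearest-neighbor
assignment (deterministic, wide-window — emulating how the original videos
were tracked), then cleaned with the study's filtering rules:

- tracks are split where the windowed mean speed changes abruptly
  (tracking jumped between cells),
- tracks that never span more than 50 px on the x- or y-axis are removed
  (Brownian jitter, cells stuck to the glass),
- only tracks longer than 10 s are kept,
- tracks whose apparent cell size differs by more than 20% across the
  track are removed (identity switches between unlike cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["TrackSet", "LinkParams", "FilterReport", "link", "split_on_speed_change", "filter_valid"]

#: columns every track table carries; size/pixel columns are optional extras
CORE_COLUMNS = ["track_id", "frame", "x_um", "y_um"]
SIZE_COLUMNS = ["area_um2", "major_um", "minor_um"]


@dataclass
class TrackSet:
    """A set of cell trajectories in one video's coordinate frame.

    ``data`` holds one row per (track, frame) with at least ``track_id, frame,
    x_um, y_um``; optionally ``area_um2, major_um, minor_um`` (ellipse fit) and
    ``x_px, y_px``. ``pixel_size`` (µm/px) and ``frame_interval`` (s) carry the
    video calibration.
    """

    data: pd.DataFrame
    frame_interval: float
    pixel_size: float | None = None
    filter_report: "FilterReport | None" = field(default=None, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"track table missing columns {missing}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    @property
    def n_tracks(self) -> int:
        return int(self.data["track_id"].nunique())

    def has_sizes(self) -> bool:
        return all(c in self.data.columns for c in ("major_um", "minor_um"))

    def translate(self, dx: float, dy: float) -> "TrackSet":
        """Rigidly shift all track coordinates by (dx, dy) µm."""
        data = self.data.copy()
        data["x_um"] = data["x_um"] + dx
        data["y_um"] = data["y_um"] + dy
        return replace(self, data=data)

    def per_track(self) -> pd.DataFrame:
        """Per-track summary: duration (s), x/y span (µm and px), mean size (µm)."""
        g = self.data.groupby("track_id", sort=False)
        out = pd.DataFrame(
            {
                "n_points": g.size(),
                "first_frame": g["frame"].min(),
                "last_frame": g["frame"].max(),
                "span_x_um": g["x_um"].max() - g["x_um"].min(),
                "span_y_um": g["y_um"].max() - g["y_um"].min(),
            }
        )
        out["duration_s"] = (out["last_frame"] - out["first_frame"]) * self.frame_interval
        if self.pixel_size:
            out["span_x_px"] = out["span_x_um"] / self.pixel_size
            out["span_y_px"] = out["span_y_um"] / self.pixel_size
        if self.has_sizes():
            size = (self.data["major_um"] + self.data["minor_um"]) / 2.0
            out["mean_size_um"] = size.groupby(self.data["track_id"], sort=False).mean()
        return out.reset_index()


@dataclass(frozen=True)
class LinkParams:
    """Linking and splitting parameters.

    ``max_displacement`` is the per-frame search radius in µm (scaled by the
    frame gap when bridging); ``max_gap`` the number of missed frames a track
    survives; ``split_window``/``split_factor`` control the sudden-speed-change
    splitter (windows of ``split_window`` frames; split when adjacent window
    mean speeds differ by more than ``split_factor``-fold).
    """

    max_displacement: float = 10.0
    max_gap: int = 3
    split_window: int = 10
    split_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be positive")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.split_factor <= 1:
            raise ValueError("split_factor must be > 1")


def link(
    detections: pd.DataFrame,
    params: LinkParams,
    frame_interval: float,
    pixel_size: float | None = None,
) -> TrackSet:
    """Link per-frame detections into tracks.

    Frame ``t`` track heads are matched to frame ``t+1`` detections by greedy
    nearest-neighbor assignment in order of increasing distance, within
    ``max_displacement x gap`` µm; unmatched detections start new tracks, and
    tracks missing from up to ``max_gap`` consecutive frames stay eligible.
    Detections are canonically ordered within each frame before matching, so
    the result is invariant to their input order; ties break toward the
    smaller distance, then the earlier track, then the canonical detection
    order.
    """
    cols = [c for c in ["frame", "x_um", "y_um", *SIZE_COLUMNS, "circularity"] if c in detections.columns]
    if not {"frame", "x_um", "y_um"}.issubset(detections.columns):
        raise ValueError("detections need columns frame, x_um, y_um")
    det = detections[cols].sort_values(["frame", "y_um", "x_um"], kind="stable").reset_index(drop=True)
    if det.empty:
        return TrackSet(pd.DataFrame(columns=CORE_COLUMNS), frame_interval, pixel_size)

    next_id = 0
    # active track heads: track_id -> (frame, x, y)
    heads: dict[int, tuple[int, float, float]] = {}
    assigned = np.empty(len(det), dtype=int)

    for f, grp in det.groupby("frame", sort=True):
        f = int(f)
        idx = grp.index.to_numpy()
        pts = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        # candidate heads seen within max_gap+1 frames
        cand = [(tid, hf, hx, hy) for tid, (hf, hx, hy) in heads.items() if 0 < f - hf <= params.max_gap + 1]
        cand.sort(key=lambda c: c[0])
        pairs = []
        for ci, (tid, hf, hx, hy) in enumerate(cand):
            gap = f - hf
            radius = params.max_displacement * gap
            dx = pts[:, 0] - hx
            dy = pts[:, 1] - hy
            dist = np.hypot(dx, dy)
            for di in np.flatnonzero(dist <= radius):
                pairs.append((dist[di], ci, int(di)))
        pairs.sort()
        used_c: set[int] = set()
        used_d: set[int] = set()
        match: dict[int, int] = {}
        for dist, ci, di in pairs:
            if ci in used_c or di in used_d:
                continue
            used_c.add(ci)
            used_d.add(di)
            match[di] = cand[ci][0]
        for di in range(len(idx)):
            if di in match:
                tid = match[di]
            else:
                tid = next_id
                next_id += 1
            assigned[idx[di]] = tid
            heads[tid] = (f, float(pts[di, 0]), float(pts[di, 1]))
        # drop heads that fell out of the gap window (bookkeeping only)
        heads = {tid: h for tid, h in heads.items() if f - h[0] <= params.max_gap + 1}

    out = det.copy()
    out.insert(0, "track_id", assigned)
    out = out.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    return TrackSet(out, frame_interval, pixel_size)


def _step_speeds(track: pd.DataFrame, frame_interval: float) -> np.ndarray:
    d = track.sort_values("frame")
    dx = np.diff(d["x_um"].to_numpy())
    dy = np.diff(d["y_um"].to_numpy())
    dt = np.diff(d["frame"].to_numpy()) * frame_interval
    return np.hypot(dx, dy) / dt


def split_on_speed_change(
    track: pd.DataFrame,
    params: LinkParams,
    frame_interval: float,
) -> list[pd.DataFrame]:
    """Split one track where its windowed mean speed changes suddenly.

    The mean step speed in the ``split_window`` steps before each candidate
    boundary is compared with the mean in the window after; a ratio above
    ``split_factor`` (or below its inverse) splits the track there. Tracks
    shorter than two windows are returned unchanged.
    """
    d = track.sort_values("frame").reset_index(drop=True)
    w = params.split_window
    out: list[pd.DataFrame] = []
    # split at the first trigger, then re-examine the right fragment on its
    # own, so comparison windows never straddle an earlier cut
    while True:
        speeds = _step_speeds(d, frame_interval)
        n = len(speeds)

        def fold_ratio(i: int) -> float:
            left = speeds[i - w:i].mean()
            right = speeds[i:i + w].mean()
            if left <= 0 or right <= 0:
                return 1.0
            r = right / left
            return max(r, 1.0 / r)

        cut = None
        for i in range(w, n - w + 1):
            if fold_ratio(i) > params.split_factor:
                # climb to the local maximum of the change ratio, which sits
                # at the true change point for a clean speed step
                j = i
                while j + 1 <= n - w and fold_ratio(j + 1) >= fold_ratio(j):
                    j += 1
                cut = j
                break
        if cut is None:
            out.append(d)
            break
        out.append(d.iloc[: cut + 1].reset_index(drop=True))
        d = d.iloc[cut + 1:].reset_index(drop=True)
        if len(d) < 2:
            break
    return [fr for fr in out if len(fr) >= 2]


def split_tracks(tracks: TrackSet, params: LinkParams) -> TrackSet:
    """Apply :func:`split_on_speed_change` to every track; fragments get fresh ids."""
    frames = []
    next_id = 0
    for _, grp in tracks.data.groupby("track_id", sort=False):
        for frag in split_on_speed_change(grp, params, tracks.frame_interval):
            frag = frag.copy()
            frag["track_id"] = next_id
            next_id += 1
            frames.append(frag)
    data = pd.concat(frames, ignore_index=True) if frames else tracks.data.iloc[:0].copy()
    return replace(tracks, data=data, filter_report=None)


@dataclass
class FilterReport:
    n_input: int
    removed_span: int
    removed_duration: int
    removed_size: int
    n_kept: int


def filter_valid(
    tracks: TrackSet,
    min_span_px: float = 50.0,
    min_duration_s: float = 10.0,
    max_size_dev: float = 0.20,
) -> TrackSet:
    """Keep only valid tracks, mirroring the study's three filtering rules.

    A track is kept iff (a) it spans more than ``min_span_px`` pixels on the
    x- or y-axis, (b) it lasts longer than ``min_duration_s`` seconds, and
    (c) its per-point mean axis sizes differ by no more than ``max_size_dev``
    across the track (size range relative to the track median; a cell whose
    apparent size jumps from 1.0 to 1.3 µm differs by 30% and is removed).
    Rules apply in order (a), (b), (c); counts removed per rule are recorded
    on the returned set's ``filter_report``. Rule (c) is vacuous for tracks
    without size data.
    """
    if tracks.pixel_size is None or tracks.pixel_size <= 0:
        raise ValueError("filter_valid needs pixel calibration (pixel_size, µm/px)")
    summary = tracks.per_track().set_index("track_id")
    n_input = len(summary)

    span_ok = (
        (summary["span_x_px"] > min_span_px) | (summary["span_y_px"] > min_span_px)
    )
    removed_span = int((~span_ok).sum())
    summary = summary[span_ok]

    dur_ok = summary["duration_s"] > min_duration_s
    removed_duration = int((~dur_ok).sum())
    summary = summary[dur_ok]

    removed_size = 0
    keep_ids = set(summary.index)
    if tracks.has_sizes():
        data = tracks.data[tracks.data["track_id"].isin(keep_ids)]
        size = (data["major_um"] + data["minor_um"]) / 2.0
        by = size.groupby(data["track_id"], sort=False)
        spread = (by.max() - by.min()) / by.median()
        bad_ids = set(spread.index[spread > max_size_dev])
        removed_size = len(bad_ids)
        keep_ids -= bad_ids

    data = tracks.data[tracks.data["track_id"].isin(keep_ids)].reset_index(drop=True)
    report = FilterReport(
        n_input=n_input,
        removed_span=removed_span,
        removed_duration=removed_duration,
        removed_size=removed_size,
        n_kept=len(keep_ids),
    )
    return replace(tracks, data=data, filter_report=report)
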