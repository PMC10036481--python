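"""Filament geometry: keyframed polylines and cell-to-filament distances.

The cable bacterium filament is annotated as a polyline every ``keyframe_spacing``
frames (manual annotation in the original workflow). Between keyframes the
polyline is linearly interpolated vertex-by-vertex; keyframes with unequal
vertex counts are first resampled by arc length to a common count.

Distances are measured from a cell centroid to the filament *centerline*
(minimum distance over all polyline segments); the ~1 µm filament radius is
not subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FilamentTrace",
    "DistanceProfile",
    "resample_polyline",
    "interpolate_filament",
    "distance_to_polyline",
    "annotate_observations",
    "distance_histogram",
    "annulus_band_areas",
]


@dataclass
class FilamentTrace:
    """Per-keyframe polylines describing the filament over time.

    Parameters
    ----------
    keyframes
        Mapping of frame index to an ``(n_vertices, 2)`` array of (x, y)
        vertex coordinates in µm. At least one keyframe with >= 2 vertices.
    keyframe_spacing
        Nominal spacing between annotated frames (50 in the original
        workflow); informational only.
    """

    keyframes: Mapping[int, np.ndarray]
    keyframe_spacing: int = 50
    _frames: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.keyframes) == 0:
            raise ValueError("FilamentTrace needs at least one keyframe")
        clean: dict[int, np.ndarray] = {}
        for f, poly in self.keyframes.items():
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(
                    f"keyframe {f}: polyline must be (n>=2, 2), got {arr.shape}"
                )
            clean[int(f)] = arr
        object.__setattr__(self, "keyframes", clean)
        self._frames = np.array(sorted(clean), dtype=int)

    @property
    def frames(self) -> np.ndarray:
        """Sorted keyframe indices."""
        return self._frames

    def translate(self, dx: float, dy: float) -> "FilamentTrace":
        """Rigidly shift all keyframe polylines by (dx, dy) µm."""
        return FilamentTrace(
            {f: poly + np.array([dx, dy]) for f, poly in self.keyframes.items()},
            keyframe_spacing=self.keyframe_spacing,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f in self._frames:
            poly = self.keyframes[f]
            for i, (x, y) in enumerate(poly):
                rows.append((f, i, x, y))
        return pd.DataFrame(rows, columns=["frame", "vertex_index", "x_um", "y_um"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, keyframe_spacing: int = 50) -> "FilamentTrace":
        required = {"frame", "vertex_index", "x_um", "y_um"}
        if not required.issubset(df.columns):
            raise ValueError(f"keyframe table needs columns {sorted(required)}")
        keyframes = {}
        for f, grp in df.groupby("frame"):
            grp = grp.sort_values("vertex_index")
            keyframes[int(f)] = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        return cls(keyframes, keyframe_spacing=keyframe_spacing)


def resample_polyline(polyline: np.ndarray, n_vertices: int) -> np.ndarray:
    """Resample a polyline to ``n_vertices`` equally spaced by arc length.

    Endpoints are preserved exactly. A degenerate polyline of zero total
    length collapses to repeated copies of its first vertex.
    """
    poly = np.asarray(polyline, dtype=float)
    if n_vertices < 2:
        raise ValueError("n_vertices must be >= 2")
    seg = np.diff(poly, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    if total == 0.0:
        return np.repeat(poly[:1], n_vertices, axis=0)
    target = np.linspace(0.0, total, n_vertices)
    x = np.interp(target, s, poly[:, 0])
    y = np.interp(target, s, poly[:, 1])
    out = np.column_stack([x, y])
    out[0] = poly[0]
    out[-1] = poly[-1]
    return out


def interpolate_filament(trace: FilamentTrace, frame: int) -> np.ndarray:
    """Polyline at ``frame`` by vertex-wise linear interpolation of keyframes.

    Exact keyframes are returned verbatim; frames outside the keyframe range
    clamp to the nearest keyframe. Bounding keyframes with unequal vertex
    counts are arc-length-resampled to the larger count before interpolating.
    """
    frames = trace.frames
    if frame <= frames[0]:
        return trace.keyframes[int(frames[0])].copy()
    if frame >= frames[-1]:
        return trace.keyframes[int(frames[-1])].copy()
    if frame in trace.keyframes:
        return trace.keyframes[int(frame)].copy()
    hi = int(np.searchsorted(frames, frame))
    f0, f1 = int(frames[hi - 1]), int(frames[hi])
    p0, p1 = trace.keyframes[f0], trace.keyframes[f1]
    if len(p0) != len(p1):
        n = max(len(p0), len(p1))
        p0 = resample_polyline(p0, n)
        p1 = resample_polyline(p1, n)
    w = (frame - f0) / (f1 - f0)
    return (1.0 - w) * p0 + w * p1


def distance_to_polyline(points: np.ndarray, polyline: np.ndarray) -> np.ndarray | float:
    """Minimum Euclidean distance from point(s) to a polyline.

    The projection onto each segment is clamped to the segment ends;
    zero-length segments are treated as points.

    Parameters
    ----------
    points
        ``(2,)`` single point or ``(m, 2)`` array, µm.
    polyline
        ``(n >= 2, 2)`` vertex array, µm.

    Returns
    -------
    Scalar for a single point, else ``(m,)`` array of distances in µm.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
        raise ValueError("polyline must be an (n>=2, 2) array")
    a = poly[:-1]                     # (s, 2) segment starts
    d = poly[1:] - a                  # (s, 2) segment vectors
    len2 = np.einsum("ij,ij->i", d, d)  # (s,)
    # t = clamp(((p - a) . d) / |d|^2); zero-length segments -> t = 0
    ap = pts[:, None, :] - a[None, :, :]          # (m, s, 2)
    t = np.einsum("msj,sj->ms", ap, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(len2 > 0.0, t / len2, 0.0)
    t = np.clip(t, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * d[None, :, :]
    diff = pts[:, None, :] - proj
    dist = np.sqrt(np.einsum("msj,msj->ms", diff, diff)).min(axis=1)
    return float(dist[0]) if single else dist


def nearest_on_polyline(points: np.ndarray, polyline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance to the polyline and the nearest polyline point, vectorized.

    Returns ``(dist (m,), nearest (m, 2))`` for ``points`` of shape ``(m, 2)``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(polyline, dtype=float)
    a = poly[:-1]
    d = poly[1:] - a
    len2 = np.einsum("ij,ij->i", d, d)
    ap = pts[:, None, :] - a[None, :, :]
    t = np.einsum("msj,sj->ms", ap, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(len2 > 0.0, t / len2, 0.0)
    t = np.clip(t, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * d[None, :, :]
    diff = pts[:, None, :] - proj
    d2 = np.einsum("msj,msj->ms", diff, diff)
    best = np.argmin(d2, axis=1)
    rows = np.arange(len(pts))
    return np.sqrt(d2[rows, best]), proj[rows, best]


def annotate_observations(
    tracks: "pd.DataFrame | object",
    trace: FilamentTrace,
    near_threshold_um: float = 20.0,
) -> pd.DataFrame:
    """Per-(track, frame) distance-to-filament and instantaneous speed.

    Every track point except the last yields one observation: the distance of
    the point to the filament interpolated at that frame, and the speed of the
    forward step, ``|displacement to next point| / (frame gap x frame_interval)``.

    Accepts a :class:`~cableflock.tracking.TrackSet` or a plain DataFrame with
    columns ``track_id, frame, x_um, y_um`` (then ``frame_interval`` must be
    carried by the TrackSet; a bare DataFrame needs attrs['frame_interval']).

    Returns a DataFrame with columns ``track_id, frame, x_um, y_um,
    distance_um, speed_um_s, within_20um, frame_clamped``.
    """
    df, frame_interval = _tracks_frame(tracks)
    if df.empty:
        return pd.DataFrame(
            columns=[
                "track_id", "frame", "x_um", "y_um",
                "distance_um", "speed_um_s", "within_20um", "frame_clamped",
            ]
        )
    df = df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)

    nxt = df.groupby("track_id", sort=False)[["frame", "x_um", "y_um"]].shift(-1)
    has_next = nxt["frame"].notna().to_numpy()
    obs = df.loc[has_next].reset_index(drop=True)
    nxt = nxt.loc[has_next].reset_index(drop=True)
    gap = (nxt["frame"].to_numpy() - obs["frame"].to_numpy()) * frame_interval
    step = np.hypot(
        nxt["x_um"].to_numpy() - obs["x_um"].to_numpy(),
        nxt["y_um"].to_numpy() - obs["y_um"].to_numpy(),
    )
    speed = step / gap

    frames = obs["frame"].to_numpy(dtype=int)
    pts = obs[["x_um", "y_um"]].to_numpy(dtype=float)
    dist = np.empty(len(obs))
    lo, hi = trace.frames[0], trace.frames[-1]
    clamped = (frames < lo) | (frames > hi)
    for f in np.unique(frames):
        sel = frames == f
        dist[sel] = np.atleast_1d(distance_to_polyline(pts[sel], interpolate_filament(trace, int(f))))

    out = pd.DataFrame(
        {
            "track_id": obs["track_id"].to_numpy(),
            "frame": frames,
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "distance_um": dist,
            "speed_um_s": speed,
            "within_20um": dist <= near_threshold_um,
            "frame_clamped": clamped,
        }
    )
    out.attrs["frame_interval"] = frame_interval
    out.attrs["near_threshold_um"] = near_threshold_um
    return out


def _tracks_frame(tracks) -> tuple[pd.DataFrame, float]:
    """Extract (points DataFrame, frame_interval) from a TrackSet or DataFrame."""
    if hasattr(tracks, "data") and hasattr(tracks, "frame_interval"):
        return tracks.data, float(tracks.frame_interval)
    df = tracks
    fi = df.attrs.get("frame_interval")
    if fi is None:
        raise ValueError(
            "plain DataFrame tracks need attrs['frame_interval'] (seconds per frame)"
        )
    return df, float(fi)


@dataclass
class DistanceProfile:
    """Binned distance-to-filament profile.

    ``counts[k]`` is the number of observations with distance in the half-open
    bin ``[k*bin_width, (k+1)*bin_width)``. If ``area_normalized``, ``density``
    holds counts divided by the area of the corresponding distance band around
    the filament (stadium-shell area: ``2*L*w + pi*(r2^2 - r1^2)``).
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    area_normalized: bool = False
    density: np.ndarray | None = None
    n_overflow: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def annulus_band_areas(bin_edges: np.ndarray, filament_length: float) -> np.ndarray:
    """Area (µm²) of the distance bands around a straight filament of given length.

    The set of points within distance ``r`` of a segment of length ``L`` is a
    stadium of area ``2*L*r + pi*r^2``; band areas are differences of stadiums.
    Arena clipping is ignored.
    """
    e = np.asarray(bin_edges, dtype=float)
    stadium = 2.0 * filament_length * e + np.pi * e**2
    return np.diff(stadium)


def distance_histogram(
    observations: pd.DataFrame | Iterable[float],
    bin_width: float = 2.0,
    max_distance: float = 100.0,
    normalize_area: bool = False,
    filament_length: float | None = None,
) -> DistanceProfile:
    """Histogram of distances to the filament with half-open bins.

    Parameters
    ----------
    observations
        Annotated observation table (uses ``distance_um``) or a distance array.
    bin_width, max_distance
        Bin width and histogram range, µm. Observations beyond ``max_distance``
        are counted in ``n_overflow`` but excluded from bins.
    normalize_area
        Also report density = counts / distance-band area, which is flat for
        spatially uniform occupancy. Requires ``filament_length``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(observations, pd.DataFrame):
        dist = observations["distance_um"].to_numpy(dtype=float)
    else:
        dist = np.asarray(list(observations) if not isinstance(observations, np.ndarray) else observations, dtype=float)
    if dist.size == 0:
        raise ValueError("no observations to histogram")
    n_bins = int(np.ceil(max_distance / bin_width))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    counts, _ = np.histogram(dist, bins=edges)
    overflow = int((dist >= edges[-1]).sum())
    density = None
    if normalize_area:
        if filament_length is None or filament_length <= 0:
            raise ValueError("area normalization needs a positive filament_length")
        areas = annulus_band_areas(edges, filament_length)
        density = counts / areas
    return DistanceProfile(
        bin_edges=edges,
        counts=counts,
        area_normalized=normalize_area,
        density=density,
        n_overflow=overflow,
    )
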