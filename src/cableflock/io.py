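"""File formats: TIFF stacks, track/keyframe/observation CSV, spectra.

CSV dialect is comma-separated UTF-8 with '.' decimal and a mandatory
header row. Spectra are two-column whitespace- or comma-delimited text
(wavenumber cm⁻¹, intensity a.u.). Every writer's output round-trips
through its reader without loss of field values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import FilamentTrace
from .imageproc import ImageStack
from .raman import RamanSpectrum, SpectrumPair
from .tracking import TrackSet

__all__ = [
    "read_stack", "write_stack",
    "read_tracks", "write_tracks",
    "read_keyframes", "write_keyframes",
    "read_spectrum", "write_spectrum", "read_pair_manifest",
    "RunConfig",
]

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a multi-page TIFF; calibration goes into the ImageJ-style
    metadata (µm/px as resolution, frame interval in the description)."""
    frames = stack.frames
    if frames.dtype.kind == "f":
        frames = frames.astype(np.float32)
    tifffile.imwrite(
        str(path),
        frames,
        resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
        metadata={"unit": "um", "finterval": stack.frame_interval, "axes": "TYX"},
        imagej=frames.dtype in (np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.float32)),
    )


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF. Calibration is taken from ImageJ metadata when
    present; explicit arguments override and are required when absent."""
    with tifffile.TiffFile(str(path)) as tif:
        frames = tif.asarray()
        meta = tif.imagej_metadata or {}
        if pixel_size is None:
            page = tif.pages[0]
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                if num:
                    pixel_size = den / num
        if frame_interval is None:
            frame_interval = meta.get("finterval")
    if frames.ndim == 2:
        frames = frames[None]
    if pixel_size is None or frame_interval is None:
        raise ValueError("stack lacks calibration: pass pixel_size and frame_interval")
    return ImageStack(frames, float(pixel_size), float(frame_interval))


def write_tracks(path: str | Path, tracks: TrackSet) -> None:
    df = tracks.data.copy()
    if tracks.pixel_size and "x_px" not in df.columns:
        df["x_px"] = df["x_um"] / tracks.pixel_size
        df["y_px"] = df["y_um"] / tracks.pixel_size
    df.to_csv(path, index=False)


def read_tracks(
    path: str | Path,
    frame_interval: float,
    pixel_size: float | None = None,
) -> TrackSet:
    """Read a track CSV.

    Accepts the full dialect (track_id, frame, x_um, y_um, ...) or a minimal
    4-column dialect ``track_id, frame, x, y`` (coordinates then interpreted
    as µm) for externally produced tracks.
    """
    df = pd.read_csv(path)
    if not set(TRACK_COLUMNS).issubset(df.columns):
        minimal = ["track_id", "frame", "x", "y"]
        if set(minimal).issubset(df.columns):
            df = df.rename(columns={"x": "x_um", "y": "y_um"})
        else:
            raise ValueError(
                f"track CSV needs columns {TRACK_COLUMNS} or {minimal}, got {list(df.columns)}"
            )
    df.attrs["frame_interval"] = frame_interval
    return TrackSet(df, frame_interval=frame_interval, pixel_size=pixel_size)


def write_keyframes(path: str | Path, trace: FilamentTrace) -> None:
    trace.to_dataframe().to_csv(path, index=False)


def read_keyframes(path: str | Path, keyframe_spacing: int = 50) -> FilamentTrace:
    return FilamentTrace.from_dataframe(pd.read_csv(path), keyframe_spacing=keyframe_spacing)


def write_spectrum(path: str | Path, spectrum: RamanSpectrum) -> None:
    np.savetxt(
        str(path),
        np.column_stack([spectrum.wavenumbers, spectrum.intensities]),
        header="wavenumber_cm1 intensity",
        fmt="%.6f",
    )


def read_spectrum(path: str | Path, label: str = "", cell_id: str = "") -> RamanSpectrum:
    """Read a two-column spectrum (whitespace- or comma-delimited)."""
    text = Path(path).read_text()
    delimiter = "," if ("," in text.splitlines()[-1]) else None
    arr = np.loadtxt(str(path), delimiter=delimiter, comments=("#", "wavenumber"))
    return RamanSpectrum(arr[:, 0], arr[:, 1], label=label, cell_id=cell_id)


def read_pair_manifest(path: str | Path) -> list[SpectrumPair]:
    """Read a pair manifest CSV (cell_id, near_path, far_path[, label]);
    paths are resolved relative to the manifest."""
    base = Path(path).parent
    df = pd.read_csv(path)
    required = {"cell_id", "near_path", "far_path"}
    if not required.issubset(df.columns):
        raise ValueError(f"pair manifest needs columns {sorted(required)}")
    pairs = []
    for row in df.itertuples(index=False):
        label = getattr(row, "label", "")
        near = read_spectrum(base / row.near_path, label=label or "near", cell_id=str(row.cell_id))
        far = read_spectrum(base / row.far_path, label=label or "far", cell_id=str(row.cell_id))
        pairs.append(SpectrumPair(near=near, far=far, cell_id=str(row.cell_id)))
    return pairs


@dataclass
class RunConfig:
    """End-to-end analysis configuration.

    Either ``stack_path`` + ``keyframes_path`` point at recorded data, or
    ``simulate`` switches to a fully synthetic run (the ``sim`` dict holds
    :class:`~cableflock.synthdata.SimConfig` overrides). Stage parameters
    mirror the module defaults; every analysis report embeds
    ``config_hash`` for provenance. Unknown keys are rejected.
    """

    output_dir: str = "results/run"
    stack_path: str | None = None
    keyframes_path: str | None = None
    pixel_size: float | None = None
    frame_interval: float | None = None
    simulate: bool = False
    render: bool = True
    sim: dict = field(default_factory=dict)
    render_params: dict = field(default_factory=dict)
    gates: dict = field(default_factory=dict)
    link: dict = field(default_factory=dict)
    threshold_method: str = "otsu"
    manual_threshold: float | None = None
    min_span_px: float = 50.0
    min_duration_s: float = 10.0
    max_size_dev: float = 0.20
    near_threshold_um: float = 20.0
    min_obs_per_group: int = 5
    bin_width_um: float = 2.0
    max_distance_um: float = 100.0
    dispersal_radius_um: float = 15.0
    sustain_window_s: float = 1.0
    cut_time: float | None = None
    seed: int = 0
    make_plots: bool = True

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
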