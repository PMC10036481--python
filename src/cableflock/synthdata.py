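"""Synthetic flocking data with known ground truth.

An agent-based 2-D simulator emulates the observed phenomenology: motile
cells run-and-tumble, are attracted toward a filament with an
exponentially distance-decaying bias, swim faster within a boost radius
(20 µm, matching the distance band in which speeds are elevated), and —
in the cut experiment — lose both attraction and boost at the cut time,
reverting to unbiased run-and-tumble.

Model choices (see docs/methods.md):

- Dynamics are 2-D; the observation chamber is shallow and the original
  tracking was 2-D.
- The attraction is a deterministic drift vector blended into the run
  direction, with the step renormalized to the cell's intrinsic speed:
  attraction steers cells but never changes how fast they swim, so any
  near/far speed difference is caused by ``speed_boost_factor`` alone.
- Swimming speed varies across cells (log-normal) and slowly within a
  cell (Ornstein-Uhlenbeck modulation of log-speed), as real per-track
  speeds do.
- The integration step equals the frame interval; every frame is one step.
- Random draws per step are independent of parameter values, so runs with
  the same seed but different attraction/boost settings see identical
  noise (matched-seed comparisons are meaningful).

The renderer turns ground-truth tracks into noisy phase-contrast-like
frames (dark filament, anisotropic Gaussian cells, Gaussian noise), and
``synth_raman_pair`` produces paired near/far spectra whose 750 cm⁻¹
cytochrome band scales with a known redox fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .geometry import FilamentTrace, interpolate_filament, nearest_on_polyline
from .imageproc import ImageStack
from .raman import RamanSpectrum, SpectrumPair
from .tracking import TrackSet

__all__ = [
    "SimConfig",
    "RenderParams",
    "simulate_flock",
    "simulate_cut",
    "render_stack",
    "synth_raman_pair",
    "default_flock_config",
    "default_cut_config",
    "default_scene_config",
    "null_calibration_config",
]


@dataclass(frozen=True)
class SimConfig:
    """Flock simulation parameters (distances µm, times s, speeds µm/s).

    ``base_speed_mean``/``base_speed_sd`` parameterize the log-normal
    distribution of intrinsic swimming speeds across cells;
    ``speed_jitter_sd``/``speed_jitter_tau`` the within-cell log-speed
    modulation (OU process). ``attraction_strength`` is the drift amplitude
    toward the nearest filament point, decaying as
    ``exp(-distance / attraction_length)``; ``speed_boost_factor``
    multiplies the speed within ``boost_radius``. ``cut_time`` (if set)
    disables attraction and boost from that moment. ``burn_in_s`` is
    simulated but not recorded, so recordings start near the stationary
    state. ``pixel_size`` is the nominal video calibration carried by
    ground-truth tracks (used by the pixel-based span filter and as the
    default render scale).
    """

    arena_width: float = 200.0
    arena_height: float = 200.0
    filament_vertices: tuple[tuple[float, float], ...] = ((100.0, 50.0), (100.0, 150.0))
    n_cells: int = 150
    frame_interval: float = 0.088
    n_frames: int = 342
    base_speed_mean: float = 25.0
    base_speed_sd: float = 3.0
    attraction_strength: float = 15.0
    attraction_length: float = 20.0
    speed_boost_factor: float = 1.4
    boost_radius: float = 20.0
    tumble_rate: float = 1.0
    cut_time: float | None = None
    seed: int = 0
    burn_in_s: float = 10.0
    filament_radius: float = 0.5
    speed_jitter_sd: float = 0.3
    speed_jitter_tau: float = 2.0
    attraction_taper_um: float = 2.5
    filament_wobble_sd: float = 0.0
    keyframe_spacing: int = 50
    cell_length_range: tuple[float, float] = (1.8, 2.8)
    cell_aspect: float = 3.0
    pixel_size: float = 0.2

    def __post_init__(self) -> None:
        positive = [
            ("arena_width", self.arena_width), ("arena_height", self.arena_height),
            ("n_cells", self.n_cells), ("frame_interval", self.frame_interval),
            ("n_frames", self.n_frames), ("base_speed_mean", self.base_speed_mean),
            ("base_speed_sd", self.base_speed_sd), ("attraction_length", self.attraction_length),
            ("boost_radius", self.boost_radius), ("tumble_rate", self.tumble_rate),
            ("filament_radius", self.filament_radius), ("speed_jitter_tau", self.speed_jitter_tau),
            ("cell_aspect", self.cell_aspect), ("pixel_size", self.pixel_size),
        ]
        for name, val in positive:
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if self.attraction_strength < 0 or self.speed_boost_factor <= 0:
            raise ValueError("attraction_strength must be >= 0 and speed_boost_factor > 0")
        if self.speed_jitter_sd < 0 or self.filament_wobble_sd < 0 or self.burn_in_s < 0:
            raise ValueError("speed_jitter_sd, filament_wobble_sd and burn_in_s must be >= 0")
        poly = np.asarray(self.filament_vertices, dtype=float)
        if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
            raise ValueError("filament needs at least 2 (x, y) vertices")
        if (
            poly[:, 0].min() < 0 or poly[:, 0].max() > self.arena_width
            or poly[:, 1].min() < 0 or poly[:, 1].max() > self.arena_height
        ):
            raise ValueError("filament vertices must lie inside the arena")
        if self.cut_time is not None and not (0.0 < self.cut_time < self.duration):
            raise ValueError("cut_time must fall inside the recorded interval")

    @property
    def duration(self) -> float:
        """Recorded duration in seconds."""
        return (self.n_frames - 1) * self.frame_interval

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filament_vertices"] = [list(v) for v in self.filament_vertices]
        d["cell_length_range"] = list(self.cell_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["filament_vertices"] = tuple(tuple(v) for v in d["filament_vertices"])
        d["cell_length_range"] = tuple(d["cell_length_range"])
        return cls(**d)


def _fold(x: np.ndarray, width: float) -> tuple[np.ndarray, np.ndarray]:
    """Reflect coordinates into [0, width]; returns (folded, direction sign)."""
    m = np.mod(x, 2.0 * width)
    over = m > width
    folded = np.where(over, 2.0 * width - m, m)
    sign = np.where(over, -1.0, 1.0)
    return folded, sign


def _filament_keyframes(config: SimConfig, rng: np.random.Generator) -> FilamentTrace:
    base = np.asarray(config.filament_vertices, dtype=float)
    frames = list(range(0, config.n_frames, config.keyframe_spacing))
    if frames[-1] != config.n_frames - 1:
        frames.append(config.n_frames - 1)
    keyframes: dict[int, np.ndarray] = {}
    poly = base.copy()
    for i, f in enumerate(frames):
        if config.filament_wobble_sd > 0 and i > 0:
            poly = poly + rng.normal(0.0, config.filament_wobble_sd, size=poly.shape)
            poly[:, 0] = np.clip(poly[:, 0], 0.0, config.arena_width)
            poly[:, 1] = np.clip(poly[:, 1], 0.0, config.arena_height)
        keyframes[f] = poly.copy()
    return FilamentTrace(keyframes, keyframe_spacing=config.keyframe_spacing)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    var = np.log1p((sd / mean) ** 2)
    return np.log(mean) - 0.5 * var, np.sqrt(var)


def simulate_flock(config: SimConfig) -> tuple[TrackSet, FilamentTrace]:
    """Simulate a flock; returns ground-truth tracks and the filament trace.

    One track per cell, one point per frame. Tracks carry per-cell ellipse
    sizes (constant per cell, drawn from ``cell_length_range`` with aspect
    ratio ``cell_aspect``). Bit-identical for identical config and seed.
    """
    rng = np.random.default_rng(config.seed)
    n, T, dt = config.n_cells, config.n_frames, config.frame_interval

    trace = _filament_keyframes(config, rng)
    static = config.filament_wobble_sd == 0
    poly0 = trace.keyframes[0]

    mu, sigma = _lognormal_params(config.base_speed_mean, config.base_speed_sd)
    s_base = rng.lognormal(mu, sigma, n)
    major = rng.uniform(*config.cell_length_range, n)
    minor = major / config.cell_aspect
    area = np.pi * major * minor / 4.0

    # initial positions: uniform, outside the filament exclusion radius
    pos = np.column_stack(
        [rng.uniform(0, config.arena_width, n), rng.uniform(0, config.arena_height, n)]
    )
    for _ in range(100):
        d, _near = nearest_on_polyline(pos, poly0)
        bad = d < config.filament_radius
        if not bad.any():
            break
        k = int(bad.sum())
        pos[bad] = np.column_stack(
            [rng.uniform(0, config.arena_width, k), rng.uniform(0, config.arena_height, k)]
        )
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    eta = rng.normal(0.0, config.speed_jitter_sd, n) if config.speed_jitter_sd > 0 else np.zeros(n)

    p_tumble = 1.0 - np.exp(-config.tumble_rate * dt)
    ou_alpha = np.exp(-dt / config.speed_jitter_tau)
    ou_sd = config.speed_jitter_sd * np.sqrt(1.0 - ou_alpha**2)
    jitter_corr = -0.5 * config.speed_jitter_sd**2  # E[exp(eta)] = 1

    burn_steps = int(round(config.burn_in_s / dt))
    cut_step = None
    if config.cut_time is not None:
        # recording time of the step's start decides whether attraction is on
        cut_step = burn_steps + int(np.ceil(config.cut_time / dt))

    xs = np.empty((T, n))
    ys = np.empty((T, n))

    def step(i_step: int, frame_for_poly: int) -> None:
        nonlocal pos, theta, eta
        # draws first, in fixed order and count (parameter-independent)
        ou_draw = rng.standard_normal(n)
        tumble_u = rng.random(n)
        tumble_angle = rng.uniform(0.0, 2.0 * np.pi, n)

        if config.speed_jitter_sd > 0:
            eta = eta * ou_alpha + ou_sd * ou_draw
        tumbled = tumble_u < p_tumble
        theta = np.where(tumbled, tumble_angle, theta)

        poly = poly0 if static else interpolate_filament(trace, frame_for_poly)
        dist, nearest = nearest_on_polyline(pos, poly)

        active = cut_step is None or i_step < cut_step
        boost = config.speed_boost_factor if active else 1.0
        attraction = config.attraction_strength if active else 0.0

        s_eff = s_base * np.exp(eta + jitter_corr)
        s_eff = np.where(dist <= config.boost_radius, s_eff * boost, s_eff)

        direction = np.column_stack([np.cos(theta), np.sin(theta)])
        if attraction > 0:
            safe_d = np.maximum(dist, 1e-9)
            to_fil = (nearest - pos) / safe_d[:, None]
            # drift decays with distance and crosses zero a small standoff
            # outside the filament surface (weakly repulsive below it), so
            # cells flock around the filament and contact stays rare and brief
            gap = np.maximum(dist - config.filament_radius, 0.0)
            taper = np.clip(
                -np.expm1(-(gap - config.attraction_taper_um) / config.attraction_taper_um),
                -1.0,
                1.0,
            )
            weight = attraction * np.exp(-dist / config.attraction_length) * taper
            v = s_eff[:, None] * direction + weight[:, None] * to_fil
            norm = np.maximum(np.hypot(v[:, 0], v[:, 1]), 1e-12)
            direction = v / norm[:, None]

        new = pos + direction * (s_eff * dt)[:, None]
        fx, sx = _fold(new[:, 0], config.arena_width)
        fy, sy = _fold(new[:, 1], config.arena_height)
        new = np.column_stack([fx, fy])
        direction = direction * np.column_stack([sx, sy])

        # reflecting boundary at the filament surface: cells approach but do
        # not cross; direction is reflected off the local surface normal so
        # cells bounce instead of sticking
        d2, near2 = nearest_on_polyline(new, poly)
        inside = d2 < config.filament_radius
        if inside.any():
            safe = np.maximum(d2[inside], 1e-9)
            normal = (new[inside] - near2[inside]) / safe[:, None]
            new[inside] = near2[inside] + normal * config.filament_radius
            into = np.einsum("ij,ij->i", direction[inside], normal)
            bounce = direction[inside] - 2.0 * np.minimum(into, 0.0)[:, None] * normal
            direction[inside] = bounce / np.maximum(
                np.hypot(bounce[:, 0], bounce[:, 1]), 1e-12
            )[:, None]
        pos = new
        theta = np.arctan2(direction[:, 1], direction[:, 0])

    for i in range(burn_steps):
        step(i, 0)
    xs[0], ys[0] = pos[:, 0], pos[:, 1]
    for f in range(1, T):
        step(burn_steps + f - 1, f)
        xs[f], ys[f] = pos[:, 0], pos[:, 1]

    frames_col = np.repeat(np.arange(T), n)
    cells_col = np.tile(np.arange(n), T)
    data = pd.DataFrame(
        {
            "track_id": cells_col,
            "frame": frames_col,
            "x_um": xs.ravel(),
            "y_um": ys.ravel(),
            "area_um2": area[cells_col],
            "major_um": major[cells_col],
            "minor_um": minor[cells_col],
        }
    ).sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    data.attrs["frame_interval"] = dt
    data.attrs["arena"] = (config.arena_width, config.arena_height)
    tracks = TrackSet(data, frame_interval=dt, pixel_size=config.pixel_size)
    return tracks, trace


def simulate_cut(config: SimConfig) -> tuple[TrackSet, FilamentTrace, float]:
    """Simulate the laser-cut experiment.

    Identical to :func:`simulate_flock` before ``config.cut_time``; from the
    cut onward, attraction and speed boost are switched off (the attractant
    is gone) and cells revert to unbiased run-and-tumble.
    """
    if config.cut_time is None:
        raise ValueError("simulate_cut needs config.cut_time")
    tracks, trace = simulate_flock(config)
    return tracks, trace, float(config.cut_time)


@dataclass(frozen=True)
class RenderParams:
    """Rendering parameters for synthetic phase-contrast-like frames.

    Cells are anisotropic Gaussian spots (``sigma = axis / 4``) aligned with
    their direction of motion; the filament is a dark band of radius
    ``filament_render_radius``; Gaussian noise with ``noise_sd`` is added.
    ``cell_axes`` (major, minor, µm) is used for all cells unless
    ``use_track_sizes`` and the tracks carry per-cell sizes.
    """

    pixel_size: float = 0.2
    cell_intensity: float = 600.0
    cell_axes: tuple[float, float] = (3.2, 0.8)
    background_level: float = 100.0
    noise_sd: float = 6.0
    filament_dark_level: float = 50.0
    filament_render_radius: float = 1.0
    pad_um: float = 5.0
    use_track_sizes: bool = False

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.cell_axes[1] > self.cell_axes[0]:
            raise ValueError("cell minor axis must not exceed major axis")


def render_stack(
    tracks: TrackSet,
    filament: FilamentTrace,
    params: RenderParams = RenderParams(),
    arena: tuple[float, float] | None = None,
    seed: int = 0,
) -> ImageStack:
    """Render ground-truth tracks into a noisy grayscale stack.

    Each frame is ``background_level`` minus a dark filament band plus one
    Gaussian ellipse per cell plus Gaussian noise; deterministic given
    ``seed``. ``arena`` (width, height, µm) defaults to the simulator's
    arena stored on the track table. The image extends ``params.pad_um``
    beyond the arena on every side so cells at the reflecting arena edge
    are never clipped; image coordinates equal arena coordinates shifted by
    ``pad_um`` (translate the filament trace and ground-truth tracks by
    ``(+pad_um, +pad_um)`` when comparing with detections).
    """
    if arena is None:
        arena = tracks.data.attrs.get("arena")
        if arena is None:
            raise ValueError("arena extent unknown: pass arena=(width, height) in µm")
    width_um, height_um = arena
    px = params.pixel_size
    # pad the image so cells reflecting at the arena edge are never clipped
    # (a clipped blob would report a spurious size); image coordinates are
    # arena coordinates plus pad_um on each axis
    pad = params.pad_um
    W = int(np.ceil((width_um + 2 * pad) / px))
    H = int(np.ceil((height_um + 2 * pad) / px))
    rng = np.random.default_rng(seed)

    data = tracks.data.sort_values(["track_id", "frame"], kind="stable")
    frames_idx = np.sort(data["frame"].unique())
    T = int(frames_idx.max()) + 1 if len(frames_idx) else 1

    use_sizes = params.use_track_sizes and tracks.has_sizes()
    if not use_sizes and params.cell_axes[1] / px < 2.0:
        warnings.warn(
            f"cell minor axis {params.cell_axes[1]:g} µm is < 2 px at {px:g} µm/px; detection may fail",
            stacklevel=2,
        )

    stack = np.full((T, H, W), params.background_level, dtype=np.float32)

    # dark filament band (distance transform only near the polyline)
    yy_c = (np.arange(H) + 0.5) * px - pad
    xx_c = (np.arange(W) + 0.5) * px - pad
    static = len(filament.frames) == 1 or all(
        np.array_equal(filament.keyframes[int(f)], filament.keyframes[int(filament.frames[0])])
        for f in filament.frames
    )

    def dark_mask(poly: np.ndarray) -> np.ndarray:
        margin = params.filament_render_radius + 2.0 * px
        x0 = max(0, int((poly[:, 0].min() - margin + pad) / px))
        x1 = min(W, int(np.ceil((poly[:, 0].max() + margin + pad) / px)))
        y0 = max(0, int((poly[:, 1].min() - margin + pad) / px))
        y1 = min(H, int(np.ceil((poly[:, 1].max() + margin + pad) / px)))
        mask = np.zeros((H, W), dtype=bool)
        if x1 <= x0 or y1 <= y0:
            return mask
        gx, gy = np.meshgrid(xx_c[x0:x1], yy_c[y0:y1])
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        d, _ = nearest_on_polyline(pts, poly)
        mask[y0:y1, x0:x1] = (d <= params.filament_render_radius).reshape(gy.shape)
        return mask

    if static:
        m = dark_mask(filament.keyframes[int(filament.frames[0])])
        stack[:, m] -= params.filament_dark_level
    else:
        for t in range(T):
            m = dark_mask(interpolate_filament(filament, t))
            stack[t, m] -= params.filament_dark_level

    # per-point orientation from the displacement to the next point
    g = data.groupby("track_id", sort=False)
    dx = g["x_um"].diff().shift(-1)
    dy = g["y_um"].diff().shift(-1)
    dx = dx.groupby(data["track_id"], sort=False).ffill().fillna(1.0)
    dy = dy.groupby(data["track_id"], sort=False).ffill().fillna(0.0)
    phi = np.arctan2(dy.to_numpy(), dx.to_numpy())

    xs = (data["x_um"].to_numpy() + pad) / px
    ys = (data["y_um"].to_numpy() + pad) / px
    fr = data["frame"].to_numpy(dtype=int)
    if use_sizes:
        majors = data["major_um"].to_numpy()
        minors = data["minor_um"].to_numpy()
    else:
        majors = np.full(len(data), params.cell_axes[0])
        minors = np.full(len(data), params.cell_axes[1])

    sig_a = majors / 4.0 / px
    sig_b = minors / 4.0 / px
    half = np.ceil(3.0 * sig_a).astype(int)
    cphi, sphi = np.cos(phi), np.sin(phi)

    for i in range(len(data)):
        cx, cy, h = xs[i], ys[i], half[i]
        x0, x1 = int(np.floor(cx)) - h, int(np.floor(cx)) + h + 1
        y0, y1 = int(np.floor(cy)) - h, int(np.floor(cy)) + h + 1
        x0c, x1c = max(0, x0), min(W, x1)
        y0c, y1c = max(0, y0), min(H, y1)
        if x1c <= x0c or y1c <= y0c:
            continue
        lx = np.arange(x0c, x1c) + 0.5 - cx
        ly = np.arange(y0c, y1c) + 0.5 - cy
        gx, gy = np.meshgrid(lx, ly)
        xr = gx * cphi[i] + gy * sphi[i]
        yr = -gx * sphi[i] + gy * cphi[i]
        blob = params.cell_intensity * np.exp(
            -0.5 * ((xr / sig_a[i]) ** 2 + (yr / sig_b[i]) ** 2)
        )
        stack[fr[i], y0c:y1c, x0c:x1c] += blob

    if params.noise_sd > 0:
        for t in range(T):  # per-frame draws keep peak memory low
            stack[t] += rng.normal(0.0, params.noise_sd, size=(H, W)).astype(np.float32)
    return ImageStack(stack, pixel_size=px, frame_interval=tracks.frame_interval)


RAMAN_GRID = np.arange(600.0, 3100.0 + 1e-9, 2.0)
_CH_CENTERS = np.array([2850.0, 2885.0, 2935.0, 2965.0])
_CH_WIDTHS = np.array([12.0, 10.0, 14.0, 10.0])
_CH_BASE_AMPS = np.array([120.0, 80.0, 160.0, 70.0])
#: 750 cm-1 band amplitude at redox fraction 1 (fully reduced), a.u.
BAND_AMP_REDUCED = 120.0


def _base_spectrum(redox: float, ch_amps: np.ndarray) -> np.ndarray:
    wn = RAMAN_GRID
    baseline = 350.0 - 0.04 * (wn - 600.0)  # locally linear: flank median cancels it at 750
    gamma = 8.0
    spectrum = baseline + BAND_AMP_REDUCED * redox * gamma**2 / ((wn - 750.0) ** 2 + gamma**2)
    # weaker companion cytochrome bands, also redox-scaled (outside the 750 windows)
    for center, amp in ((1128.0, 0.35), (1312.0, 0.4), (1585.0, 0.6)):
        spectrum += BAND_AMP_REDUCED * redox * amp * gamma**2 / ((wn - center) ** 2 + gamma**2)
    for c, w, a in zip(_CH_CENTERS, _CH_WIDTHS, ch_amps):
        spectrum += a * np.exp(-0.5 * ((wn - c) / w) ** 2)
    return spectrum


def synth_raman_pair(
    redox_near: float,
    redox_far: float,
    noise_sd: float = 2.0,
    seed: int = 0,
    cell_id: str = "",
    independent_ch: bool = False,
) -> SpectrumPair:
    """Paired near/far spectra of one cell with known redox fractions.

    Redox fraction 1 = fully reduced cytochromes (maximal 750 cm⁻¹ band),
    0 = fully oxidized (no band). Both spectra share the same C-H envelope
    (2800-3000 cm⁻¹) so the pair passes quality control, unless
    ``independent_ch`` redraws the far envelope. The local baseline is
    linear across 735-765 cm⁻¹, so at zero noise the normalized band
    intensity is exactly proportional to the redox fraction (zero at
    redox 0; the proportionality constant is below ``BAND_AMP_REDUCED``
    because the flank windows catch part of the Lorentzian tails).
    """
    for name, r in (("redox_near", redox_near), ("redox_far", redox_far)):
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    rng = np.random.default_rng(seed)
    ch = _CH_BASE_AMPS * rng.uniform(0.8, 1.2, size=4)
    ch_far = _CH_BASE_AMPS * rng.uniform(0.5, 1.5, size=4) if independent_ch else ch
    near_i = _base_spectrum(redox_near, ch)
    far_i = _base_spectrum(redox_far, ch_far)
    if noise_sd > 0:
        near_i = near_i + rng.normal(0.0, noise_sd, size=near_i.shape)
        far_i = far_i + rng.normal(0.0, noise_sd, size=far_i.shape)
    near = RamanSpectrum(RAMAN_GRID.copy(), near_i, label="near", cell_id=cell_id)
    far = RamanSpectrum(RAMAN_GRID.copy(), far_i, label="far", cell_id=cell_id)
    return SpectrumPair(near=near, far=far, cell_id=cell_id)


def default_flock_config(seed: int = 0, **overrides) -> SimConfig:
    """The default flocking scene: the study conditions for density/speed
    analyses (200x200 µm arena, 100 µm filament, 150 cells, 30 s at
    0.088 s/frame, boost 1.4 within 20 µm)."""
    return replace(SimConfig(seed=seed), **overrides)


def default_cut_config(seed: int = 0, **overrides) -> SimConfig:
    """The default cut experiment: flock forms during burn-in and 10 s of
    recording, the filament is cut, and dispersal is observed for 45 s more.
    Calibrated once so that mean dispersal time falls in the 10-15 s band."""
    cfg = SimConfig(
        arena_width=300.0,
        arena_height=300.0,
        filament_vertices=((150.0, 120.0), (150.0, 180.0)),
        n_cells=35,
        n_frames=625,  # ~55 s at 0.088 s
        cut_time=10.0,
        seed=seed,
    )
    return replace(cfg, **overrides)


def default_scene_config(seed: int = 0, **overrides) -> SimConfig:
    """The default rendered scene for end-to-end (render -> detect -> track
    -> stats) recovery: moderate density so detection and linking stay
    reliable, 16 s of video."""
    cfg = SimConfig(
        arena_width=160.0,
        arena_height=160.0,
        filament_vertices=((80.0, 40.0), (80.0, 120.0)),
        n_cells=50,
        n_frames=182,  # ~16 s
        attraction_strength=4.0,
        burn_in_s=8.0,
        seed=seed,
    )
    return replace(cfg, **overrides)


def null_calibration_config(seed: int = 0, **overrides) -> SimConfig:
    """Null configuration for speed-test calibration: no speed boost
    (factor 1), attraction as in the defaults, short 8 s recording.

    The scenario is built so that the sharp null — near and far speeds
    identically distributed — actually holds: between-cell speed spread is
    nearly off (``base_speed_sd`` 0.5) and the within-cell speed modulation
    is memoryless (``speed_jitter_tau`` far below the frame interval),
    because persistent speed differences interact with the attraction —
    slower swimmers are steered more effectively and accumulate near the
    filament — making near/far speeds genuinely different even without any
    speed boost (see docs/methods.md). Memoryless jitter supplies the
    unit-level variance without that confound.
    """
    cfg = SimConfig(
        speed_boost_factor=1.0,
        n_frames=92,
        base_speed_sd=0.5,
        speed_jitter_tau=0.005,
        seed=seed,
    )
    return replace(cfg, **overrides)
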