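"""Stimulus generation in calibrated photoisomerization units.

Everything downstream consumes :class:`StimulusMovie` objects: height x
width x time arrays of intensity in R*/cone/s, with spatial calibration in
micrometers per pixel and a photopic background (default 4000 R*/s for M/L
cones).  Stimuli are confined to a circular aperture over the receptive
field center; pixels outside the aperture sit at the background.

Provided stimulus classes: contrast-reversing and flashed square-wave
gratings, uniform spots, linear-equivalent discs of image patches,
random-walk + saccade eye trajectories, and eye-movement movies rendered
from static images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BACKGROUND = 4000.0  # R*/cone/s, photopic
DEFAULT_FRAME_DT = 1.0 / 60.0  # s, monitor refresh
DEFAULT_CONE_SPACING_UM = 3.0

__all__ = [
    "StimulusMovie",
    "CenterRF",
    "EyeTrajectoryParams",
    "Trajectory",
    "make_grating",
    "make_spot",
    "center_weights",
    "linear_equivalent_value",
    "linear_equivalent_disc",
    "simulate_eye_trajectory",
    "render_movie",
    "DEFAULT_BACKGROUND",
    "DEFAULT_FRAME_DT",
    "DEFAULT_CONE_SPACING_UM",
]


@dataclass
class StimulusMovie:
    """Space x time intensity array: frames (H, W, T) in R*/cone/s."""

    frames: np.ndarray
    dt_frame: float = DEFAULT_FRAME_DT
    pixel_pitch: float = DEFAULT_CONE_SPACING_UM
    background: float = DEFAULT_BACKGROUND

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (height, width, time)")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def duration(self) -> float:
        return self.frames.shape[2] * self.dt_frame

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frames.shape[2]) * self.dt_frame


@dataclass
class CenterRF:
    """Receptive field center geometry.

    ``sigma_c`` is the Gaussian SD of the center (um); the circular aperture
    confining stimuli defaults to a diameter of twice the SD of the center
    fit, matching how apertures are matched to recorded cells.
    """

    sigma_c: float = 60.0
    center_xy: tuple = (0.0, 0.0)
    aperture_diameter: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_c <= 0:
            raise ValueError("sigma_c must be > 0")
        if self.aperture_diameter is None:
            self.aperture_diameter = 2.0 * self.sigma_c

    @property
    def aperture_radius(self) -> float:
        return self.aperture_diameter / 2.0


def _grid_um(rf: CenterRF, pixel_pitch: float) -> tuple:
    """Pixel-center coordinates (um) of a square grid covering the aperture."""
    n = int(np.ceil(rf.aperture_diameter / pixel_pitch))
    if n % 2:
        n += 1  # even grid keeps split fields exactly balanced
    coords = (np.arange(n) - (n - 1) / 2.0) * pixel_pitch
    x = coords[None, :] + rf.center_xy[0]
    y = coords[:, None] + rf.center_xy[1]
    return x, y, n


def aperture_mask(rf: CenterRF, pixel_pitch: float) -> np.ndarray:
    x, y, _ = _grid_um(rf, pixel_pitch)
    r2 = (x - rf.center_xy[0]) ** 2 + (y - rf.center_xy[1]) ** 2
    return r2 <= rf.aperture_radius ** 2


def center_weights(rf: CenterRF, pixel_pitch: float) -> np.ndarray:
    """Unit-height Gaussian center weights restricted to the aperture (H, W)."""
    x, y, _ = _grid_um(rf, pixel_pitch)
    r2 = (x - rf.center_xy[0]) ** 2 + (y - rf.center_xy[1]) ** 2
    w = np.exp(-r2 / (2.0 * rf.sigma_c ** 2))
    w[~aperture_mask(rf, pixel_pitch)] = 0.0
    return w


def make_grating(
    kind: str,
    contrast: float,
    temporal_freq: float,
    bar_width: float,
    rf: CenterRF,
    duration: float,
    phase: float = 0.0,
    pixel_pitch: float = DEFAULT_CONE_SPACING_UM,
    dt_frame: float = DEFAULT_FRAME_DT,
    background: float = DEFAULT_BACKGROUND,
    flash_window: tuple = (0.0, None),
) -> StimulusMovie:
    """Square-wave grating confined to the aperture.

    ``kind='contrast_reversing'``: intensity(x, t) = B (1 + c g(x) sin(2 pi f t)),
    starting at sine phase 0 so the first frame is uniform background.
    ``kind='flashed'``: B (1 + c g(x)) held during ``flash_window``
    (start, end in s; end defaults to the movie end), background otherwise.

    ``g`` is a +/-1 square wave of the given ``bar_width`` (um, spatial
    ``phase`` in radians of one spatial period), corrected to have exactly
    zero mean over the aperture.  A split-field grating is the special case
    ``bar_width = rf.aperture_radius``.
    """
    if not 0 < contrast <= 1:
        raise ValueError("contrast must be in (0, 1]")
    if bar_width > rf.aperture_diameter:
        raise ValueError("bar_width exceeds the aperture")
    x, y, n = _grid_um(rf, pixel_pitch)
    mask = aperture_mask(rf, pixel_pitch)
    xr = np.broadcast_to(x - rf.center_xy[0], (n, n))
    g = np.sign(np.sin(np.pi * xr / bar_width + phase + 1e-12))
    g = np.where(g == 0, 1.0, g)
    # enforce exact zero spatial mean over the aperture
    g = g - g[mask].mean()
    g[~mask] = 0.0

    n_frames = int(round(duration / dt_frame))
    t = np.arange(n_frames) * dt_frame
    if kind == "contrast_reversing":
        temporal = np.sin(2.0 * np.pi * temporal_freq * t)
    elif kind == "flashed":
        t0, t1 = flash_window
        if t1 is None:
            t1 = duration
        temporal = ((t >= t0 - 1e-12) & (t < t1 - 1e-12)).astype(float)
    else:
        raise ValueError("kind must be 'contrast_reversing' or 'flashed'")
    frames = background * (1.0 + contrast * g[:, :, None] * temporal[None, None, :])
    return StimulusMovie(frames, dt_frame=dt_frame, pixel_pitch=pixel_pitch, background=background)


def make_spot(
    contrast: float,
    temporal: tuple,
    rf: CenterRF,
    duration: float,
    pixel_pitch: float = DEFAULT_CONE_SPACING_UM,
    dt_frame: float = DEFAULT_FRAME_DT,
    background: float = DEFAULT_BACKGROUND,
    flash_window: tuple = (0.0, None),
) -> StimulusMovie:
    """Spatially uniform disc within the aperture.

    ``temporal`` is ``('step',)`` for a contrast step held during
    ``flash_window`` or ``('sinusoid', f)`` for sinusoidal modulation at
    ``f`` Hz starting at phase 0.
    """
    if abs(contrast) > 1:
        raise ValueError("|contrast| must be <= 1")
    mask = aperture_mask(rf, pixel_pitch).astype(float)
    n_frames = int(round(duration / dt_frame))
    t = np.arange(n_frames) * dt_frame
    if temporal[0] == "step":
        t0, t1 = flash_window
        if t1 is None:
            t1 = duration
        mod = ((t >= t0 - 1e-12) & (t < t1 - 1e-12)).astype(float)
    elif temporal[0] == "sinusoid":
        mod = np.sin(2.0 * np.pi * temporal[1] * t)
    else:
        raise ValueError("temporal must be ('step',) or ('sinusoid', f)")
    frames = background * (1.0 + contrast * mask[:, :, None] * mod[None, None, :])
    return StimulusMovie(frames, dt_frame=dt_frame, pixel_pitch=pixel_pitch, background=background)


def linear_equivalent_value(patch: np.ndarray, rf: CenterRF,
                            pixel_pitch: float = DEFAULT_CONE_SPACING_UM) -> float:
    """RF-center-weighted mean intensity of a patch (R*/s).

    The weight is a unit-height Gaussian of SD ``sigma_c`` restricted to the
    aperture; the patch must cover the aperture grid.
    """
    patch = np.asarray(patch, dtype=float)
    w = center_weights(rf, pixel_pitch)
    if patch.shape != w.shape:
        raise ValueError(f"patch shape {patch.shape} must match aperture grid {w.shape}")
    return float(np.sum(w * patch) / np.sum(w))


def linear_equivalent_disc(patch: np.ndarray, rf: CenterRF,
                           pixel_pitch: float = DEFAULT_CONE_SPACING_UM,
                           background: float = DEFAULT_BACKGROUND) -> np.ndarray:
    """Spatially uniform disc with the patch's RF-weighted mean intensity.

    A spatially linear Gaussian-RF model responds identically to the patch
    and to this disc -- the defining invariant of the linear-equivalent
    stimulus.
    """
    v = linear_equivalent_value(patch, rf, pixel_pitch)
    mask = aperture_mask(rf, pixel_pitch)
    disc = np.full_like(np.asarray(patch, dtype=float), background)
    disc[mask] = v
    return disc


@dataclass
class EyeTrajectoryParams:
    """Random-walk + saccade model of fixational eye movements.

    Between saccades the gaze performs a discrete random walk: every
    ``step_dt`` (default 1 ms) each coordinate independently moves by
    +/- ``step_size`` cone spacings with equal probability.  Every
    ``saccade_interval`` (default 300 ms, first at t = saccade_interval) both
    coordinates additionally jump by independent draws from the uniform
    distribution on [-jump_range, +jump_range] cone spacings.
    """

    step_dt: float = 1e-3
    step_size: float = 1.0
    saccade_interval: float = 0.3
    jump_range: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_dt <= 0:
            raise ValueError("step_dt must be > 0")
        ratio = self.saccade_interval / self.step_dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("saccade_interval must be a multiple of step_dt")


@dataclass
class Trajectory:
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    saccade_flags: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


def simulate_eye_trajectory(duration: float, params: EyeTrajectoryParams) -> Trajectory:
    """Sample a fixational eye-movement trajectory (positions in cone spacings)."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(params.seed)
    n = int(round(duration / params.step_dt))
    times = np.arange(n + 1) * params.step_dt
    steps = rng.choice((-params.step_size, params.step_size), size=(n, 2))
    sacc_every = int(round(params.saccade_interval / params.step_dt))
    flags = np.zeros(n + 1, dtype=bool)
    idx = np.arange(1, n + 1)
    flags[idx[idx % sacc_every == 0]] = True
    jumps = np.zeros((n + 1, 2))
    n_sacc = int(flags.sum())
    jumps[flags] = rng.uniform(-params.jump_range, params.jump_range, size=(n_sacc, 2))
    pos = np.zeros((n + 1, 2))
    pos[1:] = np.cumsum(steps, axis=0)
    pos += np.cumsum(jumps, axis=0)
    return Trajectory(times=times, x=pos[:, 0], y=pos[:, 1], saccade_flags=flags)


def render_movie(
    image: np.ndarray,
    traj: Trajectory,
    rf: CenterRF,
    frame_dt: float = DEFAULT_FRAME_DT,
    pixel_pitch: float = DEFAULT_CONE_SPACING_UM,
    cone_spacing_um: float = DEFAULT_CONE_SPACING_UM,
    background: float = DEFAULT_BACKGROUND,
) -> StimulusMovie:
    """Translate an image behind the aperture along an eye trajectory.

    The image is linearly scaled so its mean maps to ``background`` (negative
    values clipped at zero with a logged count); translations use the
    nearest-sample policy (integer-pixel shifts; trajectories are in integer
    cone spacings anyway).  The image is reflect-padded by the saccade jump
    range plus the expected diffusion drift; a trajectory exceeding the pad
    raises an error naming the time of exit.
    """
    image = np.asarray(image, dtype=float)
    mean = image.mean()
    if mean <= 0:
        raise ValueError("image mean must be positive for intensity calibration")
    scaled = image * (background / mean)
    n_neg = int(np.sum(scaled < 0))
    if n_neg:
        logger.info("clipping %d negative pixels to 0 during calibration", n_neg)
        scaled = np.clip(scaled, 0.0, None)

    x, ygrid, n = _grid_um(rf, pixel_pitch)
    mask = aperture_mask(rf, pixel_pitch)
    half = n // 2

    # frame-time sampling of the trajectory (nearest sample)
    n_frames = max(int(round(traj.times[-1] / frame_dt)), 1)
    t_frames = np.arange(n_frames) * frame_dt
    ti = np.clip(np.round(t_frames / (traj.times[1] - traj.times[0])).astype(int), 0, len(traj.times) - 1)
    px_per_cone = cone_spacing_um / pixel_pitch
    dx = np.round(traj.x[ti] * px_per_cone).astype(int)
    dy = np.round(traj.y[ti] * px_per_cone).astype(int)

    duration = traj.times[-1]
    step_rate = 1.0 / 1e-3
    drift = 3.0 * np.sqrt(max(duration, 1e-9) * step_rate)
    pad = int(np.ceil((100.0 + drift) * px_per_cone)) + half + 1
    padded = np.pad(scaled, pad, mode="reflect")
    cy = pad + image.shape[0] // 2
    cx = pad + image.shape[1] // 2

    frames = np.empty((n, n, n_frames))
    for k in range(n_frames):
        r0 = cy + dy[k] - half
        c0 = cx + dx[k] - half
        if r0 < 0 or c0 < 0 or r0 + n > padded.shape[0] or c0 + n > padded.shape[1]:
            raise ValueError(f"trajectory exits the padded image at t={t_frames[k]:.3f} s")
        win = padded[r0:r0 + n, c0:c0 + n]
        frames[:, :, k] = np.where(mask, win, background)
    return StimulusMovie(frames, dt_frame=frame_dt, pixel_pitch=pixel_pitch, background=background)
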