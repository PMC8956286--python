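"""Synthetic inputs with controlled statistics.

Natural-image stand-ins are Gaussian random fields with a 1/f^alpha power
spectrum pushed through a monotone histogram transform to a target pixel
skewness -- the two statistics this work actually depends on (spatial
correlation structure and the relative abundance of dark pixels).  Also
provided: template inhibitory response time courses (alpha-function
feedforward / crossover / mixed shapes) for exercising the clustering
layer, and noisy multi-trial "recordings" from a ground-truth subunit
model for exercising the statistics layer.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .stimuli import CenterRF, linear_equivalent_disc
from .subunits import SubunitModelConfig, run_ei_static

logger = logging.getLogger(__name__)

__all__ = [
    "ImageGenSpec",
    "RecordingSet",
    "make_image",
    "sample_patches",
    "make_template_traces",
    "make_recordings",
]


@dataclass
class ImageGenSpec:
    """Recipe for a natural-image-like field.

    ``spectrum_exponent`` is the power-spectrum slope (power ~ 1/f^alpha,
    alpha = 2 for natural scenes); ``pixel_skew_target`` <= 0 makes dark
    pixels over-abundant as in natural images (0 gives the symmetric
    Gaussian-noise control); ``rms_contrast`` sets SD/mean, matched to the
    ~0.3 average spatial contrast of probed natural patches.
    """

    size: int = 256
    spectrum_exponent: float = 2.0
    pixel_skew_target: float = -0.5
    mean_level: float = 4000.0
    rms_contrast: float = 0.35
    seed: int = 0


def _skewness(x: np.ndarray) -> float:
    x = x - x.mean()
    s = x.std()
    if s == 0:
        return 0.0
    return float(np.mean(x ** 3) / s ** 3)


def _skew_transform(z: np.ndarray, lam: float) -> np.ndarray:
    """Monotone map with tunable skew: lam < 0 stretches the dark tail."""
    if abs(lam) < 1e-12:
        return z
    return (np.exp(lam * z) - 1.0) / lam


def make_image(spec: ImageGenSpec) -> np.ndarray:
    """Generate one image (R*/s) with the requested spectrum and skew.

    The spectral field is standardized, monotonically transformed to hit
    ``pixel_skew_target`` within +/-0.1 (a bisection on the transform's
    shape parameter), rescaled to ``mean_level`` and ``rms_contrast``, and
    clipped at zero.  More than 1% clipped pixels raises an error.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    white = rng.standard_normal((n, n))
    fx = np.fft.fftfreq(n)[None, :]
    fy = np.fft.fftfreq(n)[:, None]
    f = np.sqrt(fx ** 2 + fy ** 2)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** (-spec.spectrum_exponent / 2.0)
    field = np.real(np.fft.ifft2(np.fft.fft2(white) * amp))
    z = (field - field.mean()) / field.std()

    target = spec.pixel_skew_target
    lo, hi = -6.0, 6.0
    achieved = _skewness(z)
    if abs(achieved - target) > 0.1:
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            s = _skewness(_skew_transform(z, mid))
            if s > target:
                hi = mid
            else:
                lo = mid
        lam = 0.5 * (lo + hi)
        z = _skew_transform(z, lam)
        achieved = _skewness(z)
        if abs(achieved - target) > 0.1:
            raise ValueError(
                f"skew target {target} unattainable; achieved {achieved:.3f}")
    z = (z - z.mean()) / z.std()
    img = spec.mean_level * (1.0 + spec.rms_contrast * z)
    n_clip = int(np.sum(img < 0))
    frac = n_clip / img.size
    if frac >= 0.01:
        raise ValueError(f"clipping {frac:.1%} of pixels; lower rms_contrast or raise skew target")
    if n_clip:
        logger.info("make_image: clipped %d pixels (%.3f%%)", n_clip, 100 * frac)
        img = np.clip(img, 0.0, None)
    return img


def sample_patches(
    image: np.ndarray,
    rf: CenterRF,
    n_patches: int,
    pixel_pitch: float = 3.0,
    seed: int = 0,
    require_bright: bool = False,
    background: float | None = None,
) -> list:
    """Cut aperture-sized patches from an image at random locations.

    With ``require_bright`` only patches whose RF-weighted mean exceeds the
    background are kept (mirroring the selection of patches that actually
    drive On-cell spiking); the image mean serves as background by default.
    """
    from .stimuli import linear_equivalent_value

    rng = np.random.default_rng(seed)
    if background is None:
        background = float(image.mean())
    npx = int(np.ceil(rf.aperture_diameter / pixel_pitch))
    if npx % 2:
        npx += 1
    H, W = image.shape
    if H < npx or W < npx:
        raise ValueError("image smaller than the aperture")
    patches = []
    attempts = 0
    while len(patches) < n_patches and attempts < 200 * n_patches:
        attempts += 1
        r = rng.integers(0, H - npx + 1)
        c = rng.integers(0, W - npx + 1)
        patch = image[r:r + npx, c:c + npx]
        if require_bright and linear_equivalent_value(patch, rf, pixel_pitch) <= background:
            continue
        patches.append(np.asarray(patch, dtype=float))
    if len(patches) < n_patches:
        raise RuntimeError("could not find enough qualifying patches")
    return patches


def _alpha(t: np.ndarray, t0: float, tau: float) -> np.ndarray:
    """Alpha function, unit peak at t0 + tau."""
    u = np.clip((t - t0) / tau, 0.0, None)
    return u * np.exp(1.0 - u)


def make_template_traces(
    n_per: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 1e-3,
    duration: float = 0.6,
    flash_dur: float = 0.25,
    crossover_gain: float = 2.0,
) -> tuple:
    """Template inhibitory time courses for the three response classes.

    ``feedforward``: fast transient locked to stimulus onset; ``crossover``:
    larger (by ``crossover_gain``), delayed transient locked to stimulus
    offset; ``mixed``: scaled sum, smaller in amplitude.  Returns
    (traces (3 n_per, T), labels, templates dict).
    """
    t = np.arange(int(round(duration / dt))) * dt
    ff = _alpha(t, 0.03, 0.045)
    cr = crossover_gain * _alpha(t, flash_dur + 0.02, 0.06)
    mixed = 0.35 * (ff + cr)
    templates = {"feedforward": ff, "crossover": cr, "mixed": mixed}
    rng = np.random.default_rng(seed)
    traces, labels = [], []
    for name in ("feedforward", "mixed", "crossover"):
        base = templates[name]
        for _ in range(n_per):
            traces.append(base + noise_sd * rng.standard_normal(len(t)))
            labels.append(name)
    return np.array(traces), np.array(labels), templates


@dataclass
class RecordingSet:
    """Noisy multi-trial image/disc responses with ground truth attached."""

    image_trials: np.ndarray  # (n_patches, n_repeats, T)
    disc_trials: np.ndarray
    dt: float
    pathway: str
    noise_sd: float
    ground_truth_image: np.ndarray  # (n_patches,) noiseless integrated responses
    ground_truth_disc: np.ndarray

    @property
    def n_repeats(self) -> int:
        return self.image_trials.shape[1]

    def integrated(self, window: tuple | None = None) -> tuple:
        """Trial responses integrated over the flash window (mean over repeats)."""
        i0, i1 = (0, self.image_trials.shape[2]) if window is None else (
            int(round(window[0] / self.dt)), int(round(window[1] / self.dt)))
        img = self.image_trials[:, :, i0:i1].sum(axis=2) * self.dt
        dsc = self.disc_trials[:, :, i0:i1].sum(axis=2) * self.dt
        return img.mean(axis=1), dsc.mean(axis=1)


def make_recordings(
    model_cfg: SubunitModelConfig,
    patches: list,
    rf: CenterRF,
    n_repeats: int = 6,
    noise_sd: float = 0.0,
    seed: int = 0,
    pathway: str = "spike",
    background: float = 4000.0,
    pixel_pitch: float = 3.0,
    dt: float = 1e-3,
    flash_dur: float = 0.25,
) -> RecordingSet:
    """Simulated multi-trial flashed-patch recordings from a ground-truth model.

    Each patch and its linear-equivalent disc are run through the static
    subunit model; the scalar drive shapes a 250-ms response pulse, and
    independent Gaussian noise is added per trial and time sample (six
    repeats per patch by default, matching typical experimental practice).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(flash_dur / dt))) * dt
    pulse = _alpha(t, 0.02, 0.05)
    pulse /= pulse.sum() * dt  # unit integral: integrated trace == scalar drive
    gt_img, gt_disc = [], []
    img_trials, disc_trials = [], []
    for patch in patches:
        disc = linear_equivalent_disc(patch, rf, pixel_pitch, background)
        ri = run_ei_static(patch, model_cfg, rf, background, pixel_pitch)
        rd = run_ei_static(disc, model_cfg, rf, background, pixel_pitch)
        vi = getattr(ri, f"{pathway}_drive" if pathway != "spike" else "spike_proxy")
        vd = getattr(rd, f"{pathway}_drive" if pathway != "spike" else "spike_proxy")
        gt_img.append(vi)
        gt_disc.append(vd)
        img_trials.append(vi * pulse + noise_sd * rng.standard_normal((n_repeats, len(t))))
        disc_trials.append(vd * pulse + noise_sd * rng.standard_normal((n_repeats, len(t))))
    return RecordingSet(
        image_trials=np.array(img_trials), disc_trials=np.array(disc_trials),
        dt=dt, pathway=pathway, noise_sd=noise_sd,
        ground_truth_image=np.array(gt_img), ground_truth_disc=np.array(gt_disc),
    )
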