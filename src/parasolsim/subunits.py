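"""Excitatory/inhibitory subunit receptive-field models of parasol RGCs.

The receptive-field center is tiled by two independently positioned regular
grids of Gaussian subunits -- one feeding the excitatory pathway (bipolar
scale, SD = sigma_c / 5) and one the inhibitory pathway (50% larger).  Each
subunit spatially filters the input, passes it through a pathway-specific
contrast-response nonlinearity, and the subunit outputs are summed with
Gaussian center weights.  The spike proxy thresholds the weighted E - I
difference at zero, with a threefold larger excitatory weight reflecting the
larger driving force on excitatory input near spike threshold.

The excitatory nonlinearity is a smooth rectifier; the inhibitory
nonlinearity is U-shaped, with a dominant negative-contrast (crossover,
Off-pathway) lobe and a weaker positive-contrast (feedforward) lobe.
Variants used to dissect the role of inhibition: ``linear_inhibition``
(identity inhibitory curve), ``no_feedforward_inhibition`` (positive lobe
zeroed), ``big_inhibitory_subunits`` (inhibitory subunit SD and spacing
doubled).

The model runs in a static mode (a single contrast image per patch, no time)
or driven by a cone front end -- either the adapting phototransduction
cascade or its matched linear filter -- applied pixelwise, with cone output
normalized to contrast-equivalent units so the same nonlinearities serve
both modes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from . import cones
from .cones import ConeParams, DEFAULT_CONE_PARAMS, LinearConeFilter
from .stimuli import CenterRF, StimulusMovie, aperture_mask, _grid_um

logger = logging.getLogger(__name__)

__all__ = [
    "NonlinearityCurve",
    "SubunitModelConfig",
    "SubunitGrid",
    "EIResponse",
    "StaticEIResponse",
    "build_subunit_grid",
    "apply_variant",
    "run_ei_model",
    "run_ei_static",
    "run_simple_model",
    "get_linear_filter",
    "cone_contrast_norm",
    "VARIANTS",
]

VARIANTS = ("base", "linear_inhibition", "no_feedforward_inhibition", "big_inhibitory_subunits")


@dataclass
class NonlinearityCurve:
    """Piecewise-linear contrast-response curve on [-1, 1].

    Evaluated by linear interpolation between breakpoints; inputs outside
    the domain are clamped to the endpoints (with a logged count).
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("breakpoints x and y must be 1-D and equal length")
        if not np.all(np.diff(self.x) > 0):
            raise ValueError("breakpoints must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("curve outputs must be finite")

    def __call__(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        n_out = int(np.sum((c < self.x[0]) | (c > self.x[-1])))
        if n_out:
            logger.info("nonlinearity domain exceeded for %d samples; clamping", n_out)
        return np.interp(c, self.x, self.y)

    # --- constructors -----------------------------------------------------
    @classmethod
    def identity(cls, n: int = 513) -> "NonlinearityCurve":
        x = np.linspace(-1.0, 1.0, n)
        return cls(x, x.copy())

    @classmethod
    def softplus_rectifier(cls, a: float, b: float, n: int = 513) -> "NonlinearityCurve":
        """Smooth rectifier a (log(1 + exp(b c)) - log 2), zero at c = 0."""
        x = np.linspace(-1.0, 1.0, n)
        y = a * (np.logaddexp(0.0, b * x) - np.log(2.0))
        return cls(x, y)

    @classmethod
    def u_shaped(cls, a_plus: float, a_minus: float, p: float, n: int = 513) -> "NonlinearityCurve":
        """U-shaped curve a_plus relu(c)^p + a_minus relu(-c)^p.

        ``a_minus > a_plus`` makes the crossover (negative-contrast) lobe
        dominate, as measured for inhibitory input to On parasol cells.
        """
        x = np.linspace(-1.0, 1.0, n)
        y = a_plus * np.clip(x, 0, None) ** p + a_minus * np.clip(-x, 0, None) ** p
        return cls(x, y)

    def without_positive_lobe(self) -> "NonlinearityCurve":
        y = self.y.copy()
        y[self.x > 0] = 0.0
        return NonlinearityCurve(self.x.copy(), y)


def _default_exc_curve() -> NonlinearityCurve:
    """Shipped excitatory contrast-response curve.

    A shallow softplus rectifier: expansive around zero contrast, linear for
    strong increments, and saturating at a modest negative level for
    decrements (tonic excitation is suppressed below baseline by dark
    inputs).  The dip-to-slope balance (set by ``b``) is what lets the
    slower, larger decrement responses of adapting cones eat into the
    excitatory drive at grating onset; see the calibration note in the
    methods document.
    """
    return NonlinearityCurve.softplus_rectifier(a=2.0, b=2.5)


def _default_inh_curve() -> NonlinearityCurve:
    """Shipped inhibitory contrast-response curve.

    U-shaped with a fourfold-larger crossover (negative-contrast, Off
    pathway) lobe than the feedforward (positive) lobe; the U makes
    inhibitory spatial integration strongly nonlinear even though each lobe
    is linear.
    """
    return NonlinearityCurve.u_shaped(a_plus=0.6, a_minus=2.4, p=1.0)


@dataclass
class SubunitModelConfig:
    """Geometry, weights and nonlinearities of the E/I subunit model.

    Defaults: excitatory subunit SD and spacing are sigma_c / 5, inhibitory
    ones 50% larger, excitatory:inhibitory weight 3:1, subunit grids
    positioned independently (random lattice phase per pathway, seeded).
    """

    sigma_c: float = 60.0
    exc_subunit_sigma: float | None = None
    inh_subunit_sigma: float | None = None
    exc_spacing: float | None = None
    inh_spacing: float | None = None
    exc_weight: float = 3.0
    inh_weight: float = 1.0
    exc_nonlinearity: NonlinearityCurve = field(default_factory=_default_exc_curve)
    inh_nonlinearity: NonlinearityCurve = field(default_factory=_default_inh_curve)
    output_threshold: float = 0.0
    cone_front_end: str = "none"  # none | adapting | linear
    variant: str = "base"
    cone_params: ConeParams = field(default_factory=lambda: DEFAULT_CONE_PARAMS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exc_subunit_sigma is None:
            self.exc_subunit_sigma = self.sigma_c / 5.0
        if self.inh_subunit_sigma is None:
            self.inh_subunit_sigma = 1.5 * self.exc_subunit_sigma
        if self.exc_spacing is None:
            self.exc_spacing = self.exc_subunit_sigma
        if self.inh_spacing is None:
            self.inh_spacing = self.inh_subunit_sigma
        if self.exc_weight <= 0 or self.inh_weight <= 0:
            raise ValueError("pathway weights must be positive")
        if self.cone_front_end not in ("none", "adapting", "linear"):
            raise ValueError("cone_front_end must be none, adapting or linear")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; valid: {VARIANTS}")


def apply_variant(cfg: SubunitModelConfig, variant: str) -> SubunitModelConfig:
    """Return a new config with one of the inhibitory-pathway manipulations.

    ``linear_inhibition`` replaces the inhibitory curve with the identity;
    ``no_feedforward_inhibition`` zeroes its positive-contrast region;
    ``big_inhibitory_subunits`` doubles inhibitory subunit SD and spacing.
    The input config is left untouched.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; valid: {VARIANTS}")
    if variant == "base":
        return dataclasses.replace(cfg, variant="base")
    if variant == "linear_inhibition":
        return dataclasses.replace(cfg, variant=variant, inh_nonlinearity=NonlinearityCurve.identity())
    if variant == "no_feedforward_inhibition":
        return dataclasses.replace(cfg, variant=variant,
                                   inh_nonlinearity=cfg.inh_nonlinearity.without_positive_lobe())
    return dataclasses.replace(
        cfg, variant=variant,
        inh_subunit_sigma=2.0 * cfg.inh_subunit_sigma,
        inh_spacing=2.0 * cfg.inh_spacing,
    )


@dataclass
class SubunitGrid:
    """Subunit positions, pixel filters and center weights for one pathway.

    ``filters`` is (n_subunits, n_pixels), each row a unit-sum Gaussian;
    ``center_weights`` sums to 1 across subunits.
    """

    positions: np.ndarray
    filters: np.ndarray
    center_weights: np.ndarray

    @property
    def n_subunits(self) -> int:
        return len(self.positions)


def build_subunit_grid(
    sigma: float,
    spacing: float,
    rf: CenterRF,
    pixel_pitch: float,
    rng: np.random.Generator | None = None,
    positions: np.ndarray | None = None,
) -> SubunitGrid:
    """Square lattice of Gaussian subunits covering the aperture.

    The lattice phase is drawn uniformly on [0, spacing)^2 (independent
    positioning per pathway); subunit centers falling within the aperture
    are kept.  ``positions`` overrides the lattice with explicit (x, y)
    subunit centers in micrometers.
    """
    if spacing > rf.aperture_diameter:
        raise ValueError("subunit spacing exceeds the aperture")
    x, y, n = _grid_um(rf, pixel_pitch)
    px = np.broadcast_to(x, (n, n)).ravel()
    py = np.broadcast_to(y, (n, n)).ravel()
    if positions is None:
        if rng is None:
            rng = np.random.default_rng(0)
        off = rng.uniform(0.0, spacing, size=2)
        R = rf.aperture_radius
        g = np.arange(-R - spacing, R + spacing, spacing)
        sx = (g[None, :] + off[0]) + rf.center_xy[0]
        sy = (g[:, None] + off[1]) + rf.center_xy[1]
        SX, SY = np.broadcast_arrays(sx, sy)
        keep = (SX - rf.center_xy[0]) ** 2 + (SY - rf.center_xy[1]) ** 2 <= R ** 2
        positions = np.column_stack([SX[keep], SY[keep]])
        if len(positions) == 0:  # degenerate: one subunit at the center
            positions = np.array([[rf.center_xy[0], rf.center_xy[1]]])
    positions = np.asarray(positions, dtype=float)
    d2 = (px[None, :] - positions[:, 0:1]) ** 2 + (py[None, :] - positions[:, 1:2]) ** 2
    filt = np.exp(-d2 / (2.0 * sigma ** 2))
    filt /= filt.sum(axis=1, keepdims=True)
    dc2 = (positions[:, 0] - rf.center_xy[0]) ** 2 + (positions[:, 1] - rf.center_xy[1]) ** 2
    w = np.exp(-dc2 / (2.0 * rf.sigma_c ** 2))
    w /= w.sum()
    return SubunitGrid(positions=positions, filters=filt, center_weights=w)


def build_pathway_grids(cfg: SubunitModelConfig, rf: CenterRF, pixel_pitch: float,
                        exc_positions=None, inh_positions=None) -> tuple:
    rng = np.random.default_rng(cfg.seed)
    exc = build_subunit_grid(cfg.exc_subunit_sigma, cfg.exc_spacing, rf, pixel_pitch,
                             rng=rng, positions=exc_positions)
    inh = build_subunit_grid(cfg.inh_subunit_sigma, cfg.inh_spacing, rf, pixel_pitch,
                             rng=rng, positions=inh_positions)
    return exc, inh


# --- cone front ends ------------------------------------------------------

_FILTER_CACHE: dict = {}


def get_linear_filter(params: ConeParams, background: float) -> LinearConeFilter:
    """Cached linear cone filter for a parameter set and background."""
    key = (tuple(sorted(params.to_dict().items())), round(background, 6))
    if key not in _FILTER_CACHE:
        _FILTER_CACHE[key] = cones.derive_linear_cone(params, background)
    return _FILTER_CACHE[key]


def cone_contrast_norm(params: ConeParams, background: float) -> float:
    """Normalization from cone current to contrast-equivalent units.

    Peak of the linear-cone response to a 100% contrast, 250-ms step: with
    this scaling a sustained full-contrast step drives the nonlinearities
    with a peak input of ~1, so the same contrast-response curves serve the
    static and cone-driven modes.
    """
    return get_linear_filter(params, background).step_response_peak(1.0, 0.25)


def _front_end_signals(stim: StimulusMovie, cfg: SubunitModelConfig, rf: CenterRF,
                       dt_out: float, cone_dt: float) -> tuple:
    """Per-pixel pathway input signals (n_pixels, T_out) and their dt."""
    H, W, T = stim.frames.shape
    flat = stim.frames.reshape(H * W, T)
    B = stim.background
    if cfg.cone_front_end == "none":
        return (flat - B) / B, stim.dt_frame
    duration = stim.duration
    n_out = int(round(duration / dt_out))
    norm = cone_contrast_norm(cfg.cone_params, B)
    if cfg.cone_front_end == "adapting":
        uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
        resp = cones.simulate_adapting_cone(
            uniq, cfg.cone_params, dt=cone_dt, stim_dt=stim.dt_frame,
            dt_out=dt_out, background=B,
        )
        sig = resp[inverse][:, :n_out]
    else:  # linear
        filt = get_linear_filter(cfg.cone_params, B)
        t_out = np.arange(n_out) * dt_out
        fi = np.minimum((t_out / stim.dt_frame).astype(int), T - 1)
        contrast = (flat[:, fi] - B) / B
        sig = cones.simulate_linear_cone(contrast, filt, dt=dt_out, stim_is_contrast=True)
    return sig / norm, dt_out


@dataclass
class EIResponse:
    """Pathway drives and spike proxy over time.

    Invariant: spike_proxy = max(0, exc_weight * exc_drive
    - inh_weight * inh_drive - output_threshold).
    """

    exc_drive: np.ndarray
    inh_drive: np.ndarray
    spike_proxy: np.ndarray
    dt: float
    exc_subunit_outputs: np.ndarray | None = None
    inh_subunit_outputs: np.ndarray | None = None


@dataclass
class StaticEIResponse:
    exc_drive: float
    inh_drive: float
    spike_proxy: float


def run_ei_model(
    stim: StimulusMovie,
    cfg: SubunitModelConfig,
    rf: CenterRF | None = None,
    dt_out: float = 1e-3,
    cone_dt: float = 1e-4,
    keep_subunit_outputs: bool = False,
    exc_positions=None,
    inh_positions=None,
) -> EIResponse:
    """Run the full E/I subunit model on a stimulus movie.

    Pipeline per pathway: optional cone front end applied pixelwise
    (adapting cascade or linear filter, output normalized to
    contrast-equivalent units; with ``cone_front_end='none'`` the input is
    spatial contrast at the frame rate) -> Gaussian subunit filtering ->
    subunit nonlinearity -> center-weighted sum.  The spike proxy thresholds
    the weighted E - I difference at zero.
    """
    if rf is None:
        rf = CenterRF(sigma_c=cfg.sigma_c)
    exc_grid, inh_grid = build_pathway_grids(cfg, rf, stim.pixel_pitch,
                                             exc_positions, inh_positions)
    sig, dt = _front_end_signals(stim, cfg, rf, dt_out, cone_dt)
    exc_in = exc_grid.filters @ sig
    inh_in = inh_grid.filters @ sig
    exc_out = cfg.exc_nonlinearity(exc_in)
    inh_out = cfg.inh_nonlinearity(inh_in)
    exc_drive = exc_grid.center_weights @ exc_out
    inh_drive = inh_grid.center_weights @ inh_out
    spike = np.maximum(0.0, cfg.exc_weight * exc_drive - cfg.inh_weight * inh_drive
                       - cfg.output_threshold)
    return EIResponse(
        exc_drive=exc_drive, inh_drive=inh_drive, spike_proxy=spike, dt=dt,
        exc_subunit_outputs=exc_out if keep_subunit_outputs else None,
        inh_subunit_outputs=inh_out if keep_subunit_outputs else None,
    )


def run_ei_static(
    patch: np.ndarray,
    cfg: SubunitModelConfig,
    rf: CenterRF | None = None,
    background: float = 4000.0,
    pixel_pitch: float = 3.0,
    exc_positions=None,
    inh_positions=None,
) -> StaticEIResponse:
    """Static (time-free) E/I model response to a single contrast image.

    ``patch`` is an intensity image covering the aperture grid; its spatial
    contrast (patch - B) / B feeds the subunits directly.
    """
    if rf is None:
        rf = CenterRF(sigma_c=cfg.sigma_c)
    patch = np.asarray(patch, dtype=float)
    movie = StimulusMovie(patch[:, :, None], dt_frame=1.0, pixel_pitch=pixel_pitch,
                          background=background)
    static_cfg = cfg if cfg.cone_front_end == "none" else dataclasses.replace(cfg, cone_front_end="none")
    r = run_ei_model(movie, static_cfg, rf, exc_positions=exc_positions,
                     inh_positions=inh_positions)
    return StaticEIResponse(exc_drive=float(r.exc_drive[0]),
                            inh_drive=float(r.inh_drive[0]),
                            spike_proxy=float(r.spike_proxy[0]))


def run_simple_model(
    patch: np.ndarray,
    polarity: str,
    integration: str,
    rf: CenterRF,
    subunit_sigma: float | None = None,
    spacing: float | None = None,
    background: float = 4000.0,
    pixel_pitch: float = 3.0,
    seed: int = 0,
) -> float:
    """One-pathway linear or rectified-subunit model (On or Off polarity).

    Used for the constant-response-contour analysis.  ``polarity='off'``
    negates the input contrast first.  The nonlinear branch filters through
    the subunit grid, half-wave rectifies each subunit output and sums with
    Gaussian center weights.  The linear branch is the zero-size-subunit
    limit of the same cascade: the exact Gaussian-RF weighted mean of pixel
    contrast -- so by construction it responds identically to a patch and
    to its linear-equivalent disc.
    """
    from .stimuli import center_weights

    if polarity not in ("on", "off"):
        raise ValueError("polarity must be 'on' or 'off'")
    if integration not in ("linear", "nonlinear"):
        raise ValueError("integration must be 'linear' or 'nonlinear'")
    patch = np.asarray(patch, dtype=float)
    c = (patch - background) / background
    if polarity == "off":
        c = -c
    if integration == "linear":
        w = center_weights(rf, pixel_pitch)
        return float(np.sum(w * c) / np.sum(w))
    if subunit_sigma is None:
        subunit_sigma = rf.sigma_c / 5.0
    if spacing is None:
        spacing = subunit_sigma
    key = (subunit_sigma, spacing, rf.sigma_c, rf.aperture_diameter,
           rf.center_xy, pixel_pitch, seed)
    grid = _SIMPLE_GRID_CACHE.get(key)
    if grid is None:
        grid = build_subunit_grid(subunit_sigma, spacing, rf, pixel_pitch,
                                  rng=np.random.default_rng(seed))
        _SIMPLE_GRID_CACHE[key] = grid
    s = np.maximum(grid.filters @ c.ravel(), 0.0)
    return float(grid.center_weights @ s)


_SIMPLE_GRID_CACHE: dict = {}
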