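"""Cone phototransduction: an adapting biophysical cascade and its linear control.

The adapting model is the canonical five-state phototransduction cascade:
opsin activity ``R`` drives phosphodiesterase (PDE) activity ``P``, which
hydrolyzes cGMP ``G``; the circulating (outward) current is ``I = k_cur *
G**n_cur``; calcium ``C`` enters in proportion to the current and feeds back
on cGMP synthesis through a Hill function.  Light-dependent PDE activity
lowers cGMP and hence the current; the calcium feedback loop restores it,
producing rapid gain adaptation (time constant of tens of milliseconds at
photopic backgrounds).

All simulated responses are reported baseline-subtracted with light
*increments positive*, so downstream contrast-response functions apply with
their natural sign convention.

The linear (nonadapting) control is an impulse response measured from the
full model with a brief, low-contrast flash; convolving it with a contrast
trace gives the response a cone without adaptation would produce.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ConeParams",
    "ConeState",
    "LinearConeFilter",
    "DEFAULT_CONE_PARAMS",
    "steady_state",
    "simulate_adapting_cone",
    "derive_linear_cone",
    "simulate_linear_cone",
]


@dataclass(frozen=True)
class ConeParams:
    """Parameters of the phototransduction cascade.

    Rates are per second; ``gamma`` is the opsin activation gain per R*,
    ``k_cur``/``n_cur`` map cGMP to current, ``q_ca`` scales calcium influx
    per unit current, and ``s_max``/``k_gc``/``h_gc`` parameterize the
    calcium-dependent cGMP synthesis rate
    ``syn(C) = s_max / (1 + (C / k_gc) ** h_gc)``.
    """

    gamma: float = 10.0
    sigma: float = 22.0
    phi: float = 22.0
    eta: float = 2000.0
    k_cur: float = 0.01
    n_cur: float = 3.0
    beta: float = 9.0
    q_ca: float = 0.1125
    s_max: float = 30909.0909090909
    k_gc: float = 0.5
    h_gc: float = 4.0

    def __post_init__(self) -> None:
        for name in ("gamma", "sigma", "phi", "eta", "k_cur", "beta", "q_ca", "s_max", "k_gc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ConeParams.{name} must be strictly positive")
        if self.n_cur < 1:
            raise ValueError("ConeParams.n_cur must be >= 1")
        if self.h_gc < 1:
            raise ValueError("ConeParams.h_gc must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ConeParams":
        return cls(**d)


#: Default parameter set.  Calibrated so that in darkness G = 20, C = 1 and
#: I = 80 (arbitrary current units) and so that at a photopic background of
#: 4000 R*/s the model shows the three adaptation signatures relevant here:
#: a reduced first half-cycle response to a sinusoid, larger decrement than
#: increment excursions, and faster dark-to-light than light-to-dark
#: kinetics, with a gain-recovery time constant well under 100 ms.
DEFAULT_CONE_PARAMS = ConeParams()


@dataclass
class ConeState:
    """State of the cascade: opsin R, PDE P, cGMP G, calcium C, current I."""

    R: float
    P: float
    G: float
    C: float
    I: float

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.P, self.G, self.C])


@dataclass
class LinearConeFilter:
    """Impulse response of the linearized cone at a fixed background.

    ``kernel`` is in current units per unit contrast per second, sampled at
    ``dt``; convolving ``kernel * dt`` with a contrast trace gives the
    linear-cone response.
    """

    kernel: np.ndarray
    dt: float
    background: float

    def __post_init__(self) -> None:
        peak = float(np.max(np.abs(self.kernel)))
        if peak > 0 and abs(self.kernel[-1]) > 0.01 * peak:
            raise ValueError("LinearConeFilter kernel does not decay below 1% of its peak")

    @property
    def duration(self) -> float:
        return len(self.kernel) * self.dt

    def step_response_peak(self, contrast: float = 1.0, dur: float = 0.25) -> float:
        """Peak of the linear response to a contrast step of ``dur`` seconds."""
        n = int(round(dur / self.dt))
        resp = np.cumsum(self.kernel[: max(n, 1)]) * self.dt * contrast
        return float(np.max(np.abs(resp)))


def _synthesis(C: np.ndarray, p: ConeParams) -> np.ndarray:
    return p.s_max / (1.0 + (C / p.k_gc) ** p.h_gc)


def steady_state(params: ConeParams, background: float) -> ConeState:
    """Fixed point of the cascade at a constant background (R*/s).

    Reduces to a monotone one-dimensional root problem in cGMP: with
    ``R = gamma * S / sigma`` and ``P = (R + eta) / phi`` fixed, the cGMP
    balance ``syn(C(G)) = P * G`` with ``C(G) = q_ca * k_cur * G**n / beta``
    has a unique root on ``(0, s_max / P]``.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    R = params.gamma * background / params.sigma
    P = (R + params.eta) / params.phi

    def f(G: float) -> float:
        I = params.k_cur * G ** params.n_cur
        C = params.q_ca * I / params.beta
        return _synthesis(np.asarray(C), params) - P * G

    g_hi = params.s_max / P * (1.0 + 1e-9)
    try:
        G = brentq(f, 0.0, g_hi, xtol=1e-14, rtol=1e-15, maxiter=200)
    except ValueError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"cone steady state failed to converge at background {background} R*/s") from exc
    I = params.k_cur * G ** params.n_cur
    C = params.q_ca * I / params.beta
    state = ConeState(R=R, P=P, G=G, C=C, I=I)
    _check_fixed_point(state, params, background)
    return state


def _check_fixed_point(state: ConeState, p: ConeParams, S: float) -> None:
    scale = max(abs(state.G * state.P), 1e-12)
    dR = p.gamma * S - p.sigma * state.R
    dP = state.R + p.eta - p.phi * state.P
    dG = float(_synthesis(np.asarray(state.C), p)) - state.P * state.G
    dC = p.q_ca * state.I - p.beta * state.C
    rel = max(
        abs(dR) / max(abs(p.eta), 1.0),
        abs(dP) / max(abs(state.P * p.phi), 1.0),
        abs(dG) / scale,
        abs(dC) / max(abs(state.C * p.beta), 1e-12),
    )
    if rel > 1e-9:
        raise RuntimeError(f"cone steady state did not converge at background {S} R*/s (residual {rel:.2e})")


def _derivs(y: np.ndarray, S: np.ndarray, p: ConeParams) -> np.ndarray:
    R, P, G, C = y
    dR = p.gamma * S - p.sigma * R
    dP = R + p.eta - p.phi * P
    dG = _synthesis(C, p) - P * G
    dC = p.q_ca * p.k_cur * G ** p.n_cur - p.beta * C
    return np.stack([dR, dP, dG, dC])


def _integrate(y0: np.ndarray, stim: np.ndarray, stim_dt: float, dt: float, n_steps: int,
               p: ConeParams, out_stride: int) -> np.ndarray:
    """Fixed-step RK4 with zero-order-hold stimulus, vectorized over traces.

    ``y0``: (4, B); ``stim``: (B, T_frames).  Returns current I sampled every
    ``out_stride`` steps, shape (B, n_steps // out_stride + 1).
    """
    y = y0.copy()
    n_out = n_steps // out_stride + 1
    B = stim.shape[0]
    out = np.empty((B, n_out))
    out[:, 0] = p.k_cur * y[2] ** p.n_cur
    T_frames = stim.shape[1]
    j = 1
    for i in range(n_steps):
        fi = int(i * dt / stim_dt)
        if fi >= T_frames:
            fi = T_frames - 1
        S = stim[:, fi]
        k1 = _derivs(y, S, p)
        k2 = _derivs(y + 0.5 * dt * k1, S, p)
        k3 = _derivs(y + 0.5 * dt * k2, S, p)
        k4 = _derivs(y + dt * k3, S, p)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if (i + 1) % out_stride == 0:
            out[:, j] = p.k_cur * y[2] ** p.n_cur
            j += 1
    return out[:, :j]


def simulate_adapting_cone(
    stim: np.ndarray,
    params: ConeParams = DEFAULT_CONE_PARAMS,
    dt: float = 5e-5,
    stim_dt: float | None = None,
    dt_out: float | None = None,
    background: float | None = None,
) -> np.ndarray:
    """Simulate the adapting cascade for one or many intensity traces.

    Parameters
    ----------
    stim : array, shape (T,) or (B, T)
        Light intensity in R*/s, held constant over each ``stim_dt`` frame
        (zero-order hold).
    dt : float
        Integration step (s); must be <= 1e-4.
    stim_dt : float, optional
        Frame duration of ``stim``; defaults to ``dt`` (stimulus already at
        integration resolution).
    dt_out : float, optional
        Output sampling interval; must be an integer multiple of ``dt``.
        Defaults to ``dt``.
    background : float, optional
        Pre-stimulus background used to initialize at steady state.  Defaults
        to the first stimulus sample (which must be common across traces).

    Returns
    -------
    array of photocurrent responses, baseline-subtracted, increment-positive,
    same leading shape as ``stim``.
    """
    stim = np.asarray(stim, dtype=float)
    if np.any(stim < 0):
        raise ValueError("stimulus intensities must be >= 0 (R*/s)")
    if dt > 1e-4 + 1e-12:
        raise ValueError("integration dt must be <= 0.1 ms")
    single = stim.ndim == 1
    st = stim[None, :] if single else stim.reshape(-1, stim.shape[-1])
    if stim_dt is None:
        stim_dt = dt
    if background is None:
        bgs = np.unique(st[:, 0])
        if len(bgs) != 1:
            raise ValueError("traces start at different values; pass background explicitly")
        background = float(bgs[0])
    ss = steady_state(params, background)
    y0 = np.tile(ss.as_array()[:, None], (1, st.shape[0]))
    duration = st.shape[1] * stim_dt
    n_steps = int(round(duration / dt))
    if dt_out is None:
        stride = 1
    else:
        stride = int(round(dt_out / dt))
        if abs(stride * dt - dt_out) > 1e-12:
            raise ValueError("dt_out must be an integer multiple of dt")
    I = _integrate(y0, st, stim_dt, dt, n_steps, params, stride)
    if not np.all(np.isfinite(I)):
        raise RuntimeError("cone integration diverged (NaN/inf); use a smaller dt")
    out = ss.I - I  # increment-positive
    out = out[:, 1:]  # drop the t=0 sample so length matches the stimulus duration
    if single:
        return out[0]
    return out.reshape(stim.shape[:-1] + (out.shape[-1],))


def derive_linear_cone(
    params: ConeParams = DEFAULT_CONE_PARAMS,
    background: float = 4000.0,
    flash_contrast: float = 0.01,
    flash_dur: float = 0.002,
    dt: float = 5e-5,
    t_max: float = 0.8,
) -> LinearConeFilter:
    """Impulse response of the cascade from a brief, low-contrast flash.

    The kernel is the baseline-subtracted full-model flash response divided
    by the flash strength (contrast x duration), truncated once it has
    decayed below 0.5% of its peak.  A halving check guards linearity: the
    normalized response shape must change by < 1% when the flash contrast is
    halved.
    """
    if background <= 0:
        raise ValueError("background must be > 0 to define contrast")

    def flash_response(c: float) -> np.ndarray:
        n = int(round(t_max / dt))
        stim = np.full(n, background)
        nf = max(int(round(flash_dur / dt)), 1)
        stim[:nf] = background * (1.0 + c)
        return simulate_adapting_cone(stim, params, dt=dt, stim_dt=dt, background=background)

    r1 = flash_response(flash_contrast)
    r2 = flash_response(flash_contrast / 2.0)
    peak = np.max(np.abs(r1))
    if peak == 0:
        raise RuntimeError("flash produced no response; increase flash_contrast")
    shape_change = np.max(np.abs(r1 - 2.0 * r2)) / peak
    if shape_change > 0.01:
        raise ValueError(
            f"flash_contrast={flash_contrast} is outside the linear range "
            f"(shape change {shape_change:.3%}); use a smaller flash_contrast"
        )
    kernel = r1 / (flash_contrast * flash_dur)
    # center the kernel on the flash: the boxcar flash's effective impulse
    # time is its midpoint, so advance by half the flash duration
    shift = int(round(flash_dur / (2.0 * dt)))
    if shift:
        kernel = kernel[shift:]
    kpeak = np.max(np.abs(kernel))
    above = np.nonzero(np.abs(kernel) > 0.005 * kpeak)[0]
    kernel = kernel[: above[-1] + 1]
    return LinearConeFilter(kernel=kernel, dt=dt, background=background)


def resample_kernel(filt: LinearConeFilter, dt: float) -> np.ndarray:
    """Resample the kernel to a coarser or finer time base by interpolation."""
    t_old = np.arange(len(filt.kernel)) * filt.dt
    t_new = np.arange(0.0, t_old[-1] + 0.5 * dt, dt)
    return np.interp(t_new, t_old, filt.kernel)


def simulate_linear_cone(
    stim: np.ndarray,
    filt: LinearConeFilter,
    dt: float | None = None,
    stim_is_contrast: bool = False,
) -> np.ndarray:
    """Response of the linear (nonadapting) cone: contrast convolved with kernel.

    ``stim`` is an intensity trace in R*/s (converted to contrast about
    ``filt.background``) or, with ``stim_is_contrast=True``, already a
    contrast trace.  ``dt`` is the sampling interval of ``stim`` (defaults to
    the kernel's).  Output has the same shape as ``stim``.
    """
    from scipy.signal import fftconvolve

    stim = np.asarray(stim, dtype=float)
    if dt is None:
        dt = filt.dt
    if stim_is_contrast:
        contrast = stim
    else:
        mean = float(np.mean(stim))
        if abs(mean - filt.background) > 0.10 * filt.background:
            import logging

            logging.getLogger(__name__).warning(
                "stimulus mean %.1f differs from filter background %.1f by more than 10%%",
                mean, filt.background,
            )
        contrast = (stim - filt.background) / filt.background
    kernel = filt.kernel if abs(dt - filt.dt) < 1e-15 else resample_kernel(filt, dt)
    full = fftconvolve(contrast, kernel[(None,) * (contrast.ndim - 1)], axes=-1)
    return full[..., : stim.shape[-1]] * dt
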