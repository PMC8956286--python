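"""Response statistics: NLI, Fourier components, I/E ratios, timing.

The nonlinearity index NLI = (R_image - R_disc) / (R_image + R_disc)
summarizes spatial integration: 0 for a spatially linear cell (image and
linear-equivalent disc give the same response), 1 for a cell responding to
the image but not at all to the disc.

Grating responses are summarized per half-cycle (half-cycle k spans
[(k-1)/(2f), k/(2f)] from stimulus onset, matching the phase-0 sinusoid
convention of the stimulus generators); I/E ratios are integrals of
inhibitory over excitatory drive, normalized to the steady-state mean over
half-cycles >= 6.  F1/F2 amplitudes and phases are DFT components at the
stimulus frequency and its double, equivalent to least-squares sinusoid fits
at fixed frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "nli",
    "fourier_components",
    "phase_to_ms",
    "half_cycle_stats",
    "windowed_ie",
    "half_max_time",
    "harmonic_distortion",
]


def nli(r_image, r_disc):
    """Nonlinearity index (R_image - R_disc) / (R_image + R_disc).

    Accepts scalars or arrays.  Pairs with R_image + R_disc == 0 are flagged
    as NaN (excluded from averages) with a logged count.
    """
    r_image = np.asarray(r_image, dtype=float)
    r_disc = np.asarray(r_disc, dtype=float)
    if not (np.all(np.isfinite(r_image)) and np.all(np.isfinite(r_disc))):
        raise ValueError("responses must be finite")
    denom = r_image + r_disc
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (r_image - r_disc) / np.where(denom == 0, 1.0, denom), np.nan)
    n_bad = int(np.sum(denom == 0))
    if n_bad:
        logger.info("nli: %d patch(es) with zero total response flagged NaN", n_bad)
    if out.ndim == 0:
        return float(out)
    return out


def fourier_components(trace: np.ndarray, f: float, dt: float,
                       window: tuple | None = None) -> dict:
    """F1 and F2 amplitude/phase of a trace at stimulus frequency ``f``.

    ``window`` is (t_start, t_end) in seconds and must span an integer number
    of periods of ``f`` (the first cycle is typically excluded for
    steady-state fits).  Amplitudes are 2 |X| / N; phases in degrees.
    """
    trace = np.asarray(trace, dtype=float)
    if window is None:
        i0, i1 = 0, len(trace)
    else:
        i0 = int(round(window[0] / dt))
        i1 = int(round(window[1] / dt))
    seg = trace[i0:i1]
    n_per = (i1 - i0) * dt * f
    if abs(n_per - round(n_per)) > 1e-6 or round(n_per) < 1:
        raise ValueError(f"window spans {n_per:.4f} periods; must be a positive integer")
    t = (np.arange(i0, i1) - i0) * dt
    out = {}
    for name, freq in (("F1", f), ("F2", 2.0 * f)):
        z = np.sum(seg * np.exp(-2j * np.pi * freq * t)) * 2.0 / len(seg)
        out[f"{name}_amp"] = float(np.abs(z))
        out[f"{name}_phase_deg"] = float(np.degrees(np.angle(z)))
    return out


def phase_to_ms(delta_deg: float, component_freq: float) -> float:
    """Convert a phase difference (degrees) at a component frequency to ms.

    The component frequency is the frequency of the fitted sinusoid -- 2f for
    frequency-doubled responses, f otherwise; the caller supplies it
    explicitly because both conventions occur.
    """
    if component_freq <= 0:
        raise ValueError("component_freq must be > 0")
    return delta_deg / 360.0 * 1000.0 / component_freq


def half_cycle_stats(exc: np.ndarray, inh: np.ndarray, f: float, dt: float,
                     spike: np.ndarray | None = None,
                     steady_from: int = 6) -> pd.DataFrame:
    """Per-half-cycle integrals, I/E ratios, and steady-state-normalized values.

    Integrals are charge-like sums (trace x dt) over each half-cycle.
    ``ie_ratio`` entries with non-positive excitatory integral are NaN.
    Normalized columns divide by the mean over half-cycles >= ``steady_from``.
    """
    exc = np.asarray(exc, dtype=float)
    inh = np.asarray(inh, dtype=float)
    if exc.shape != inh.shape:
        raise ValueError("exc and inh traces must have equal length")
    half = 1.0 / (2.0 * f)
    n_half = int(len(exc) * dt / half + 1e-9)
    rows = []
    for k in range(1, n_half + 1):
        i0 = int(round((k - 1) * half / dt))
        i1 = int(round(k * half / dt))
        e = float(np.sum(exc[i0:i1]) * dt)
        i = float(np.sum(inh[i0:i1]) * dt)
        s = float(np.sum(spike[i0:i1]) * dt) if spike is not None else np.nan
        rows.append({
            "half_cycle": k,
            "exc_integral": e,
            "inh_integral": i,
            "spike_integral": s,
            "ie_ratio": i / e if e > 0 else np.nan,
        })
    df = pd.DataFrame(rows)
    steady = df[df.half_cycle >= steady_from]
    for col in ("exc_integral", "inh_integral", "spike_integral", "ie_ratio"):
        m = steady[col].mean()
        df[col + "_norm"] = df[col] / m if m and np.isfinite(m) else np.nan
    return df


def windowed_ie(exc: np.ndarray, inh: np.ndarray, dt: float,
                window_s: float = 0.030, eps: float = 1e-9,
                threshold: float = 3.0) -> pd.DataFrame:
    """I/E ratios in consecutive 30-ms windows.

    Returns one row per window with the integrals, the ratio (NaN-flagged
    when the excitatory integral is <= ``eps``), and whether the ratio
    strictly exceeds ``threshold`` (ratios above ~3 can overcome the
    threefold excitatory driving-force advantage near spike threshold).
    """
    exc = np.asarray(exc, dtype=float)
    inh = np.asarray(inh, dtype=float)
    if exc.shape != inh.shape:
        raise ValueError("exc and inh traces must have equal length")
    nw = int(round(window_s / dt))
    n_bins = len(exc) // nw
    rows = []
    for b in range(n_bins):
        e = float(np.sum(exc[b * nw:(b + 1) * nw]) * dt)
        i = float(np.sum(inh[b * nw:(b + 1) * nw]) * dt)
        flagged = e <= eps
        ratio = np.nan if flagged else i / e
        rows.append({
            "window": b,
            "t_start": b * nw * dt,
            "exc_integral": e,
            "inh_integral": i,
            "ie_ratio": ratio,
            "flagged": flagged,
            "exceeds": bool(ratio > threshold) if not flagged else False,
        })
    return pd.DataFrame(rows)


def half_max_time(trace: np.ndarray, dt: float) -> float:
    """Time of the first crossing of half the (positive) peak, interpolated.

    The trace must be baseline-subtracted with a positive peak; returns NaN
    if there is no crossing (flat trace).
    """
    trace = np.asarray(trace, dtype=float)
    peak = trace.max()
    if peak <= 0:
        return float("nan")
    target = 0.5 * peak
    above = np.nonzero(trace >= target)[0]
    if len(above) == 0:
        return float("nan")
    i = above[0]
    if i == 0:
        return 0.0
    frac = (target - trace[i - 1]) / (trace[i] - trace[i - 1])
    return (i - 1 + frac) * dt


def harmonic_distortion(trace: np.ndarray, f: float, dt: float,
                        window: tuple | None = None, n_harmonics: int = 8) -> float:
    """Power above the fundamental relative to power at the fundamental.

    Measures how non-sinusoidal a response to a sinusoidal stimulus is:
    sum of squared DFT amplitudes at harmonics 2f..n_harmonics*f divided by
    the squared amplitude at f.
    """
    trace = np.asarray(trace, dtype=float)
    if window is None:
        i0, i1 = 0, len(trace)
    else:
        i0, i1 = int(round(window[0] / dt)), int(round(window[1] / dt))
    seg = trace[i0:i1]
    n_per = (i1 - i0) * dt * f
    if abs(n_per - round(n_per)) > 1e-6:
        raise ValueError("window must span an integer number of periods")
    t = np.arange(len(seg)) * dt
    amp = lambda freq: np.abs(np.sum(seg * np.exp(-2j * np.pi * freq * t)) * 2.0 / len(seg))
    a1 = amp(f)
    if a1 == 0:
        return float("inf")
    return float(sum(amp(k * f) ** 2 for k in range(2, n_harmonics + 1)) / a1 ** 2)
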