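"""Light-adaptation clamp: stimulus transformation that cancels cone adaptation.

Given a stimulus, the clamp searches for a transformed stimulus such that
the *adapting* cone model's response to the transformed stimulus matches the
*linear* cone model's response to the original.  For a sinusoidal stimulus
the linear response is sinusoidal, so the clamp finds the input for which an
adapting cone produces a sinusoidal output -- removing the history
dependence and increment/decrement asymmetry that adaptation imposes.

The optimizer is a deterministic, derivative-free coordinate search on
per-bin additive intensity offsets, coarse-to-fine: it starts from a few
bins per period, accepts only moves that lower the mean-squared difference
between the two model outputs, shrinks the step when no single-bin move
helps, and doubles the bin count (upsampling the offsets) until the relative
improvement across a refinement falls below tolerance.  All single-bin
candidate moves at a given step size are evaluated in one vectorized batch
of cone simulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import cones
from .cones import ConeParams, LinearConeFilter

logger = logging.getLogger(__name__)

__all__ = ["ClampOptions", "ClampResult", "clamp_stimulus"]


@dataclass
class ClampOptions:
    """Tuning knobs of the clamp search.

    ``start_bins`` offsets per period (or per 250 ms for aperiodic
    stimuli), doubled until ``max_bins``; refinement stops early when the
    relative MSE improvement across a bin level is below ``tol``.
    ``period`` (s) enables periodic mode: offsets for one period are tiled
    across the trace and the MSE excludes the first cycle.  ``max_mse`` only
    controls a warning flag on the result, never an exception.
    """

    tol: float = 1e-3
    start_bins: int = 8
    max_bins: int = 32
    period: float | None = None
    initial_step_frac: float = 0.10
    min_step_frac: float = 0.005
    max_iter_per_level: int = 25
    max_mse: float | None = None
    cone_dt: float = 1e-4
    mse_floor: float = 1e-20


@dataclass
class ClampResult:
    """Clamp output.

    ``mse_trajectories`` holds one list of accepted MSE values per search
    phase (periodic fit, then full-trace polish); each list is
    non-increasing by construction.  ``mse_trajectory`` is the final
    phase's list.
    """

    transformed_stimulus: np.ndarray
    target: np.ndarray
    response: np.ndarray
    mse_trajectories: list
    final_mse: float
    bin_schedule: list
    warning: bool = False

    @property
    def mse_trajectory(self) -> list:
        return self.mse_trajectories[-1]


def _upsample_offsets(offsets: np.ndarray, n_bins: int, n_samples: int,
                      period_samples: int | None) -> np.ndarray:
    """Expand per-bin offsets to a per-sample perturbation (ZOH, tiled if periodic)."""
    span = period_samples if period_samples else n_samples
    edges = np.linspace(0, span, n_bins + 1).astype(int)
    one = np.zeros(span)
    for b in range(n_bins):
        one[edges[b]:edges[b + 1]] = offsets[b]
    if period_samples:
        reps = int(np.ceil(n_samples / span))
        return np.tile(one, reps)[:n_samples]
    return one


def clamp_stimulus(
    original: np.ndarray,
    cone_params: ConeParams,
    lin_filter: LinearConeFilter,
    opts: ClampOptions | None = None,
    dt: float | None = None,
    forward: str = "adapting",
) -> ClampResult:
    """Find the transformed stimulus whose adapting-cone response matches the target.

    ``original`` is an intensity trace (R*/s) sampled at ``dt`` (defaults to
    ``opts.cone_dt``); the target is the linear-cone response to the
    original.  ``forward='linear'`` substitutes the linear model as the
    forward model (the identity case: the original already achieves zero
    error and is returned unchanged).

    The transformed stimulus is clipped at zero; the recorded
    ``mse_trajectory`` contains accepted iterations only and is
    non-increasing by construction.
    """
    if opts is None:
        opts = ClampOptions()
    original = np.asarray(original, dtype=float)
    if np.any(original < 0):
        raise ValueError("stimulus must be >= 0")
    if dt is None:
        dt = opts.cone_dt
    background = float(original[0])

    target = cones.simulate_linear_cone(original, lin_filter, dt=dt)
    n = len(original)
    period_samples = int(round(opts.period / dt)) if opts.period else None
    mse_start = period_samples if period_samples else 0  # periodic: skip first cycle

    def forward_response(stim_batch: np.ndarray) -> np.ndarray:
        if forward == "adapting":
            return cones.simulate_adapting_cone(
                stim_batch, cone_params, dt=dt, stim_dt=dt, background=background)
        return cones.simulate_linear_cone(stim_batch, lin_filter, dt=dt)

    def mse_of(resp: np.ndarray) -> np.ndarray:
        d = resp[..., mse_start:] - target[mse_start:]
        return np.mean(d * d, axis=-1)

    def build(offsets: np.ndarray, n_bins: int) -> np.ndarray:
        pert = _upsample_offsets(offsets, n_bins, n, period_samples)
        return np.clip(original + pert, 0.0, None)

    scale = background if background > 0 else float(np.max(original))
    mse_trajectories: list = []
    bin_schedule: list = []

    def search_phase(pert0: np.ndarray, start_bins: int, max_bins: int,
                     p_samples: int | None, m_start: int) -> np.ndarray:
        """Coarse-to-fine accept-if-better coordinate search; returns a per-sample perturbation."""

        def build_p(offsets: np.ndarray, n_bins: int) -> np.ndarray:
            pert = pert0 + _upsample_offsets(offsets, n_bins, n, p_samples)
            return np.clip(original + pert, 0.0, None)

        def mse_p(resp: np.ndarray) -> np.ndarray:
            d = resp[..., m_start:] - target[m_start:]
            return np.mean(d * d, axis=-1)

        n_bins = start_bins
        offsets = np.zeros(n_bins)
        current = float(mse_p(forward_response(build_p(offsets, n_bins))))
        mse_traj = [current]
        mse_trajectories.append(mse_traj)
        while True:
            bin_schedule.append(n_bins)
            level_start_mse = current
            if current <= opts.mse_floor:
                break
            step = opts.initial_step_frac * scale
            it = 0
            while step >= opts.min_step_frac * scale and it < opts.max_iter_per_level:
                it += 1
                # batch: +/- step on each bin -> 2 n_bins candidate stimuli
                cand = np.repeat(offsets[None, :], 2 * n_bins, axis=0)
                for b in range(n_bins):
                    cand[2 * b, b] += step
                    cand[2 * b + 1, b] -= step
                stims = np.stack([build_p(c, n_bins) for c in cand])
                mses = mse_p(forward_response(stims))
                best = int(np.argmin(mses))
                if mses[best] < current:
                    # try combining all improving moves; fall back to the best single one
                    improving = mses < current
                    combined = offsets.copy()
                    for b in range(n_bins):
                        if improving[2 * b] and mses[2 * b] <= mses[2 * b + 1]:
                            combined[b] += step
                        elif improving[2 * b + 1]:
                            combined[b] -= step
                    comb_mse = float(mse_p(forward_response(build_p(combined, n_bins))))
                    if comb_mse < mses[best]:
                        offsets, current = combined, comb_mse
                    else:
                        offsets = cand[best]
                        current = float(mses[best])
                    mse_traj.append(current)
                else:
                    step *= 0.5
            improvement = (level_start_mse - current) / level_start_mse if level_start_mse > 0 else 0.0
            if n_bins >= max_bins or improvement < opts.tol:
                break
            n_bins *= 2
            offsets = np.repeat(offsets, 2)
        return pert0 + _upsample_offsets(offsets, n_bins, n, p_samples)

    pert = search_phase(np.zeros(n), opts.start_bins, opts.max_bins,
                        period_samples, mse_start)
    if period_samples and pert.any():
        # full-trace polish: per-bin offsets over the whole trace (first cycle
        # included) remove the residual history dependence of the onset cycle
        n_periods = max(int(round(n / period_samples)), 1)
        pert = search_phase(pert, opts.start_bins * n_periods,
                            4 * opts.start_bins * n_periods, None, 0)

    transformed = np.clip(original + pert, 0.0, None)
    response = forward_response(transformed)
    final = float(mse_of(response))
    warn = opts.max_mse is not None and final > opts.max_mse
    if warn:
        logger.warning("clamp did not reach max_mse=%g (final %g)", opts.max_mse, final)
    return ClampResult(
        transformed_stimulus=transformed, target=target, response=response,
        mse_trajectories=mse_trajectories, final_mse=final, bin_schedule=bin_schedule,
        warning=warn,
    )
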