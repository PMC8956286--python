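"""Reproducible experiment pipelines chaining the library modules.

Each experiment writes a run directory containing a copy of its config, a
log of the stages executed, CSV/JSON outputs, and a ``summary.json`` with
the headline numbers.  Runs are deterministic under their seed; default
problem sizes are desk scale (a few minutes on one CPU).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clamp as clamp_mod
from . import clustering, cones, metrics, synth
from . import subunits
from .stimuli import (CenterRF, linear_equivalent_disc, make_grating, make_spot,
                      render_movie, simulate_eye_trajectory, EyeTrajectoryParams)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "EXPERIMENTS"]


@dataclass
class ExperimentConfig:
    """Named experiment + seed + output directory + free-form overrides."""

    name: str
    seed: int = 0
    outdir: str = "runs"
    params: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _setup(cfg: ExperimentConfig) -> Path:
    run_dir = Path(cfg.outdir) / f"{cfg.name}_seed{cfg.seed}"
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")
    return run_dir


def _finish(run_dir: Path, summary: dict, stages: list) -> dict:
    with open(run_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    with open(run_dir / "log.json", "w") as fh:
        json.dump({"stages": stages}, fh, indent=2)
    return summary


def grating_timecourse(cfg: ExperimentConfig) -> dict:
    """Contrast-reversing grating through the E/I model, adapting vs linear cones."""
    p = cfg.params
    run_dir = _setup(cfg)
    f = p.get("temporal_freq", 4.0)
    contrast = p.get("contrast", 0.5)
    duration = p.get("duration", 2.0)
    rf = CenterRF(sigma_c=p.get("sigma_c", 60.0))
    stim = make_grating("contrast_reversing", contrast, f, rf.aperture_radius, rf,
                        duration=duration)
    model = subunits.SubunitModelConfig(sigma_c=rf.sigma_c, seed=cfg.seed)
    stages, summary = [], {}
    for fe in ("adapting", "linear"):
        t0 = time.time()
        r = subunits.run_ei_model(stim, dataclasses.replace(model, cone_front_end=fe), rf)
        df = metrics.half_cycle_stats(r.exc_drive, r.inh_drive, f, r.dt, spike=r.spike_proxy)
        df.to_csv(run_dir / f"half_cycles_{fe}.csv", index=False)
        steady = df[df.half_cycle >= 6].ie_ratio.mean()
        fc_e = metrics.fourier_components(r.exc_drive, f, r.dt, window=(1.0 / f, duration))
        fc_i = metrics.fourier_components(r.inh_drive, f, r.dt, window=(1.0 / f, duration))
        summary[fe] = {
            "first_ie_ratio": float(df.ie_ratio.iloc[0]),
            "steady_ie_ratio": float(steady),
            "ie_elevation_pct": float(100.0 * (df.ie_ratio.iloc[0] / steady - 1.0)),
            "exc_inh_phase_deg": fc_i["F2_phase_deg"] - fc_e["F2_phase_deg"],
        }
        stages.append({"stage": f"ei_model_{fe}", "seconds": round(time.time() - t0, 2)})
    return _finish(run_dir, summary, stages)


def flashed_patches(cfg: ExperimentConfig) -> dict:
    """Flashed natural-like patches: NLI of exc vs spike output across variants."""
    p = cfg.params
    run_dir = _setup(cfg)
    rf = CenterRF(sigma_c=p.get("sigma_c", 60.0))
    n_patches = p.get("n_patches", 50)
    img = synth.make_image(synth.ImageGenSpec(seed=cfg.seed))
    patches = synth.sample_patches(img, rf, n_patches, seed=cfg.seed + 1,
                                   require_bright=True, background=4000.0)
    base = subunits.SubunitModelConfig(sigma_c=rf.sigma_c, seed=cfg.seed)
    rows = []
    for variant in subunits.VARIANTS:
        model = subunits.apply_variant(base, variant)
        for i, patch in enumerate(patches):
            disc = linear_equivalent_disc(patch, rf)
            ri = subunits.run_ei_static(patch, model, rf)
            rd = subunits.run_ei_static(disc, model, rf)
            rows.append({
                "variant": variant, "patch": i,
                "exc_nli": metrics.nli(ri.exc_drive, rd.exc_drive),
                "spike_nli": metrics.nli(ri.spike_proxy, rd.spike_proxy),
                "ie_ratio": ri.inh_drive / ri.exc_drive if ri.exc_drive > 0 else np.nan,
            })
    df = pd.DataFrame(rows)
    df.to_csv(run_dir / "patch_nli.csv", index=False)
    summary = {}
    for variant, g in df.groupby("variant"):
        summary[variant] = {
            "mean_exc_nli": float(g.exc_nli.mean()),
            "mean_spike_nli": float(np.nanmean(g.spike_nli)),
            "delta_nli": float(g.exc_nli.mean() - np.nanmean(g.spike_nli)),
        }
    return _finish(run_dir, summary, [{"stage": "variants", "n_patches": n_patches}])


def clamp_gratings(cfg: ExperimentConfig) -> dict:
    """Light-adaptation clamp on a sinusoidal grating pixel class."""
    p = cfg.params
    run_dir = _setup(cfg)
    f = p.get("temporal_freq", 4.0)
    contrast = p.get("contrast", 0.5)
    n_cycles = p.get("n_cycles", 3)
    dt = 1e-4
    B = 4000.0
    filt = subunits.get_linear_filter(cones.DEFAULT_CONE_PARAMS, B)
    t = np.arange(0, n_cycles / f, dt)
    orig = B * (1.0 + contrast * np.sin(2.0 * np.pi * f * t))
    res = clamp_mod.clamp_stimulus(orig, cones.DEFAULT_CONE_PARAMS, filt,
                                   clamp_mod.ClampOptions(period=1.0 / f), dt=dt)
    r_orig = cones.simulate_adapting_cone(orig, dt=dt, stim_dt=dt)
    n = int(1.0 / f / dt)
    w = (1.0 / f, n_cycles / f)
    pd.DataFrame({"time_s": t, "original": orig, "transformed": res.transformed_stimulus,
                  "resp_original": r_orig, "resp_transformed": res.response,
                  "target": res.target}).to_csv(run_dir / "clamp_traces.csv", index=False)
    seg_o, seg_t = r_orig[n:], res.response[n:]
    summary = {
        "final_mse": res.final_mse,
        "distortion_original": metrics.harmonic_distortion(r_orig, f, dt, window=w),
        "distortion_clamped": metrics.harmonic_distortion(res.response, f, dt, window=w),
        "cycle_ratio_original": float(r_orig[:n].max() / r_orig[n:2 * n].max()),
        "cycle_ratio_clamped": float(res.response[:n].max() / res.response[n:2 * n].max()),
        "dec_inc_original": float(-seg_o.min() / seg_o.max()),
        "dec_inc_clamped": float(-seg_t.min() / seg_t.max()),
    }
    return _finish(run_dir, summary, [{"stage": "clamp", "bins": res.bin_schedule}])


def natural_movie_ie(cfg: ExperimentConfig) -> dict:
    """Eye-movement movies over synthetic scenes: windowed I/E, adapting vs linear."""
    p = cfg.params
    run_dir = _setup(cfg)
    n_images = p.get("n_images", 5)
    duration = p.get("duration", 0.9)
    rf = CenterRF(sigma_c=p.get("sigma_c", 60.0))
    model = subunits.SubunitModelConfig(sigma_c=rf.sigma_c, seed=cfg.seed)
    rows = []
    stages = []
    for i in range(n_images):
        t0 = time.time()
        img = synth.make_image(synth.ImageGenSpec(seed=cfg.seed + 100 + i))
        traj = simulate_eye_trajectory(duration, EyeTrajectoryParams(seed=cfg.seed + 200 + i))
        movie = render_movie(img, traj, rf)
        for fe in ("adapting", "linear"):
            r = subunits.run_ei_model(movie, dataclasses.replace(model, cone_front_end=fe), rf)
            df = metrics.windowed_ie(r.exc_drive, r.inh_drive, r.dt)
            df["image"] = i
            df["front_end"] = fe
            rows.append(df)
        stages.append({"stage": f"image_{i}", "seconds": round(time.time() - t0, 2)})
    all_df = pd.concat(rows, ignore_index=True)
    all_df.to_csv(run_dir / "windowed_ie.csv", index=False)
    summary = {}
    for fe, g in all_df.groupby("front_end"):
        summary[fe] = {
            "n_windows": int(len(g)),
            "n_exceeding_3": int(g.exceeds.sum()),
            "median_ie": float(g.ie_ratio.median()),
        }
    return _finish(run_dir, summary, stages)


def contours_experiment(cfg: ExperimentConfig) -> dict:
    """Constant-response contours of linear/nonlinear On/Off models."""
    from . import contours as cont

    p = cfg.params
    run_dir = _setup(cfg)
    rf = CenterRF(sigma_c=p.get("sigma_c", 60.0))
    n_patches = p.get("n_patches", 600)
    skew = p.get("pixel_skew_target", -0.5)
    img = synth.make_image(synth.ImageGenSpec(seed=cfg.seed, pixel_skew_target=skew))
    patches = synth.sample_patches(img, rf, n_patches, seed=cfg.seed + 1)
    summary = {}
    for pol in ("on", "off"):
        for integ in ("linear", "nonlinear"):
            surf = cont.response_surface(patches, rf, pol, integ, seed=cfg.seed)
            np.savetxt(run_dir / f"surface_{pol}_{integ}.csv", surf.mean_response, delimiter=",")
            finite = surf.mean_response[np.isfinite(surf.mean_response)]
            levels = np.percentile(finite, [40, 60])
            cs = cont.constant_response_contours(surf, levels)
            slopes = [cont.contour_slope(v) for v in cs.values()]
            summary[f"{pol}_{integ}_contour_slope"] = float(np.nanmean(slopes))
    return _finish(run_dir, summary, [{"stage": "contours", "n_patches": n_patches}])


def cluster_demo(cfg: ExperimentConfig) -> dict:
    """Template inhibitory traces through the clustering pipeline."""
    from sklearn.metrics import adjusted_rand_score

    p = cfg.params
    run_dir = _setup(cfg)
    noise = p.get("noise_sd", 0.2)
    traces, labels, _ = synth.make_template_traces(n_per=p.get("n_per", 20),
                                                   noise_sd=noise, seed=cfg.seed)
    model, assignments = clustering.fit_clusters(traces, seed=cfg.seed)
    model.to_json(run_dir / "cluster_model.json")
    pd.DataFrame({"true_label": labels,
                  "assigned": [model.labels[a] for a in assignments]}
                 ).to_csv(run_dir / "assignments.csv", index=False)
    ari = adjusted_rand_score(labels, assignments)
    return _finish(run_dir, {"ari": float(ari), "noise_sd": noise},
                   [{"stage": "cluster", "n_traces": len(traces)}])


EXPERIMENTS = {
    "grating_timecourse": grating_timecourse,
    "flashed_patches": flashed_patches,
    "clamp_gratings": clamp_gratings,
    "natural_movie_ie": natural_movie_ie,
    "contours": contours_experiment,
    "cluster_demo": cluster_demo,
}


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Dispatch a named experiment; returns its summary dict."""
    if cfg.name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {cfg.name!r}; valid: {sorted(EXPERIMENTS)}")
    return EXPERIMENTS[cfg.name](cfg)
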