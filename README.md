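# parasolsim

Simulation and analysis tools for a question in retinal circuit computation:
why do primate **On parasol retinal ganglion cells** respond nonlinearly to
spatial structure in periodic gratings but near-linearly to flashed patches
and natural movies?  The package implements the in-silico machinery needed to
study this stimulus dependence: an adapting cone phototransduction model and
its matched linear control, excitatory/inhibitory (E/I) subunit
receptive-field models, a "light-adaptation clamp" stimulus optimizer,
calibrated stimulus generators (gratings, spots, linear-equivalent discs,
fixational eye-movement movies), response statistics (NLI, F1/F2, I/E
ratios), PCA + k-means clustering of inhibitory time courses, and
constant-response-contour analysis of On/Off models.

## The model in brief

**Cone front end.**  Phototransduction is the standard five-state cascade:
opsin activity R drives PDE activity P; cGMP G obeys
dG/dt = s_max / (1 + (C/K_GC)^h) − P·G; the circulating current is
I = k·G^n; calcium C enters in proportion to I and feeds back on cGMP
synthesis.  Light-driven increases in P lower the current and engage rapid
gain adaptation (τ ≈ 50 ms at 4000 R\*/s).  The linear control is the
impulse response of the same model to a brief, low-contrast flash.

**E/I subunit model.**  The receptive-field center is tiled by independent
regular grids of Gaussian subunits — excitatory (SD = σ_c/5) and inhibitory
(50% larger).  Each subunit filters the input, applies a contrast–response
nonlinearity (excitatory: a shallow softplus rectifier; inhibitory: a
U-shape whose negative-contrast **crossover** lobe dominates the positive
**feedforward** lobe), and the subunit outputs are summed with Gaussian
center weights.  The spike proxy is max(0, 3·E − I), the threefold
excitatory weight reflecting driving forces near spike threshold.

**Nonlinearity index.**  For a flashed image patch and its
*linear-equivalent disc* (a uniform disc at the RF-weighted mean intensity),

    NLI = (R_image − R_disc) / (R_image + R_disc)

is 0 for spatially linear integration and 1 for fully nonlinear integration.

**Light-adaptation clamp.**  A derivative-free coarse-to-fine search for a
transformed stimulus such that the adapting cone's response to the transform
matches the linear cone's response to the original — i.e., a stimulus that
cancels adaptation.

## Worked example

```python
import dataclasses
from parasolsim import SubunitModelConfig, CenterRF, make_grating, run_ei_model, half_cycle_stats

rf = CenterRF(sigma_c=60.0)                       # parasol center, 120-um aperture
stim = make_grating("contrast_reversing", contrast=0.5, temporal_freq=4.0,
                    bar_width=rf.aperture_radius, rf=rf, duration=2.0)
cfg = SubunitModelConfig(sigma_c=rf.sigma_c, cone_front_end="adapting")
r = run_ei_model(stim, cfg, rf)
df = half_cycle_stats(r.exc_drive, r.inh_drive, 4.0, r.dt)
steady = df[df.half_cycle >= 6].ie_ratio.mean()
print(f"first-cycle I/E {df.ie_ratio.iloc[0]:.2f}, steady {steady:.2f}, "
      f"elevation {100 * (df.ie_ratio.iloc[0] / steady - 1):.1f}%")
```

prints

```
first-cycle I/E 5.39, steady 2.99, elevation 80.3%
```

The first half-cycle of a split-field grating drives a much larger ratio of
inhibitory to excitatory input than the steady state — because all cones
start from a common adaptational state, the increment-driven excitatory
drive is small and slow while the decrement-driven crossover inhibition is
large.  Rerunning with `cone_front_end="linear"` gives an elevation of ~4%:
without cone adaptation the effect disappears, which is the package's
central result.

The same pipelines are available from the shell, e.g.

```
parasol repro grating_timecourse --seed 0 --out runs/
parasol repro all --seed 0 --out runs/
```

Each run directory contains a copy of its config, a log, tidy CSV outputs,
and a `summary.json`.

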