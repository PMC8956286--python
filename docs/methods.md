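# Methods

This note documents the models, their parameters, the synthetic data the
tests run on, and the numerical and design choices made where the design was
genuinely open.  No empirical claim is made here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cone phototransduction model

The adapting cone is the canonical five-state cascade:

    dR/dt = γ·S(t) − σ·R                    (opsin activity, S in R*/s)
    dP/dt = R + η − φ·P                     (PDE activity)
    dG/dt = s_max / (1 + (C/K_GC)^h) − P·G  (cGMP)
    I     = k·G^n                           (outward current)
    dC/dt = q·I − β·C                       (calcium)

Light raises P, lowering G and the current; the calcium feedback on cGMP
synthesis restores gain with a time constant of tens of milliseconds at
photopic backgrounds — the adaptation at the heart of this package.

Default parameters (all config, YAML-serializable): γ = 10 /R\*, σ = φ =
22 s⁻¹, η = 2000 s⁻¹, k = 0.01, n = 3, β = 9 s⁻¹, K_GC = 0.5, h = 4, with
s_max and q fixed by the dark fixed point G = 20, C = 1, I = 80 (arbitrary
current units).  This is the field-standard primate-cone parameter regime;
at the working background of 4000 R\*/cone/s it reproduces the three
qualitative adaptation signatures the downstream modeling depends on —
a suppressed first half-cycle response to a sinusoid, larger decrement than
increment excursions, faster dark→light than light→dark kinetics — and a
probe-flash gain that decays after a light step with τ ≈ 57 ms (< 100 ms).
The test suite asserts all four.

Numerics: fixed-step RK4 at dt = 0.05 ms (tests and movie pipelines use the
0.1 ms ceiling), zero-order-hold interpolation of frame-rate stimuli,
vectorized across pixel batches.  Steady states come from a monotone 1-D
Brent root solve in G; residuals are checked to 1e−9.  Responses are
reported baseline-subtracted, increments positive.  Only the photocurrent is
modeled — voltage, rods, S-cones, and horizontal-cell feedback are out of
scope.

The linear (nonadapting) control is the impulse response measured from the
full model with a 1%-contrast, 2-ms flash, shifted by half the flash
duration (the boxcar's effective impulse time is its midpoint), truncated
when decayed below 0.5% of peak.  An internal halving check rejects flashes
outside the linear range.  At ≤ 2% contrast the adapting and linear models
agree within 5% RMS.

## E/I subunit model

Square lattices of Gaussian subunits tile the receptive-field center
(aperture diameter 2σ_c; σ_c = 60 µm by default, pixel pitch = cone spacing
= 3 µm).  Excitatory subunits: SD = spacing = σ_c/5 = 12 µm; inhibitory:
50% larger.  Each pathway's lattice has an independent seeded phase offset.
Subunit filters are unit-normalized; center weights are a σ_c Gaussian
normalized to 1 per pathway.  Spike proxy = max(0, 3·E − I), with no spike
dynamics, noise, or refractoriness.

With a cone front end, the cascade (or linear filter) is applied per pixel
and its output divided by the peak linear-cone response to a 100% contrast,
250-ms step, so the same contrast–response curves serve the static
(time-free) and cone-driven modes.  For gratings the per-pixel simulation
collapses to the stimulus's unique pixel classes, which keeps those runs
cheap.

### Contrast–response calibration

The measured parasol contrast–response functions are not published as
tables, so the shipped curves are calibrated stand-ins with the qualitative
shapes reported for these cells:

- excitatory: softplus rectifier `a (log(1+exp(b c)) − log 2)` with
  **a = 2.0, b = 2.5** — expansive around zero, linear for strong
  increments, and saturating at a modest negative level (−a·log 2) for
  decrements.  The shallow negative saturation matters: it lets the large,
  slow decrement responses of adapting cones cut into the excitatory drive
  at grating onset.  Sharp rectifiers (b ≥ 8) cap the first-cycle I/E
  elevation near 20–30% and cannot reproduce the predicted 70–80% band.
- inhibitory: U-shape `a₊ relu(c)^p + a₋ relu(−c)^p` with **a₊ = 0.6,
  a₋ = 2.4, p = 1** — a fourfold-dominant crossover (Off-pathway) lobe.
  The lobes are linear; the U itself supplies the spatially nonlinear
  integration (a uniform disc drives the curve near its minimum, a
  structured patch drives both lobes).

Under this single calibration the package's tests measure: first-half-cycle
I/E elevation of 80% with adapting cones vs 4% with linear cones (4 Hz, 50%
split-field grating); mean excitatory-minus-spike NLI on flashed
natural-like patches of +0.10 (base model), +0.09 (no feedforward), +0.03
(doubled inhibitory subunits), −0.01 (linear inhibition).  The elevation
magnitude depends on the subunit-lattice phase relative to the split-field
boundary (42–81% across phase draws; the linear-cone control stays below
10% at every phase); the shipped default configuration is the calibration
point and `scripts/acceptance.py` runs exactly that configuration, making
its output deterministic.

Curves are stored as piecewise-linear tables on [−1, 1] (513 breakpoints)
with clamped extrapolation and a logged out-of-domain count.

### Simplified one-pathway models

For the constant-response-contour analysis the model drops the inhibitory
pathway.  The nonlinear branch half-wave rectifies subunit outputs before
the center-weighted sum; the Off polarity negates input contrast.  The
linear branch is implemented as the exact Gaussian-RF weighted mean of pixel
contrast — the zero-size-subunit limit — so that a spatially linear model
responds *identically* (to 1e−10) to a patch and its linear-equivalent
disc, which is the defining invariant tying the model to the disc
construction.  A finite-σ linear subunit cascade would differ from the disc
weighting at the 1e−3 level.

## Stimuli

All stimuli are height × width × time arrays in R\*/cone/s at a 60 Hz frame
rate, confined to the circular aperture (background outside).  Square-wave
gratings are mean-corrected to exactly zero spatial mean over the aperture;
contrast-reversing stimuli start at sine phase 0 so the first frame is
uniform.  Eye movements follow a discrete random walk (±1 cone spacing per
axis per ms, equal probability, no zero step) interrupted every 300 ms —
first saccade at t = 300 ms, none at t = 0 — by jumps uniform on ±100 cone
spacings per axis.  Movies are rendered with the nearest-sample (integer
pixel) translation policy; images are reflect-padded by the jump range plus
three diffusion standard deviations and a trajectory leaving the pad raises
an error rather than wrapping.  Images are linearly scaled so their mean
maps to the 4000 R\*/s background.

## Light-adaptation clamp

The clamp minimizes the mean-squared difference between the adapting
model's response to a perturbed stimulus and the linear model's response to
the original.  Perturbations are per-bin additive intensity offsets; the
search is a deterministic accept-if-better coordinate descent that
evaluates all ±step single-bin moves in one vectorized batch, tries the
combined improving move, halves the step when nothing helps, and doubles
the bin count (starting at 8 per period, to 32) until the relative MSE
improvement falls below 1e−3.  Periodic stimuli are fit with per-period
offsets (first cycle excluded from the error), then polished with
full-trace bins including the onset cycle — the polish is what removes the
first-cycle history dependence.  The transformed stimulus is clipped at
zero; accepted-move MSE sequences are non-increasing per phase; failure to
reach a requested error sets a warning flag, never an exception.  When the
forward model is itself linear the initial error is zero and the original
stimulus is returned unchanged.

Measured on the 4 Hz, 50% contrast sinusoid: harmonic distortion of the
adapting response drops ~800-fold, the increment/decrement asymmetry moves
from 1.08 to 1.00, and the first/second-cycle ratio moves to the linear
target's own value (0.91).

## Clustering of inhibitory time courses

Traces are centered on the mean trace (the amplitude scale is retained —
amplitude legitimately separates the clusters), projected on the first
three principal components, and partitioned by k-means (k = 3, 20 seeded
k-means++ restarts, best by within-cluster sum of squares).  Cluster
indices are arbitrary, so they are relabeled deterministically from the
reconstructed centroid time courses: earliest peak → *feedforward*; of the
remaining two, larger peak → *crossover*; the last → *mixed*.  Only k = 3
is supported (config-overridable), and degenerate trace sets fall back to
the available PCA rank with a warning.

## Synthetic data

The natural-image stand-in is a Gaussian random field with a 1/f² amplitude
spectrum, pushed through a monotone exponential transform tuned by
bisection to a target pixel skewness (default −0.5, i.e., dark-abundant;
0 gives the symmetric control), scaled to mean 4000 R\*/s at RMS contrast
0.35 (matching the ~0.3 average spatial contrast of natural patches probed
in this preparation), and clipped at zero (error if ≥ 1% of pixels clip).
These two dials — spectrum and skew — are exactly the image statistics the
contour analysis depends on; the generator does not attempt photometric
realism, object structure, or the heavy bright tails of real scenes, so
passing tests demonstrate the mechanisms, not quantitative predictions for
any particular natural image.  Template inhibitory traces are alpha
functions: feedforward fast and onset-locked, crossover twice as large and
offset-locked, mixed a 0.35-scaled sum.  Synthetic "recordings" shape the
static model's scalar drive into a 250-ms pulse and add independent
Gaussian noise per trial and sample (6 repeats by default); they are a
synthetic stand-in for voltage-clamp data, used only to exercise the
statistics layer.

## Metrics conventions

Half-cycle k spans [(k−1)/(2f), k/(2f)] from stimulus onset; steady-state
normalization divides by the mean over half-cycles ≥ 6.  Sinusoid "fits"
are DFT components at the specified frequency (equivalent to fixed-frequency
least squares); windows must span integer period counts.  Phase-to-time
conversion takes the component frequency explicitly because both the
fundamental and the doubled frequency are legitimate conventions for
frequency-doubled responses.  I/E ratios are integrals over 30-ms windows;
windows with non-positive excitatory integrals are flagged rather than
propagated, and the ratio-above-3 flag marks inhibition large enough to
overcome the threefold excitatory driving-force advantage.  Iso-response
contour *tilt* is summarized two ways: polyline slope on a binned surface,
and a regression-implied slope −β_contrast/β_luminance; the On/Off mirror
comparison uses SD/background rather than SD/mean as the structure
covariate because SD/mean warps under luminance negation.

## Problem sizes

Defaults are desk scale: 2-s gratings, 0.9-s eye-movement movies over
256×256 images with a 40×40-pixel aperture, 50–60 patches for NLI
analyses, 1500 patches for contour surfaces, 20 scenes for the
natural-movie I/E comparison.  These sizes were chosen so the full pipeline
(tests plus acceptance script) completes in minutes on one CPU while
leaving every comparison well clear of its decision threshold.

## Known limitations

- Subunit nonlinearity shapes are calibrated stand-ins, not measured
  curves; only their qualitative class is constrained.
- The first-cycle I/E elevation magnitude varies with the subunit-lattice
  phase (42–81%); the direction of the effect and the < 10% linear-cone
  control do not.
- No receptive-field surround, spike generation, synaptic depression, or
  cone-to-cone coupling; Off-cell behavior is obtained by polarity flips
  only.
- The clamp optimizes single traces (gratings have two unique pixel
  classes); spatiotemporal movies would need a per-pixel map.
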