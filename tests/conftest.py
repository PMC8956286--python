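"""Shared fixtures: receptive field, cone filter, synthetic patch sets, model runs.

Heavy simulations are session-scoped so unit and acceptance tests share them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from parasolsim import cones, metrics, subunits, synth
from parasolsim.stimuli import CenterRF, StimulusMovie, make_grating

BACKGROUND = 4000.0


@pytest.fixture(scope="session")
def rf():
    return CenterRF(sigma_c=60.0)


@pytest.fixture(scope="session")
def cone_filter():
    """Linear cone filter at the photopic background (shared, cached)."""
    return subunits.get_linear_filter(cones.DEFAULT_CONE_PARAMS, BACKGROUND)


@pytest.fixture(scope="session")
def natural_image():
    return synth.make_image(synth.ImageGenSpec(seed=1))


@pytest.fixture(scope="session")
def bright_patches(natural_image, rf):
    """Sixty natural-like patches brighter than the background in the RF center."""
    return synth.sample_patches(natural_image, rf, 60, seed=2,
                                require_bright=True, background=BACKGROUND)


@pytest.fixture(scope="session")
def split_field_grating(rf):
    """4 Hz, 50% contrast split-field contrast-reversing grating, 2 s."""
    return make_grating("contrast_reversing", 0.5, 4.0, rf.aperture_radius, rf,
                        duration=2.0)


@pytest.fixture(scope="session")
def grating_ei_runs(split_field_grating, rf):
    """Base E/I model driven by the grating with adapting and linear cones."""
    cfg = subunits.SubunitModelConfig(sigma_c=rf.sigma_c)
    out = {}
    for fe in ("adapting", "linear"):
        r = subunits.run_ei_model(split_field_grating,
                                  dataclasses.replace(cfg, cone_front_end=fe), rf)
        out[fe] = r
    return out


@pytest.fixture(scope="session")
def grating_half_cycles(grating_ei_runs):
    return {fe: metrics.half_cycle_stats(r.exc_drive, r.inh_drive, 4.0, r.dt,
                                         spike=r.spike_proxy)
            for fe, r in grating_ei_runs.items()}


@pytest.fixture(scope="session")
def patch_sets(rf):
    """Dark-skewed (natural-like) and symmetric patch sets (1500 each)."""
    out = {}
    for name, skew in (("skewed", -0.5), ("symmetric", 0.0)):
        img = synth.make_image(synth.ImageGenSpec(seed=21, pixel_skew_target=skew))
        out[name] = synth.sample_patches(img, rf, 1500, seed=22)
    return out


def model_tilt(patches, rf, polarity, integration):
    """Implied iso-response slope d(luminance)/d(contrast) by linear regression.

    Luminance is the RF-weighted mean contrast; spatial structure is measured
    as SD/background (warp-free under luminance negation, so On/Off mirror
    symmetry is testable).  The tilt is -(contrast coefficient)/(luminance
    coefficient).
    """
    from parasolsim.stimuli import aperture_mask, center_weights
    from parasolsim.subunits import run_simple_model

    mask = aperture_mask(rf, 3.0)
    w = center_weights(rf, 3.0)
    X, y = [], []
    for p in patches:
        dm = (np.sum(w * p) / w.sum() - BACKGROUND) / BACKGROUND
        cB = p[mask].std() / BACKGROUND
        X.append([1.0, dm, cB])
        y.append(run_simple_model(p, polarity, integration, rf))
    coef, *_ = np.linalg.lstsq(np.array(X), np.array(y), rcond=None)
    return float(-coef[2] / coef[1])


@pytest.fixture(scope="session")
def tilts(rf, patch_sets):
    out = {}
    for name, patches in patch_sets.items():
        for pol in ("on", "off"):
            for integ in ("linear", "nonlinear"):
                out[(name, pol, integ)] = model_tilt(patches, rf, pol, integ)
    return out


def flash_movie(patch: np.ndarray, background: float = BACKGROUND,
                flash: float = 0.25, total: float = 0.5) -> StimulusMovie:
    """Patch flashed from a gray background for 250 ms."""
    nf = int(round(total * 60.0))
    t = np.arange(nf) / 60.0
    frames = np.stack([patch if tt < flash else np.full_like(patch, background)
                       for tt in t], axis=2)
    return StimulusMovie(frames)
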