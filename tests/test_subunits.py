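"""E/I subunit model: grids, nonlinearities, variants, oracle equivalences."""

import dataclasses

import numpy as np
import pytest

from parasolsim import subunits
from parasolsim.stimuli import (CenterRF, aperture_mask, center_weights,
                                linear_equivalent_disc, make_grating)
from parasolsim.subunits import (NonlinearityCurve, SubunitModelConfig,
                                 apply_variant, build_subunit_grid,
                                 run_ei_static, run_simple_model)

B = 4000.0


class TestNonlinearityCurves:
    def test_identity(self):
        c = NonlinearityCurve.identity()
        x = np.linspace(-1, 1, 7)
        assert np.allclose(c(x), x)

    def test_no_feedforward_zeroes_positive_lobe_only(self):
        base = NonlinearityCurve.u_shaped(0.6, 2.4, 1.0)
        cut = base.without_positive_lobe()
        assert cut(0.5) == 0.0
        assert cut(-0.5) == base(-0.5)

    def test_u_shape_crossover_dominates(self):
        c = NonlinearityCurve.u_shaped(0.6, 2.4, 1.0)
        assert c(-0.5) > c(0.5) > 0

    def test_out_of_domain_clamped(self):
        c = NonlinearityCurve.identity()
        assert c(2.0) == 1.0 and c(-2.0) == -1.0

    def test_invalid_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            NonlinearityCurve(np.array([0.0, 0.0, 1.0]), np.zeros(3))


class TestVariants:
    def test_variant_transformations(self):
        cfg = SubunitModelConfig()
        lin = apply_variant(cfg, "linear_inhibition")
        assert lin.inh_nonlinearity(0.37) == pytest.approx(0.37)
        noff = apply_variant(cfg, "no_feedforward_inhibition")
        assert noff.inh_nonlinearity(0.5) == 0.0
        assert noff.inh_nonlinearity(-0.5) == cfg.inh_nonlinearity(-0.5)
        big = apply_variant(cfg, "big_inhibitory_subunits")
        assert big.inh_subunit_sigma == pytest.approx(2 * cfg.inh_subunit_sigma)
        assert big.inh_spacing == pytest.approx(2 * cfg.inh_spacing)

    def test_base_config_untouched(self):
        cfg = SubunitModelConfig()
        sigma0 = cfg.inh_subunit_sigma
        apply_variant(cfg, "big_inhibitory_subunits")
        apply_variant(cfg, "linear_inhibition")
        assert cfg.inh_subunit_sigma == sigma0
        assert cfg.inh_nonlinearity(0.5) != 0.5

    def test_unknown_variant_lists_valid_names(self):
        with pytest.raises(ValueError, match="linear_inhibition"):
            apply_variant(SubunitModelConfig(), "bogus")


class TestGrids:
    def test_center_weights_sum_to_one(self, rf):
        g = build_subunit_grid(12.0, 12.0, rf, 3.0, rng=np.random.default_rng(0))
        assert g.center_weights.sum() == pytest.approx(1.0)
        assert np.allclose(g.filters.sum(axis=1), 1.0)

    def test_doubling_sigma_halves_linear_density(self, rf):
        n_base = len(build_subunit_grid(18.0, 18.0, rf, 3.0,
                                        rng=np.random.default_rng(0)).positions)
        n_big = len(build_subunit_grid(36.0, 36.0, rf, 3.0,
                                       rng=np.random.default_rng(0)).positions)
        # half the linear density -> a quarter of the count, within lattice rounding
        assert n_big == pytest.approx(n_base / 4, abs=3)

    def test_single_subunit_reduces_to_ln_model(self, rf):
        """A one-subunit grid is a single LN unit: response = NL(filtered contrast)."""
        cfg = SubunitModelConfig(exc_subunit_sigma=rf.sigma_c, inh_subunit_sigma=rf.sigma_c)
        pos = np.array([[0.0, 0.0]])
        rng = np.random.default_rng(4)
        patch = np.clip(B * (1.0 + 0.3 * rng.standard_normal(aperture_mask(rf, 3.0).shape)),
                        0.0, None)
        r = run_ei_static(patch, cfg, rf, exc_positions=pos, inh_positions=pos)
        g = build_subunit_grid(rf.sigma_c, rf.sigma_c, rf, 3.0, positions=pos)
        s = float(g.filters[0] @ ((patch.ravel() - B) / B))
        assert r.exc_drive == pytest.approx(float(cfg.exc_nonlinearity(s)), rel=1e-12)

    def test_spacing_exceeding_aperture_rejected(self, rf):
        with pytest.raises(ValueError):
            build_subunit_grid(10.0, 500.0, rf, 3.0, rng=np.random.default_rng(0))


def _two_subunit_setup(rf):
    """Two narrow subunits, one per half-field of a split-field grating."""
    pos = np.array([[-30.0, 0.0], [30.0, 0.0]])
    cfg = SubunitModelConfig(exc_subunit_sigma=3.0, inh_subunit_sigma=3.0)
    return pos, cfg


class TestTwoSubunitOracle:
    """Brute-force hand computation against the vectorized model."""

    def test_linear_subunits_cancel_on_split_field(self, rf):
        pos, cfg = _two_subunit_setup(rf)
        cfg = dataclasses.replace(cfg, exc_nonlinearity=NonlinearityCurve.identity())
        m = make_grating("contrast_reversing", 0.5, 3.75, rf.aperture_radius, rf,
                         duration=0.5)
        peak = m.frames[:, :, 4]
        r = run_ei_static(peak, cfg, rf, exc_positions=pos, inh_positions=pos)
        assert abs(r.exc_drive) < 1e-10

    def test_half_wave_rectifier_gives_half_contrast(self, rf):
        pos, cfg = _two_subunit_setup(rf)
        relu = NonlinearityCurve(np.array([-1.0, 0.0, 1.0]), np.array([0.0, 0.0, 1.0]))
        cfg = dataclasses.replace(cfg, exc_nonlinearity=relu)
        c = 0.5
        m = make_grating("contrast_reversing", c, 3.75, rf.aperture_radius, rf,
                         duration=0.5)
        peak = m.frames[:, :, 4]
        r = run_ei_static(peak, cfg, rf, exc_positions=pos, inh_positions=pos)
        # each subunit sees +/-c; rectified and averaged with equal weights: c/2
        assert r.exc_drive == pytest.approx(c / 2.0, rel=1e-6)

    def test_brute_force_matches_model_to_1e10(self, rf, split_field_grating):
        """Explicit loops over pixels and subunits reproduce run_ei_static exactly."""
        pos, cfg = _two_subunit_setup(rf)
        peak = split_field_grating.frames[:, :, 4]
        r = run_ei_static(peak, cfg, rf, exc_positions=pos, inh_positions=pos)

        x, y, n = subunits._grid_um(rf, 3.0)
        px = np.broadcast_to(x, (n, n)).ravel()
        py = np.broadcast_to(y, (n, n)).ravel()
        contrast = (peak.ravel() - B) / B
        drives = {}
        for name, sigma, curve in (("exc", cfg.exc_subunit_sigma, cfg.exc_nonlinearity),
                                   ("inh", cfg.inh_subunit_sigma, cfg.inh_nonlinearity)):
            outs, ws = [], []
            for (sx, sy) in pos:
                wpix = np.array([np.exp(-((a - sx) ** 2 + (b - sy) ** 2) / (2 * sigma ** 2))
                                 for a, b in zip(px, py)])
                wpix /= wpix.sum()
                outs.append(float(curve(np.dot(wpix, contrast))))
                ws.append(np.exp(-(sx ** 2 + sy ** 2) / (2 * rf.sigma_c ** 2)))
            ws = np.array(ws) / np.sum(ws)
            drives[name] = float(np.dot(ws, outs))
        assert abs(r.exc_drive - drives["exc"]) < 1e-10
        assert abs(r.inh_drive - drives["inh"]) < 1e-10
        spike = max(0.0, cfg.exc_weight * drives["exc"] - cfg.inh_weight * drives["inh"])
        assert abs(r.spike_proxy - spike) < 1e-10


class TestSimpleModel:
    def test_uniform_patch_linear_on_gives_mean_contrast(self, rf):
        shape = aperture_mask(rf, 3.0).shape
        patch = np.full(shape, B * 1.2)
        r = run_simple_model(patch, "on", "linear", rf)
        assert r == pytest.approx(0.2, rel=1e-9)

    def test_zero_mean_grating_linear_zero_nonlinear_positive(self, rf):
        m = make_grating("contrast_reversing", 0.5, 3.75, rf.aperture_radius, rf,
                         duration=0.5)
        peak = m.frames[:, :, 4]
        lin = run_simple_model(peak, "on", "linear", rf)
        nl = run_simple_model(peak, "on", "nonlinear", rf)
        assert abs(lin) < 1e-6
        assert nl > 0.01

    def test_off_model_equals_on_model_on_negated_patch(self, rf, bright_patches):
        patch = bright_patches[0]
        negated = 2 * B - patch
        for integ in ("linear", "nonlinear"):
            assert run_simple_model(patch, "off", integ, rf) == pytest.approx(
                run_simple_model(negated, "on", integ, rf), rel=1e-9, abs=1e-12)

    def test_linear_integration_cannot_distinguish_patch_from_disc(self, rf, bright_patches):
        """Ties the model to the linear-equivalent-disc invariant (1e-10)."""
        for patch in bright_patches[:5]:
            disc = linear_equivalent_disc(patch, rf)
            rp = run_simple_model(patch, "on", "linear", rf)
            rd = run_simple_model(disc, "on", "linear", rf)
            assert abs(rp - rd) < 1e-10


class TestEIModelInvariants:
    def test_spike_proxy_invariant(self, grating_ei_runs):
        for r in grating_ei_runs.values():
            cfg = SubunitModelConfig()
            expected = np.maximum(0.0, cfg.exc_weight * r.exc_drive
                                  - cfg.inh_weight * r.inh_drive)
            assert np.allclose(r.spike_proxy, expected)

    def test_grating_f2_present_across_contrasts(self, rf):
        """Rectified subunits frequency-double the excitatory drive."""
        from parasolsim.metrics import fourier_components

        cfg = SubunitModelConfig(cone_front_end="adapting")
        for c in (0.1, 1.0):
            m = make_grating("contrast_reversing", c, 4.0, rf.aperture_radius, rf,
                             duration=1.0)
            r = subunits.run_ei_model(m, cfg, rf)
            fc = fourier_components(r.exc_drive, 4.0, r.dt, window=(0.25, 1.0))
            assert fc["F2_amp"] > 3.0 * fc["F1_amp"]
            assert fc["F2_amp"] > 1e-4
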