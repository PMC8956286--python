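"""Cone cascade: fixed points, adaptation signatures, linearized control."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from parasolsim import cones
from parasolsim.cones import ConeParams, DEFAULT_CONE_PARAMS

B = 4000.0
DT = 1e-4


def test_dark_fixed_point_matches_algebra():
    """At S=0 the fixed point solves R=0, P=eta/phi and the cGMP/Ca balance."""
    p = DEFAULT_CONE_PARAMS
    ss = cones.steady_state(p, 0.0)
    assert ss.R == 0.0
    assert ss.P == pytest.approx(p.eta / p.phi, rel=1e-12)
    syn = p.s_max / (1.0 + (ss.C / p.k_gc) ** p.h_gc)
    assert syn == pytest.approx(ss.P * ss.G, rel=1e-9)
    assert ss.C == pytest.approx(p.q_ca * ss.I / p.beta, rel=1e-9)
    # default calibration: dark cGMP 20, dark current 80
    assert ss.G == pytest.approx(20.0, rel=1e-6)
    assert ss.I == pytest.approx(80.0, rel=1e-6)


def test_fixed_point_persistence_under_constant_input():
    """Simulating from steady state at constant background stays constant (0.1%)."""
    n = int(1.0 / DT)
    r = cones.simulate_adapting_cone(np.full(n, B), dt=DT, stim_dt=DT)
    ss = cones.steady_state(DEFAULT_CONE_PARAMS, B)
    assert np.max(np.abs(r)) < 1e-3 * ss.I


def test_root_solve_matches_ode_integrator_long_time():
    """Independent oracle: scipy's ODE integrator converges to the root-solve fixed point."""
    p = DEFAULT_CONE_PARAMS

    def rhs(t, y):
        R, P, G, C = y
        syn = p.s_max / (1.0 + (C / p.k_gc) ** p.h_gc)
        return [p.gamma * B - p.sigma * R, R + p.eta - p.phi * P,
                syn - P * G, p.q_ca * p.k_cur * G ** p.n_cur - p.beta * C]

    sol = solve_ivp(rhs, (0.0, 5.0), [0.0, p.eta / p.phi, 20.0, 1.0], rtol=1e-10, atol=1e-12)
    G_end = sol.y[2, -1]
    ss = cones.steady_state(p, B)
    assert G_end == pytest.approx(ss.G, rel=1e-3)


def test_small_signal_linearity_flash_ratio():
    """1% vs 2% flashes produce peak responses in ratio 2.00 within 5%."""

    def flash(c):
        n = int(0.4 / DT)
        s = np.full(n, B)
        s[: int(0.01 / DT)] = B * (1.0 + c)
        return cones.simulate_adapting_cone(s, dt=DT, stim_dt=DT, background=B)

    ratio = flash(0.02).max() / flash(0.01).max()
    assert ratio == pytest.approx(2.0, rel=0.05)


@pytest.fixture(scope="module")
def sinusoid_response():
    t = np.arange(0, 2.0, DT)
    stim = B * (1.0 + 0.75 * np.sin(2 * np.pi * 5.0 * t))
    return cones.simulate_adapting_cone(stim, dt=DT, stim_dt=DT)


def test_first_half_cycle_smaller_than_steady(sinusoid_response):
    """Adaptation makes the first increment response smaller than later ones."""
    r = sinusoid_response
    n_half = int(0.1 / DT)
    first = r[:n_half].max()
    steady = r[8 * n_half:10 * n_half].max()
    assert first < steady


def test_decrement_exceeds_increment_excursion(sinusoid_response):
    """Responses to the dark phase are larger than to the bright phase."""
    r = sinusoid_response
    steady = r[int(1.0 / DT):]
    assert -steady.min() > steady.max()


def test_dark_to_light_kinetics_faster_than_light_to_dark():
    """Cones stepped dark->light reach peak sooner than light->dark cones."""
    c, n, i0 = 0.5, int(0.7 / DT), int(0.3 / DT)
    s_up = np.full(n, B * (1 - c)); s_up[i0:] = B * (1 + c)
    s_dn = np.full(n, B * (1 + c)); s_dn[i0:] = B * (1 - c)
    r_up = cones.simulate_adapting_cone(s_up, dt=DT, stim_dt=DT, background=B * (1 - c))
    r_dn = cones.simulate_adapting_cone(s_dn, dt=DT, stim_dt=DT, background=B * (1 + c))
    assert np.argmax(r_up[i0:]) < np.argmin(r_dn[i0:])


def test_probe_gain_declines_after_light_step():
    """Instantaneous gain declines after a +100% step, most of it within 300 ms."""

    def probe_gain(t_probe):
        n = int(1.0 / DT)
        s = np.full(n, B); s[int(0.4 / DT):] = 2 * B
        base = cones.simulate_adapting_cone(s, dt=DT, stim_dt=DT, background=B)
        ip = int((0.4 + t_probe) / DT)
        s2 = s.copy(); s2[ip:ip + int(0.01 / DT)] *= 1.01
        rp = cones.simulate_adapting_cone(s2, dt=DT, stim_dt=DT, background=B)
        return np.max(np.abs((rp - base)[ip:ip + int(0.08 / DT)]))

    g10, g100, g300 = probe_gain(0.010), probe_gain(0.100), probe_gain(0.300)
    assert g300 < g100 < g10
    # time constant < 100 ms: by 100 ms the gain has decayed most of the way
    assert (g10 - g100) > 0.6 * (g10 - g300)


def test_steady_current_monotone_in_background():
    currents = [cones.steady_state(DEFAULT_CONE_PARAMS, s).I
                for s in (0, 1000, 4000, 16000, 64000)]
    assert all(a >= b for a, b in zip(currents, currents[1:]))


def test_input_validation():
    with pytest.raises(ValueError):
        cones.simulate_adapting_cone(np.array([-1.0, 0.0]), dt=DT, stim_dt=DT)
    with pytest.raises(ValueError):
        cones.simulate_adapting_cone(np.full(10, B), dt=1e-3, stim_dt=1e-3)
    with pytest.raises(ValueError):
        ConeParams(gamma=-1.0)
    with pytest.raises(ValueError):
        ConeParams(n_cur=0.5)


class TestLinearCone:
    def test_kernel_decays(self, cone_filter):
        k = cone_filter.kernel
        assert abs(k[-1]) < 0.01 * np.max(np.abs(k))

    def test_flash_reconstruction_within_2pct(self, cone_filter):
        """Convolving the kernel with the derivation flash reproduces the full model."""
        dtk = cone_filter.dt
        c, dur = 0.01, 0.002
        n = int(0.6 / dtk)
        stim = np.full(n, B)
        stim[: int(dur / dtk)] = B * (1 + c)
        full = cones.simulate_adapting_cone(stim, dt=dtk, stim_dt=dtk, background=B)
        lin = cones.simulate_linear_cone(stim, cone_filter)
        assert np.max(np.abs(full - lin)) < 0.02 * np.max(np.abs(full))

    def test_zero_contrast_gives_zero_output(self, cone_filter):
        out = cones.simulate_linear_cone(np.full(2000, B), cone_filter, dt=1e-3)
        assert np.allclose(out, 0.0)

    def test_amplitude_scales_linearly_with_contrast(self, cone_filter):
        t = np.arange(0, 1.0, 1e-3)
        r1 = cones.simulate_linear_cone(0.1 * np.sin(2 * np.pi * 4 * t), cone_filter,
                                        dt=1e-3, stim_is_contrast=True)
        r3 = cones.simulate_linear_cone(0.3 * np.sin(2 * np.pi * 4 * t), cone_filter,
                                        dt=1e-3, stim_is_contrast=True)
        assert np.allclose(r3, 3.0 * r1, atol=1e-12)

    def test_sinusoid_harmonic_distortion_below_1e4(self, cone_filter):
        from parasolsim.metrics import harmonic_distortion

        dt = 1e-3
        t = np.arange(0, 2.0, dt)
        out = cones.simulate_linear_cone(0.5 * np.sin(2 * np.pi * 4 * t), cone_filter,
                                         dt=dt, stim_is_contrast=True)
        assert harmonic_distortion(out, 4.0, dt, window=(0.5, 2.0)) < 1e-4

    def test_time_invariance_after_transient(self, cone_filter):
        """First-vs-later cycle amplitude ratio is 1 after one kernel length."""
        dt = 1e-3
        t = np.arange(0, 2.0, dt)
        out = cones.simulate_linear_cone(0.5 * np.sin(2 * np.pi * 4 * t), cone_filter,
                                         dt=dt, stim_is_contrast=True)
        n = int(0.25 / dt)
        k0 = int(np.ceil(cone_filter.duration / 0.25))
        a_first = np.abs(out[k0 * n:(k0 + 1) * n]).max()
        a_later = np.abs(out[(k0 + 2) * n:(k0 + 3) * n]).max()
        assert a_first == pytest.approx(a_later, rel=1e-6)

    def test_small_signal_equivalence_with_adapting_model(self, cone_filter):
        """At <=2% contrast the adapting and linear cones agree within 5% RMS."""
        t = np.arange(0, 1.5, DT)
        stim = B * (1 + 0.02 * np.sin(2 * np.pi * 4 * t))
        ra = cones.simulate_adapting_cone(stim, dt=DT, stim_dt=DT)
        rl = cones.simulate_linear_cone(stim, cone_filter, dt=DT)
        n0 = len(cone_filter.kernel)
        err = np.sqrt(np.mean((ra[n0:] - rl[n0:]) ** 2) / np.mean(ra[n0:] ** 2))
        assert err < 0.05

    def test_nonlinear_flash_contrast_rejected(self):
        with pytest.raises(ValueError, match="smaller flash_contrast"):
            cones.derive_linear_cone(background=B, flash_contrast=5.0, dt=DT, t_max=0.6)
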