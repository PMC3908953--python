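"""Tone set-point, rate laws, variant masks and the derivative oracle."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import arterywall as aw
from arterywall import (
    Inputs,
    VariantMask,
    VesselState,
    characteristic_times,
    equilibrium_tone,
    make_variant,
    state_derivative,
    tone_reducing_factor,
)


class TestToneSetpoint:
    def test_no_dilator_stimulus(self):
        assert tone_reducing_factor(0.0, 0.0) == 1.0

    def test_endothelial_dysfunction_blocks_dilation(self, params):
        p0 = params.replace(ecf=0.0)
        assert tone_reducing_factor(100.0, 50.0, p0) == 1.0

    def test_half_maximal_dilation(self, params):
        assert tone_reducing_factor(params.tau_50, 0.0) == pytest.approx(0.5)
        assert tone_reducing_factor(0.0, params.tau_50) == pytest.approx(0.5)

    def test_equilibrium_tone_limits(self, params):
        assert equilibrium_tone(0.0, 0.0, 1.0) == 0.0
        assert equilibrium_tone(params.sigma_50, 0.0, 1.0) == pytest.approx(0.5)
        # product of the two half-max Hill values
        trf = tone_reducing_factor(params.tau_50, 0.0)
        assert equilibrium_tone(params.sigma_50, 0.0, trf) == pytest.approx(0.25)

    @given(
        tau=st.floats(0.0, 50.0),
        dtau=st.floats(0.0, 10.0),
        sigma=st.floats(0.0, 2e5),
        dsig=st.floats(0.0, 5e4),
    )
    def test_bounded_and_monotone(self, tau, dtau, sigma, dsig):
        trf1 = tone_reducing_factor(tau, 0.0)
        trf2 = tone_reducing_factor(tau + dtau, 0.0)
        assert 0.0 <= trf2 <= trf1 <= 1.0
        a1 = equilibrium_tone(sigma, 0.0, trf1)
        a2 = equilibrium_tone(sigma + dsig, 0.0, trf1)
        assert 0.0 <= a1 <= a2 <= 1.0

    def test_constrictor_equipotent_to_wall_stress(self, params):
        assert equilibrium_tone(1e4, 2e4, 1.0) == pytest.approx(
            equilibrium_tone(3e4, 0.0, 1.0)
        )


class TestVariants:
    @pytest.mark.parametrize(
        "name, flags",
        [
            ("MECH", (True, False, False, False, False)),
            ("FUNCT", (True, True, False, False, False)),
            ("PLAST", (True, True, True, False, False)),
            ("REMOD", (True, True, True, True, False)),
            ("GROWTH", (True, True, True, True, True)),
            ("FUNCTKO", (True, False, True, True, True)),
            ("PLASTKO", (True, True, False, True, True)),
            ("REMODKO", (True, True, True, False, True)),
        ],
    )
    def test_mask_hierarchy(self, name, flags):
        m = make_variant(name)
        assert (m.mech, m.tone, m.plasticity, m.remodeling, m.growth) == flags

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="unknown variant"):
            make_variant("NOPE")

    def test_mechanics_always_on(self):
        assert all(make_variant(n).mech for n in aw.VARIANT_NAMES)


class TestRateLaws:
    def test_all_rates_vanish_at_fixed_point(self, analytic_fp):
        f = state_derivative(0.0, analytic_fp.as_array(), aw.DEFAULT_INPUTS)
        assert np.max(np.abs(f / aw.ABS_TOLERANCES)) < 1e-9

    def test_strain_drives_outward_remodeling(self):
        # distended, fully relaxed wall: slack radius must grow
        y = VesselState(eps=0.3, tone=0.0, span=0.16, r_mslack=65e-6,
                        wcsa=1.2e-8).as_array()
        f = state_derivative(0.0, y, aw.DEFAULT_INPUTS)
        assert f[3] > 0.0

    def test_tone_drives_inward_remodeling(self):
        y = VesselState(eps=0.0, tone=0.9, span=0.16, r_mslack=65e-6,
                        wcsa=1.2e-8).as_array()
        f = state_derivative(0.0, y, aw.DEFAULT_INPUTS)
        assert f[3] < 0.0

    def test_high_wall_stress_drives_growth(self, analytic_fp):
        # raise pressure: sigma_eq > sigma has no immediate growth effect,
        # but high sigma itself (here via strong distension) does
        y = analytic_fp.as_array().copy()
        y[0] *= 2.0  # strain up -> sigma above sigma_ref
        f = state_derivative(0.0, y, aw.DEFAULT_INPUTS)
        assert f[4] > 0.0

    def test_plasticity_restores_reference_length(self, params):
        short = VesselState(eps=0.1, tone=0.3, span=0.10, r_mslack=65e-6,
                            wcsa=1.2e-8)  # l < l_ref
        long = VesselState(eps=0.1, tone=0.3, span=0.30, r_mslack=65e-6,
                           wcsa=1.2e-8)  # l > l_ref
        assert state_derivative(0.0, short.as_array(), aw.DEFAULT_INPUTS)[2] > 0
        assert state_derivative(0.0, long.as_array(), aw.DEFAULT_INPUTS)[2] < 0

    @given(
        eps=st.floats(0.0, 1.0),
        tone=st.floats(0.0, 1.0),
        span=st.floats(0.08, 0.4),
        flags=st.tuples(*(st.booleans() for _ in range(4))),
    )
    def test_mask_zeroes_disabled_processes(self, eps, tone, span, flags):
        """A disabled process contributes exactly zero rate."""
        mask = VariantMask(True, *flags)
        y = VesselState(eps, tone, span, 65e-6, 1.2e-8).as_array()
        f = state_derivative(0.0, y, aw.DEFAULT_INPUTS, aw.DEFAULT_PARAMETERS, mask)
        for i, on in enumerate(mask.as_array()):
            if not on:
                assert f[i] == 0.0

    def test_timescale_ordering(self, analytic_fp):
        """Relaxation times order mechanics < tone < plasticity <
        remodeling < growth — the separation that makes the system stiff."""
        ct = characteristic_times(analytic_fp)
        order = ["mechanics", "tone", "plasticity", "remodeling", "growth"]
        times = [ct[k] for k in order]
        assert times == sorted(times)
        assert ct["growth"] / ct["mechanics"] > 1e3


class TestDerivativeOracle:
    def test_matches_independent_symbolic_model(self, params):
        """Full derivative agrees with an independently transcribed sympy
        model on 100 random states, to near machine precision."""
        sympy = pytest.importorskip("sympy")
        eps, A, sp, rms, w = sympy.symbols("eps A sp rms w", real=True)
        P, Q, CON, DIL = sympy.symbols("P Q CON DIL", nonnegative=True)
        p = params

        r_m = rms * (1 + eps)
        h = w / (2 * sympy.pi * r_m)
        r_i = r_m - h / 2
        l = sp * 2 * sympy.pi * r_m
        s_p = p.c_p1 * (sympy.exp(p.c_p3 * eps) - 1) + p.c_p2 * (
            sympy.exp(p.c_p4 * eps) - 1
        )
        s_cap = p.sigma_amax * sympy.exp(-(((l - p.l_opt) / p.l_w) ** 2))
        s_c = p.c_c1 * (l / p.c_c3) ** p.c_c2
        sigma = (p.af_p * s_p + p.af_a * A * s_cap + p.af_c * s_c)
        sigma_eq = P * r_i / h
        tau = 4 * p.eta * Q / (sympy.pi * r_i**3)
        stim_d = tau + DIL
        trf = 1 - p.ecf * stim_d**p.hd / (p.tau_50**p.hd + stim_d**p.hd)
        stim_c = sigma + CON
        a_eq = stim_c**p.hc / (p.sigma_50**p.hc + stim_c**p.hc) * trf
        rates = sympy.Matrix(
            [
                p.k_mech * (sigma_eq - sigma),
                p.k_tone * (a_eq - A),
                p.k_span * (p.l_ref - l) * l / p.l_ref,
                p.k_slack * rms * (p.beta_strain * eps - p.alpha_tone * A),
                p.k_growth * w * (sigma - p.sigma_ref),
            ]
        )
        oracle = sympy.lambdify((eps, A, sp, rms, w, P, Q, CON, DIL), rates, "numpy")

        rng = np.random.default_rng(42)
        for _ in range(100):
            y = rng.uniform(
                [0.01, 0.0, 0.05, 30e-6, 0.3e-8], [1.0, 1.0, 0.5, 120e-6, 3e-8]
            )
            inp = Inputs(*rng.uniform([2e3, 0.05e-9, 0, 0], [25e3, 1e-9, 2e4, 3]))
            got = state_derivative(0.0, y, inp)
            want = np.asarray(oracle(*y, inp.P, inp.Q, inp.CON, inp.DIL)).ravel()
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-30)

    def test_nonfinite_signalled(self):
        y = np.array([0.5, 0.3, math.nan, 65e-6, 1.2e-8])
        with pytest.raises((FloatingPointError, ValueError)):
            state_derivative(0.0, y, aw.DEFAULT_INPUTS)
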