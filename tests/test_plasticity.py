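"""Unit and property tests for the three-factor plasticity framework."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stdebg.plasticity import (
    DEFAULT_SIGN_MASK,
    EligibilityState,
    KernelCoefficients,
    MixingParams,
    SpikePair,
    TimingParams,
    blended_amplitude,
    default_coefficients,
    default_mixing,
    eligibility_apply_pair,
    kernel_value,
    mixing_value,
    stde_integrate,
    stdp_weight_change,
)

TIMING = TimingParams()
MIX = default_mixing()
COEFFS = default_coefficients()


class TestKernel:
    @pytest.mark.parametrize(
        "dt, tau, amp, expected",
        [
            (0.001, 0.02, 1.0, math.exp(-0.05)),       # near-zero-lag limit
            (0.02, 0.02, 1.0, math.exp(-1.0)),          # one time constant
            (-0.04, 0.02, -0.5, -0.5 * math.exp(-2.0)),  # negative side, LTD amp
        ],
    )
    def test_closed_form(self, dt, tau, amp, expected):
        assert kernel_value(dt, tau, amp) == pytest.approx(expected, rel=1e-12)

    def test_rejects_coincident_pair(self):
        with pytest.raises(ValueError):
            kernel_value(0.0, 0.02, 1.0)
        with pytest.raises(ValueError):
            SpikePair(0.0)

    def test_rejects_bad_tau(self):
        with pytest.raises(ValueError):
            kernel_value(0.01, -0.02, 1.0)

    @given(
        dt1=st.floats(0.0005, 0.1),
        dt2=st.floats(0.0005, 0.1),
    )
    @settings(max_examples=50, derandomize=True)
    def test_magnitude_decreasing_in_lag(self, dt1, dt2):
        lo, hi = sorted((dt1, dt2))
        if lo == hi:
            return
        assert abs(kernel_value(hi, 0.02, 1.0)) < abs(kernel_value(lo, 0.02, 1.0))


class TestMixing:
    def test_zero_dopamine(self):
        assert mixing_value(0.0, MIX["D1"]) == 0.0

    def test_half_saturation_at_threshold(self):
        # m(theta) = M/2 for any exponent
        assert mixing_value(6.0, MIX["D1"]) == pytest.approx(0.6, rel=1e-12)
        assert mixing_value(1.8, MIX["D2"]) == pytest.approx(0.5, rel=1e-12)

    def test_saturation_limit(self):
        assert mixing_value(1e6, MIX["D1"]) == pytest.approx(1.2, rel=1e-4)

    def test_monotone_on_dense_grid(self):
        d = np.linspace(0.0, 12.0, 1201)
        for p in MIX.values():
            m = mixing_value(d, p)
            assert np.all(np.diff(m) >= 0)
            assert m[0] == 0.0

    def test_rejects_negative_dopamine(self):
        with pytest.raises(ValueError):
            mixing_value(-0.1, MIX["D1"])

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            MixingParams(n=-1.0)


class TestBlendedAmplitude:
    def test_endpoints(self):
        co = COEFFS
        # m(0) = 0 -> A_lo exactly
        for t in ("D1", "D2"):
            for s in ("pos", "neg"):
                assert blended_amplitude(t, s, 0.0, co, MIX) == pytest.approx(
                    co.amplitude(t, "lo", s)
                )

    def test_symmetric_cancellation(self):
        a = {}
        for t in ("D1", "D2"):
            a[(t, "hi", "pos")] = 1.0
            a[(t, "lo", "pos")] = -1.0
            a[(t, "hi", "neg")] = 0.0
            a[(t, "lo", "neg")] = 0.0
        co = KernelCoefficients(a=a)
        # m(theta) = M/2 = 0.5 for D2 -> perfect cancellation
        assert blended_amplitude("D2", "pos", 1.8, co, MIX) == pytest.approx(0.0, abs=1e-12)

    def test_continuity(self):
        d = np.linspace(0.0, 12.0, 4001)
        p = blended_amplitude("D1", "pos", d, COEFFS, MIX)
        # Lipschitz on a bounded interval: increments vanish with step size
        assert np.max(np.abs(np.diff(p))) < 1e-2

    def test_saturating_blend_can_extrapolate(self):
        # D1 mixing maximum is 1.2, so the blend passes beyond A_hi
        co = COEFFS
        p_inf = blended_amplitude("D1", "pos", 1e6, co, MIX)
        a_hi = co.amplitude("D1", "hi", "pos")
        a_lo = co.amplitude("D1", "lo", "pos")
        assert p_inf == pytest.approx(1.2 * a_hi - 0.2 * a_lo, rel=1e-3)


class TestStdp:
    def test_zero_learning_rate(self):
        t0 = TimingParams(alpha=0.0)
        assert stdp_weight_change(SpikePair(0.01), 3.0, "D1", COEFFS, MIX, t0) == 0.0

    @pytest.mark.parametrize("dt", [0.005, 0.02, -0.01, -0.05])
    @pytest.mark.parametrize("msn_type", ["D1", "D2"])
    def test_sign_follows_plasticity_factor(self, dt, msn_type):
        pair = SpikePair(dt)
        p = blended_amplitude(msn_type, pair.sign, 3.0, COEFFS, MIX)
        dw = stdp_weight_change(pair, 3.0, msn_type, COEFFS, MIX, TIMING)
        assert math.copysign(1, dw) == math.copysign(1, p)


class TestEligibility:
    def test_near_zero_lag_unit_step(self):
        st0 = EligibilityState()
        st1 = eligibility_apply_pair(st0, SpikePair(0.001), TIMING)
        assert st1.c_pos == pytest.approx(1.0, abs=0.05)
        assert st1.c_neg == 0.0

    def test_free_decay_one_constant(self):
        st0 = EligibilityState(c_pos=0.8, last_update=0.0)
        st1 = st0.decayed_to(TIMING.tau_e, TIMING)
        assert st1.c_pos == pytest.approx(0.8 * math.exp(-1.0), rel=1e-12)

    def test_linear_superposition(self):
        st0 = EligibilityState()
        one = eligibility_apply_pair(st0, SpikePair(0.01), TIMING)
        two = eligibility_apply_pair(one, SpikePair(0.01), TIMING)
        assert two.c_pos == pytest.approx(2 * one.c_pos, rel=1e-12)

    def test_no_backwards_decay(self):
        with pytest.raises(ValueError):
            EligibilityState(last_update=1.0).decayed_to(0.5, TIMING)

    def test_k_pairs_scale_weight_change_k_fold(self):
        # linearity carries through the integral at constant dopamine
        d_fn = lambda t: np.full_like(np.asarray(t, dtype=float), 3.0)
        st1 = eligibility_apply_pair(EligibilityState(), SpikePair(0.01), TIMING)
        dw1 = stde_integrate(st1, d_fn, (0.0, 3.0), "D1", COEFFS, MIX, TIMING)
        stk = EligibilityState(c_pos=st1.c_pos * 5, last_update=0.0)
        dwk = stde_integrate(stk, d_fn, (0.0, 3.0), "D1", COEFFS, MIX, TIMING)
        assert dwk == pytest.approx(5 * dw1, rel=1e-9)


class TestStdeIntegration:
    def test_zero_traces(self):
        d_fn = lambda t: np.full_like(np.asarray(t, dtype=float), 3.0)
        assert stde_integrate(EligibilityState(), d_fn, (0, 1), "D1", COEFFS, MIX, TIMING) == 0.0

    @pytest.mark.parametrize("msn_type", ["D1", "D2"])
    @pytest.mark.parametrize("dopamine", [0.0, 1.5, 3.0, 6.0])
    @pytest.mark.parametrize("dt", [0.004, 0.02, -0.01, -0.06])
    def test_reduces_to_stdp_at_constant_dopamine(self, msn_type, dopamine, dt):
        """The STDE integral over an infinite window equals the STDP change."""
        pair = SpikePair(dt)
        state = eligibility_apply_pair(EligibilityState(), pair, TIMING)
        d_fn = lambda t: np.full_like(np.asarray(t, dtype=float), dopamine)
        dw = stde_integrate(
            state, d_fn, (0.0, 30 * TIMING.tau_e), msn_type, COEFFS, MIX, TIMING,
            step=TIMING.tau_plus / 20,
        )
        ref = stdp_weight_change(pair, dopamine, msn_type, COEFFS, MIX, TIMING)
        assert dw == pytest.approx(ref, rel=1e-6)

    def test_delayed_pulse_attenuated_by_trace_decay(self):
        """A dopamine pulse delayed by d acts on a trace decayed by e^{-d/tau_e}.

        Closed form: with zero plasticity factor outside the pulse, the
        weight change is proportional to the integral of the decaying trace
        over the pulse window, which scales exactly as exp(-d/tau_e).
        """
        a = {(t, d, s): 0.0 for t in ("D1", "D2") for d in ("hi", "lo") for s in ("pos", "neg")}
        a[("D1", "hi", "pos")] = 1.0  # P+ = m(D): zero at D = 0, positive in a burst
        co = KernelCoefficients(a=a)
        width = 0.05
        state = eligibility_apply_pair(EligibilityState(), SpikePair(0.01), TIMING)

        def pulse(delay):
            def d_fn(t):
                t = np.asarray(t, dtype=float)
                return np.where((t >= delay) & (t < delay + width), 6.0, 0.0)
            return d_fn

        dws = []
        for delay in (0.0, 0.15):
            dws.append(
                stde_integrate(
                    state, pulse(delay), (0.0, 2.0), "D1", co, MIX, TIMING, step=1e-3
                )
            )
        assert dws[1] / dws[0] == pytest.approx(math.exp(-0.15 / TIMING.tau_e), rel=1e-9)


class TestKernelCoefficients:
    def test_flat_round_trip(self):
        flat = COEFFS.to_flat()
        assert set(flat) == {
            f"A.{t}.{d}.{s}"
            for t in ("D1", "D2")
            for d in ("hi", "lo")
            for s in ("pos", "neg")
        }
        co2 = KernelCoefficients.from_flat(flat)
        assert co2.a == COEFFS.a

    def test_missing_amplitude_rejected(self):
        with pytest.raises(ValueError):
            KernelCoefficients(a={("D1", "hi", "pos"): 1.0})

    def test_sign_mask_enforced(self):
        bad = dict(COEFFS.a)
        bad[("D1", "lo", "pos")] = +0.5  # constrained to LTD
        with pytest.raises(ValueError):
            KernelCoefficients(a=bad, sign_mask=DEFAULT_SIGN_MASK)

    def test_default_set_satisfies_mask(self):
        assert COEFFS.satisfies_mask()

    def test_standard_stdp_at_tonic(self):
        """At tonic dopamine both types express standard STDP (LTP+, LTD-)."""
        for t in ("D1", "D2"):
            assert blended_amplitude(t, "pos", 3.0, COEFFS, MIX) > 0
            assert blended_amplitude(t, "neg", 3.0, COEFFS, MIX) < 0

    def test_timing_params_validation(self):
        with pytest.raises(ValueError):
            TimingParams(tau_e=0.01)  # must exceed the kernel constants
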