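"""Tests of the spiking MSN model and its dopaminergic modulation."""

import math

import numpy as np
import pytest

from stdebg.msn import (
    DopamineModulation,
    DopamineOccupancy,
    MembraneState,
    MSNParams,
    SynapseBank,
    SynapseParams,
    apply_dopamine,
    gen_poisson_inputs,
    holding_current,
    init_conductances,
    mg_block,
    phi_of_dopamine,
    step_membrane,
    synaptic_current,
)
from stdebg.simulate import MSNSimulation

PARAMS = MSNParams()
SYN = SynapseParams()


class TestMembrane:
    def test_rest_is_fixed_point(self):
        st, spiked = step_membrane(MembraneState(v=PARAMS.vr, u=0.0), 0.0, PARAMS)
        assert not spiked
        assert st.v == pytest.approx(PARAMS.vr)
        assert st.u == pytest.approx(0.0)

    def test_reset_contract(self):
        st, spiked = step_membrane(MembraneState(v=PARAMS.vpeak, u=5.0), 1e4, PARAMS)
        assert spiked
        assert st.v == PARAMS.vreset
        assert st.u > 5.0

    def test_rate_increases_with_current(self):
        """Suprathreshold step currents: firing rate monotone in I.

        Cross-checked against a fine-step (dt = 0.001 ms) integration of the
        same ODE: rates agree within 10% (forward Euler at 0.1 ms slightly
        advances threshold crossings).
        """
        def rate(i_inj, dt):
            st = MembraneState(v=PARAMS.vr, u=0.0)
            n = int(2000.0 / dt)  # 2 s
            count = 0
            for _ in range(n):
                st, spiked = step_membrane(st, i_inj, PARAMS, dt=dt)
                count += spiked
            return count / 2.0

        rates = [rate(i, 0.1) for i in (300.0, 500.0, 800.0)]
        assert rates[0] > 0
        assert rates[0] < rates[1] < rates[2]
        fine = rate(500.0, 0.001)
        assert rates[1] == pytest.approx(fine, rel=0.10)

    def test_nonfinite_state_aborts(self):
        with pytest.raises(FloatingPointError):
            step_membrane(MembraneState(v=math.nan, u=0.0), 0.0, PARAMS)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            MSNParams(vr=-20.0, vt=-30.0)


class TestMgBlock:
    def test_limits(self):
        assert mg_block(200.0) > 0.99
        assert mg_block(-300.0) < 0.01

    def test_matches_formula_mid_range(self):
        for v in (-80.0, -60.0, -40.0, -20.0):
            expected = 1.0 / (1.0 + (1.0 / 3.57) * math.exp(-0.062 * v))
            assert mg_block(v, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone(self):
        v = np.linspace(-120, 60, 500)
        assert np.all(np.diff(mg_block(v)) > 0)


class TestSynapticCurrent:
    def test_zero_activation_zero_current(self):
        bank = SynapseBank.init(SYN, np.random.default_rng(0))
        assert synaptic_current(bank, -70.0, SYN) == 0.0

    def test_gaba_reversal(self):
        bank = SynapseBank.init(SYN, np.random.default_rng(0))
        bank.z_gaba[:] = 1.0
        assert synaptic_current(bank, SYN.e_gaba, SYN) == pytest.approx(0.0)

    def test_single_ampa_transient_decays_with_tau(self):
        """One spike at one synapse: engine current transient has tau = 6 ms."""
        sim = MSNSimulation(msn_type="D2", rng=np.random.default_rng(0))
        sim.bank.g_nmda[:] = 0.0
        i_hold = holding_current(-70.0, sim.params)
        sim.v, sim.u = -70.0, sim.params.b * (-70.0 - sim.params.vr)
        res = sim.run_segment(
            0.3,
            [np.array([0.05])] + [np.array([])] * (sim.syn.n_exc - 1),
            [np.array([])] * sim.syn.n_gaba,
            0.0,
            plastic=False,
            i_inject=i_hold,
            record_v=True,
        )
        v = res.v_trace
        peak = np.argmax(v)
        assert v[peak] > -70.0 + 0.5  # a visible EPSP
        # well after the EPSP the membrane has returned near holding
        assert abs(v[-1] + 70.0) < 0.2


class TestDopamineModulation:
    def test_zero_occupancy_is_identity(self):
        for t in ("D1", "D2"):
            eff = apply_dopamine(DopamineOccupancy(), t, PARAMS)
            assert eff.vr == PARAMS.vr
            assert eff.k == PARAMS.k
            assert eff.d == PARAMS.d
            assert eff.ampa_scale == 1.0
            assert eff.nmda_scale == 1.0

    def test_d2_attenuates_ampa(self):
        eff = apply_dopamine(DopamineOccupancy(phi2=1.0), "D2", PARAMS)
        assert eff.ampa_scale < 1.0
        assert eff.nmda_scale == 1.0

    def test_d1_enhances_nmda_and_kir(self):
        eff = apply_dopamine(DopamineOccupancy(phi1=1.0), "D1", PARAMS)
        assert eff.nmda_scale > 1.0
        assert eff.vr < PARAMS.vr          # KIR: hyperpolarised rest
        assert eff.d < PARAMS.d            # L-type Ca: lowered recovery increment

    def test_occupancy_saturates_at_phasic_levels(self):
        mod = DopamineModulation()
        assert phi_of_dopamine(0.0, mod) == 0.0
        assert 0.9 < phi_of_dopamine(3.0, mod) < 1.0
        assert phi_of_dopamine(6.0, mod) > phi_of_dopamine(3.0, mod)

    def test_occupancy_bounds_validated(self):
        with pytest.raises(ValueError):
            DopamineOccupancy(phi1=1.5)


class TestPoissonInputs:
    def test_expected_count(self):
        rng = np.random.default_rng(0)
        trains = gen_poisson_inputs(500, 25.0, 0.4, rng)
        counts = [len(t) for t in trains]
        assert np.mean(counts) == pytest.approx(10.0, abs=3 * math.sqrt(10 / 500))

    def test_zero_rate_empty(self):
        trains = gen_poisson_inputs(3, 0.0, 10.0, np.random.default_rng(0))
        assert all(len(t) == 0 for t in trains)

    def test_fano_factor_near_one(self):
        rng = np.random.default_rng(1)
        counts = np.array([len(t) for t in gen_poisson_inputs(10_000, 3.0, 1.0, rng)])
        fano = counts.var(ddof=1) / counts.mean()
        # var(F) ~ 2/(n-1) for Poisson counts
        assert abs(fano - 1.0) < 3 * math.sqrt(2 / 9999)

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            gen_poisson_inputs(2, -1.0, 1.0, np.random.default_rng(0))

    def test_reproducible_under_seed(self):
        t1 = gen_poisson_inputs(5, 10.0, 1.0, np.random.default_rng(42))
        t2 = gen_poisson_inputs(5, 10.0, 1.0, np.random.default_rng(42))
        for a, b in zip(t1, t2):
            assert np.array_equal(a, b)


class TestInitConductances:
    def test_sample_mean_matches_default(self):
        rng = np.random.default_rng(3)
        g = init_conductances(200, 0.458, 0.1, 2.0, rng)
        se = 0.1 * 0.458 / math.sqrt(200)
        assert g.mean() == pytest.approx(0.458, abs=3 * se)

    def test_zero_cv_all_equal(self):
        g = init_conductances(50, 0.458, 0.0, 2.0, np.random.default_rng(0))
        assert np.all(g == 0.458)

    def test_clipping_contract(self):
        g = init_conductances(10_000, 0.5, 2.0, 1.0, np.random.default_rng(0))
        assert g.min() >= 0.0
        assert g.max() <= 1.0


class TestStabilityInvariants:
    def test_quiescent_membrane_stays_at_rest(self):
        """Zero input for 10 s: v remains within 1 mV of rest."""
        sim = MSNSimulation(msn_type="D1", rng=np.random.default_rng(0))
        empty_exc = [np.array([])] * sim.syn.n_exc
        empty_gab = [np.array([])] * sim.syn.n_gaba
        res = sim.run_segment(10.0, empty_exc, empty_gab, 0.0, plastic=False, record_v=True)
        assert res.n_spikes == 0
        assert np.max(np.abs(res.v_trace - sim.params.vr)) < 1.0

    def test_conductances_bounded_through_learning(self):
        from stdebg.experiment import build_schedule, run_trial

        sched = build_schedule(seed=5)
        sim = MSNSimulation(msn_type="D1", rng=np.random.default_rng(5))
        rng = np.random.default_rng(6)
        # run through the epoch transitions that drive the largest changes
        for t in list(range(13, 22)) + list(range(83, 92)):
            run_trial(sim, sched, t, rng)
            assert sim.bank.g_ampa.min() >= 0.0
            assert sim.bank.g_ampa.max() <= sim.syn.g_ceiling

    def test_spike_count_converges_in_dt(self):
        """Halving dt changes the spike count of a fixed input by < 2%."""
        from stdebg.experiment import build_schedule, run_trial

        sched = build_schedule(seed=7)
        counts = {}
        for dt in (0.025, 0.0125):  # the default step and its half
            sim = MSNSimulation(msn_type="D1", dt_ms=dt, rng=np.random.default_rng(8))
            rng = np.random.default_rng(9)
            counts[dt] = sum(run_trial(sim, sched, t, rng, plastic=False) for t in range(6))
        assert abs(counts[0.025] - counts[0.0125]) <= 0.02 * counts[0.0125]
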