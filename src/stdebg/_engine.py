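"""Compiled single-neuron trial engine.

Simulates the dopamine-modulated MSN with conductance synapses and the STDE
plasticity rule over one stretch of time (a trial, or a protocol segment).

Performance design
------------------
* Synaptic drive: per receptor type the total weighted activation
  ``S = sum_i g_i z_i`` itself decays with the receptor time constant, so
  only three scalars are updated per step; a presynaptic spike at synapse i
  adds ``g_i`` to the relevant sum.
* Pairing: all-to-all pairing with exponential kernels is computed with
  per-synapse presynaptic traces ``x_i`` (decay tau+) and a shared
  postsynaptic trace ``y`` (decay tau-).  A postsynaptic spike deposits
  ``x_i`` into the positive eligibility trace ``c+_i`` of every synapse; a
  presynaptic spike at synapse i deposits ``y`` into ``c-_i``.  Exactly
  coincident pre/post events (same time step) contribute nothing.
* Weight integration: between eligibility events, ``c_i`` decays freely, so
  the STDE integral ``(alpha/tau_e) Int P(D(t)) c_i(t) dt`` factorises into
  the trace value at the last event times a synapse-independent running
  integral of ``P(D(t)) exp(-t/tau_e)``, accumulated with exact per-step
  exponential segments.  The run is processed in chunks with a reset time
  origin so the running integrals never suffer cancellation.

Plasticity factor arrays ``p_pos``/``p_neg`` (the dopamine-dependent STDP
amplitudes per step) are precomputed by the caller; weight changes are
accumulated into ``dw`` and applied by the caller (the within-trial change
is a fraction of a percent of the conductance, so applying it at segment
boundaries is indistinguishable from the continuous update).
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: engine error codes
OK = 0
NONFINITE = 1

_CHUNK = 10_000  # steps per renormalisation chunk (1 s at dt = 0.1 ms)


@njit(cache=True, fastmath=False)
def run_segment(  # noqa: PLR0913 - flat argument list for numba
    n_steps,
    dt_ms,
    # presynaptic spikes, sorted by step
    exc_step,
    exc_syn,
    gab_step,
    gab_syn,
    # conductances
    g_ampa,
    g_nmda,
    g_gaba,
    # per-step dopamine-modulated parameters
    vr_t,
    k_t,
    d_t,
    ampa_sc_t,
    nmda_sc_t,
    # intrinsic / synaptic constants
    C,
    vt,
    vpeak,
    vreset,
    a,
    b,
    tau_ampa_ms,
    tau_nmda_ms,
    tau_gaba_ms,
    mg,
    e_gaba,
    i_inject,
    # membrane state
    v0,
    u0,
    s_ampa0,
    s_nmda0,
    s_gaba0,
    # plasticity
    plast_on,
    alpha,
    tau_e_s,
    tau_p_s,
    tau_m_s,
    p_pos,
    p_neg,
    x_pre,
    c_pos,
    c_neg,
    dw,
    y_state,  # (y_val, y_last_step) length-2 float array, carried across calls
    # fictive postsynaptic spikes (sorted steps; pairing + reset, not counted)
    forced_step,
    # outputs
    spike_steps,
    v_trace,
    record_v,
):
    n_exc = g_ampa.shape[0]
    dt_s = dt_ms * 1e-3
    dec_a = np.exp(-dt_ms / tau_ampa_ms)
    dec_n = np.exp(-dt_ms / tau_nmda_ms)
    dec_g = np.exp(-dt_ms / tau_gaba_ms)
    mg_f = mg / 3.57

    v = v0
    u = u0
    s_ampa = s_ampa0
    s_nmda = s_nmda0
    s_gaba = s_gaba0
    y_val = y_state[0]
    y_last = y_state[1]  # absolute step of last y update

    pe = 0  # pointer into exc spikes
    pg = 0
    pf = 0
    n_spk = 0
    max_rec = spike_steps.shape[0]

    last = np.zeros(n_exc, dtype=np.int64)  # chunk-local step of last sync
    hp = np.empty(_CHUNK + 1)
    hn = np.empty(_CHUNK + 1)
    pre_buf = np.empty(n_exc * 4, dtype=np.int64)

    inv_tau_e = 1.0 / tau_e_s
    lr = alpha * inv_tau_e

    c0 = 0
    while c0 < n_steps:
        c1 = min(c0 + _CHUNK, n_steps)
        nloc = c1 - c0
        if plast_on:
            hp[0] = 0.0
            hn[0] = 0.0
            e0 = 1.0
            for s in range(nloc):
                e1 = np.exp(-(s + 1) * dt_s * inv_tau_e)
                seg = tau_e_s * (e0 - e1)
                hp[s + 1] = hp[s] + p_pos[c0 + s] * seg
                hn[s + 1] = hn[s] + p_neg[c0 + s] * seg
                e0 = e1

        for s_abs in range(c0, c1):
            s = s_abs - c0  # chunk-local
            # conductance decays
            s_ampa *= dec_a
            s_nmda *= dec_n
            s_gaba *= dec_g
            # GABA arrivals
            while pg < gab_step.shape[0] and gab_step[pg] == s_abs:
                s_gaba += g_gaba[gab_syn[pg]]
                pg += 1
            # excitatory arrivals: conductance now, plasticity after the
            # membrane update (so a same-step post spike pairs at dt=0
            # with nothing)
            n_buf = 0
            while pe < exc_step.shape[0] and exc_step[pe] == s_abs:
                i = exc_syn[pe]
                s_ampa += g_ampa[i]
                s_nmda += g_nmda[i]
                if n_buf < pre_buf.shape[0]:
                    pre_buf[n_buf] = i
                    n_buf += 1
                pe += 1
            # currents and membrane update
            bv = 1.0 / (1.0 + mg_f * np.exp(-0.062 * v))
            i_syn = (
                ampa_sc_t[s_abs] * s_ampa * (0.0 - v)
                + nmda_sc_t[s_abs] * s_nmda * bv * (0.0 - v)
                + s_gaba * (e_gaba - v)
                + i_inject
            )
            v = v + dt_ms / C * (k_t[s_abs] * (v - vr_t[s_abs]) * (v - vt) - u + i_syn)
            u = u + dt_ms * a * (b * (v - vr_t[s_abs]) - u)
            if not (np.isfinite(v) and np.isfinite(u)):
                y_state[0] = y_val
                y_state[1] = y_last
                return v, u, s_ampa, s_nmda, s_gaba, n_spk, NONFINITE

            spiked = v >= vpeak
            forced = False
            if pf < forced_step.shape[0] and forced_step[pf] == s_abs:
                forced = True
                pf += 1
            if spiked or forced:
                v = vreset
                u = u + d_t[s_abs]
                if spiked:
                    if n_spk < max_rec:
                        spike_steps[n_spk] = s_abs
                    n_spk += 1
                if plast_on:
                    # pair this post spike with all past presynaptic spikes
                    for i in range(n_exc):
                        ds = s - last[i]
                        if ds > 0:
                            t0 = last[i] * dt_s
                            w = np.exp(t0 * inv_tau_e)
                            dw[i] += lr * w * (
                                c_pos[i] * (hp[s] - hp[last[i]])
                                + c_neg[i] * (hn[s] - hn[last[i]])
                            )
                            f = np.exp(-ds * dt_s * inv_tau_e)
                            c_pos[i] *= f
                            c_neg[i] *= f
                            x_pre[i] *= np.exp(-ds * dt_s / tau_p_s)
                            last[i] = s
                        c_pos[i] += x_pre[i]
            if plast_on and n_buf > 0:
                # decayed post trace before any same-step increment
                y_now = y_val * np.exp(-(s_abs - y_last) * dt_s / tau_m_s)
                for j in range(n_buf):
                    i = pre_buf[j]
                    ds = s - last[i]
                    if ds > 0:
                        t0 = last[i] * dt_s
                        w = np.exp(t0 * inv_tau_e)
                        dw[i] += lr * w * (
                            c_pos[i] * (hp[s] - hp[last[i]])
                            + c_neg[i] * (hn[s] - hn[last[i]])
                        )
                        f = np.exp(-ds * dt_s * inv_tau_e)
                        c_pos[i] *= f
                        c_neg[i] *= f
                        x_pre[i] *= np.exp(-ds * dt_s / tau_p_s)
                        last[i] = s
                    c_neg[i] += y_now
                    x_pre[i] += 1.0
            if plast_on and (spiked or forced):
                y_val = y_val * np.exp(-(s_abs - y_last) * dt_s / tau_m_s) + 1.0
                y_last = s_abs
            if record_v:
                v_trace[s_abs] = v

        # chunk boundary: bring every synapse to the boundary time
        if plast_on:
            for i in range(n_exc):
                ds = nloc - last[i]
                if ds > 0:
                    t0 = last[i] * dt_s
                    w = np.exp(t0 * inv_tau_e)
                    dw[i] += lr * w * (
                        c_pos[i] * (hp[nloc] - hp[last[i]])
                        + c_neg[i] * (hn[nloc] - hn[last[i]])
                    )
                    f = np.exp(-ds * dt_s * inv_tau_e)
                    c_pos[i] *= f
                    c_neg[i] *= f
                    x_pre[i] *= np.exp(-ds * dt_s / tau_p_s)
                last[i] = 0
        c0 = c1

    y_state[0] = y_val
    y_state[1] = y_last
    return v, u, s_ampa, s_nmda, s_gaba, n_spk, OK
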