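"""High-level driver for the spiking MSN: one neuron simulated over segments.

A :class:`MSNSimulation` owns the neuron's full state (membrane, synaptic
drive, conductances, eligibility and pairing traces) and advances it
through arbitrary segments of time given presynaptic spike trains and a
dopamine time course.  Trials of the operant experiment and the induction
protocols are both built from such segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import _engine
from .msn import (
    DopamineModulation,
    MSNParams,
    SynapseBank,
    SynapseParams,
    phi_of_dopamine,
)
from .plasticity import (
    KernelCoefficients,
    MixingParams,
    TimingParams,
    blended_amplitude,
    default_coefficients,
    default_mixing,
)

__all__ = ["MSNSimulation", "SegmentResult", "spike_trains_to_steps"]

DEFAULT_DT_MS = 0.025


def spike_trains_to_steps(
    trains: list[np.ndarray], dt_ms: float, n_steps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten per-synapse spike-time lists (seconds) into sorted step/synapse arrays."""
    times = np.concatenate(trains) if trains else np.empty(0)
    syn = np.concatenate(
        [np.full(len(t), i, dtype=np.int64) for i, t in enumerate(trains)]
    ) if trains else np.empty(0, dtype=np.int64)
    steps = np.floor(times * 1000.0 / dt_ms).astype(np.int64)
    keep = (steps >= 0) & (steps < n_steps)
    steps, syn = steps[keep], syn[keep]
    order = np.argsort(steps, kind="stable")
    return steps[order], syn[order]


@dataclass
class SegmentResult:
    n_spikes: int
    spike_times: np.ndarray  # seconds, relative to segment start
    dw: np.ndarray           # applied AMPA conductance change, nS
    v_trace: np.ndarray | None = None


@dataclass
class MSNSimulation:
    """A single dopamine-modulated MSN with plastic AMPA synapses."""

    msn_type: str
    params: MSNParams = field(default_factory=MSNParams)
    syn: SynapseParams = field(default_factory=SynapseParams)
    mod: DopamineModulation = field(default_factory=DopamineModulation)
    timing: TimingParams = field(default_factory=TimingParams)
    coeffs: KernelCoefficients = field(default_factory=default_coefficients)
    mixing: Mapping[str, MixingParams] = field(default_factory=default_mixing)
    dt_ms: float = DEFAULT_DT_MS
    bank: SynapseBank | None = None
    rng: np.random.Generator | None = None

    def __post_init__(self) -> None:
        if self.msn_type not in ("D1", "D2"):
            raise ValueError(f"unknown MSN type {self.msn_type!r}")
        if self.bank is None:
            rng = self.rng if self.rng is not None else np.random.default_rng(0)
            self.bank = SynapseBank.init(self.syn, rng)
        self.v = self.params.vr
        self.u = 0.0
        self._s_ampa = 0.0
        self._s_nmda = 0.0
        self._s_gaba = 0.0
        self._y_state = np.zeros(2)

    # -- dopamine-dependent per-step arrays ---------------------------------
    def _modulation_arrays(self, d_steps: np.ndarray):
        p = self.params
        phi = phi_of_dopamine(d_steps, self.mod)
        n = d_steps.shape[0]
        if self.msn_type == "D1":
            vr_t = p.vr * (1.0 + self.mod.k_kir * phi)
            k_t = np.full(n, p.k)
            d_t = p.d * (1.0 - self.mod.l_lca * phi)
            asc = np.ones(n)
            nsc = 1.0 + self.mod.beta_nmda * phi
        else:
            vr_t = np.full(n, p.vr)
            k_t = p.k * (1.0 - self.mod.alpha_ka * phi)
            d_t = np.full(n, p.d)
            asc = 1.0 - self.mod.beta_ampa * phi
            nsc = np.ones(n)
        return (
            np.ascontiguousarray(vr_t),
            np.ascontiguousarray(k_t),
            np.ascontiguousarray(d_t),
            np.ascontiguousarray(asc),
            np.ascontiguousarray(nsc),
        )

    def _plasticity_arrays(self, d_steps: np.ndarray, m_override: float | None):
        if m_override is not None:
            a = self.coeffs.amplitude
            t = self.msn_type
            pp = m_override * a(t, "hi", "pos") + (1 - m_override) * a(t, "lo", "pos")
            pn = m_override * a(t, "hi", "neg") + (1 - m_override) * a(t, "lo", "neg")
            n = d_steps.shape[0]
            return np.full(n, pp), np.full(n, pn)
        p_pos = blended_amplitude(self.msn_type, "pos", d_steps, self.coeffs, self.mixing)
        p_neg = blended_amplitude(self.msn_type, "neg", d_steps, self.coeffs, self.mixing)
        return np.ascontiguousarray(p_pos), np.ascontiguousarray(p_neg)

    def run_segment(
        self,
        duration_s: float,
        exc_trains: list[np.ndarray] | tuple[np.ndarray, np.ndarray],
        gaba_trains: list[np.ndarray] | tuple[np.ndarray, np.ndarray],
        dopamine,
        *,
        plastic: bool = True,
        m_override: float | None = None,
        forced_spike_times: np.ndarray | None = None,
        i_inject: float = 0.0,
        record_v: bool = False,
        apply_dw: bool = True,
    ) -> SegmentResult:
        """Advance the neuron through ``duration_s`` seconds.

        ``dopamine`` is a scalar level or a per-step array; ``exc_trains`` /
        ``gaba_trains`` are per-synapse spike-time lists (seconds) or
        pre-flattened ``(steps, syn)`` pairs.  ``m_override`` pins the
        plasticity mixing weight (used by the induction protocols to work
        at the dopamine extremes); ``forced_spike_times`` registers fictive
        postsynaptic spikes for pairing and reset without counting them as
        genuine spikes.
        """
        n_steps = int(round(duration_s * 1000.0 / self.dt_ms))
        d_steps = np.broadcast_to(np.asarray(dopamine, dtype=float), (n_steps,))
        d_steps = np.ascontiguousarray(d_steps)

        if isinstance(exc_trains, tuple):
            e_step, e_syn = exc_trains
        else:
            e_step, e_syn = spike_trains_to_steps(exc_trains, self.dt_ms, n_steps)
        if isinstance(gaba_trains, tuple):
            g_step, g_syn = gaba_trains
        else:
            g_step, g_syn = spike_trains_to_steps(gaba_trains, self.dt_ms, n_steps)

        vr_t, k_t, d_t, asc, nsc = self._modulation_arrays(d_steps)
        p_pos, p_neg = self._plasticity_arrays(d_steps, m_override)

        if forced_spike_times is None:
            forced = np.empty(0, dtype=np.int64)
        else:
            forced = np.unique(
                np.floor(np.asarray(forced_spike_times) * 1000.0 / self.dt_ms)
            ).astype(np.int64)

        bank = self.bank
        dw = np.zeros(self.syn.n_exc)
        spike_steps = np.zeros(20_000, dtype=np.int64)
        v_trace = np.zeros(n_steps if record_v else 1)

        alpha_eff = self.timing.alpha if plastic else 0.0
        out = _engine.run_segment(
            n_steps,
            self.dt_ms,
            e_step,
            e_syn,
            g_step,
            g_syn,
            bank.g_ampa,
            bank.g_nmda,
            bank.g_gaba,
            vr_t,
            k_t,
            d_t,
            asc,
            nsc,
            self.params.C,
            self.params.vt,
            self.params.vpeak,
            self.params.vreset,
            self.params.a,
            self.params.b,
            self.syn.tau_ampa,
            self.syn.tau_nmda,
            self.syn.tau_gaba,
            self.syn.mg,
            self.syn.e_gaba,
            i_inject,
            self.v,
            self.u,
            self._s_ampa,
            self._s_nmda,
            self._s_gaba,
            True,  # pairing traces always maintained; alpha gates the weight change
            alpha_eff,
            self.timing.tau_e,
            self.timing.tau_plus,
            self.timing.tau_minus,
            p_pos,
            p_neg,
            bank.x_pre,
            bank.c_pos,
            bank.c_neg,
            dw,
            self._y_state,
            forced,
            spike_steps,
            v_trace,
            record_v,
        )
        v, u, s_a, s_n, s_g, n_spk, err = out
        if err != _engine.OK:
            raise FloatingPointError(
                f"membrane state diverged (v={v}, u={u}); reduce dt or inputs"
            )
        self.v, self.u = v, u
        self._s_ampa, self._s_nmda, self._s_gaba = s_a, s_n, s_g
        # rebase the post-pairing trace to the next segment's time origin
        self._y_state[1] -= n_steps

        if plastic and apply_dw:
            bank.g_ampa += dw
            np.clip(bank.g_ampa, 0.0, self.syn.g_ceiling, out=bank.g_ampa)

        n_rec = min(n_spk, spike_steps.shape[0])
        times = spike_steps[:n_rec] * self.dt_ms / 1000.0
        return SegmentResult(
            n_spikes=n_spk,
            spike_times=times,
            dw=dw,
            v_trace=v_trace if record_v else None,
        )

    def reset_traces(self) -> None:
        """Zero the pairing and eligibility traces (not the conductances)."""
        self.bank.c_pos[:] = 0.0
        self.bank.c_neg[:] = 0.0
        self.bank.x_pre[:] = 0.0
        self._y_state[:] = 0.0
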