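"""Dopamine-modulated spiking medium spiny neuron (MSN).

The neuron is the biophysical (dimensional) form of the Izhikevich model,

    C dv/dt = k (v - vr)(v - vt) - u + I_syn
      du/dt = a [ b (v - vr) - u ]
    if v >= vpeak:  v <- vreset, u <- u + d

with AMPA, NMDA and GABAa conductance synapses (single-exponential channel
kinetics, NMDA gated by the Jahr-Stevens magnesium block) and direct
dopaminergic modulation of both intrinsic and synaptic parameters:

* D1 receptors (phi1): enhanced inward-rectifying K+ current, modelled as a
  hyperpolarising scaling of the resting potential ``vr (1 + K phi1)``;
  enhanced L-type Ca2+ current, as a reduction of the after-spike recovery
  increment ``d (1 - L phi1)``; and enhancement of NMDA-evoked EPSPs by
  ``(1 + beta_nmda phi1)``.
* D2 receptors (phi2): a small inhibitory effect on the slow A-type K+
  current raising rheobase, as ``k (1 - alpha_k phi2)``; and attenuation of
  AMPA-evoked EPSPs by ``(1 - beta_ampa phi2)``.

Receptor occupancies ``phi1, phi2`` follow the dopamine level through a
saturating map that is close to 1 across the phasic range.  A D1-type MSN
applies only the phi1 modulations, a D2-type MSN only the phi2 ones.

Units follow the Izhikevich convention: mV, ms, pA, pF, nS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MSNParams",
    "SynapseParams",
    "DopamineModulation",
    "DopamineOccupancy",
    "MembraneState",
    "SynapseBank",
    "phi_of_dopamine",
    "mg_block",
    "apply_dopamine",
    "step_membrane",
    "synaptic_current",
    "gen_poisson_inputs",
    "init_conductances",
    "holding_current",
]


@dataclass(frozen=True)
class MSNParams:
    """Intrinsic membrane parameters of the MSN."""

    C: float = 15.2        # pF
    vr: float = -80.0      # mV, resting potential
    vt: float = -29.7      # mV, threshold potential
    vpeak: float = 40.0    # mV, spike cutoff
    vreset: float = -55.0  # mV, post-spike reset
    k: float = 1.0         # scaling (integrator for b < 0)
    a: float = 0.01        # 1/ms, recovery rate
    b: float = -20.0       # recovery coupling
    d: float = 91.0        # after-spike recovery increment

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance must be positive")
        if not (self.vr < self.vt < self.vpeak):
            raise ValueError("require vr < vt < vpeak")


@dataclass(frozen=True)
class SynapseParams:
    """Synaptic population parameters.

    200 excitatory synapses each carry an AMPA and an NMDA receptor model;
    84 GABAergic synapses carry GABAa receptors.  Fixed NMDA and GABA
    conductances are tied to the initial AMPA scale by the ratio
    parameters; only AMPA conductances are plastic.
    """

    n_exc: int = 200
    n_gaba: int = 84
    e_ampa: float = 0.0      # mV (also NMDA reversal)
    e_gaba: float = -60.0    # mV
    tau_ampa: float = 6.0    # ms
    tau_nmda: float = 160.0  # ms
    tau_gaba: float = 4.0    # ms
    mg: float = 1.0          # mM
    g_ampa_mean: float = 0.458   # nS, initial mean AMPA conductance
    g_cv: float = 0.1            # coefficient of variation at initialisation
    g_ceiling: float = 2.0       # nS, hard ceiling on any synaptic conductance
    nmda_ampa_ratio: float = 0.2
    gaba_ampa_ratio: float = 1.4


@dataclass(frozen=True)
class DopamineModulation:
    """Dopamine-to-parameter coupling coefficients and the occupancy map."""

    k_kir: float = 0.0289    # D1: vr scaling (KIR enhancement)
    l_lca: float = 0.331     # D1: d scaling (L-type Ca2+ enhancement)
    alpha_ka: float = 0.032  # D2: k scaling (A-type K+, raised rheobase)
    beta_nmda: float = 0.5   # D1: NMDA efficacy enhancement
    beta_ampa: float = 0.215  # D2: AMPA efficacy attenuation
    phi_theta: float = 0.6   # half-occupancy dopamine level
    phi_n: float = 2.0       # occupancy map steepness


@dataclass(frozen=True)
class DopamineOccupancy:
    """Fractions of activated D1 and D2 receptors, each in [0, 1]."""

    phi1: float = 0.0
    phi2: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi1 <= 1.0 and 0.0 <= self.phi2 <= 1.0):
            raise ValueError("receptor occupancies must lie in [0, 1]")


def phi_of_dopamine(dopamine, mod: DopamineModulation = DopamineModulation()):
    """Saturating dopamine -> receptor occupancy map (same for D1 and D2).

    ``phi(D) = D**n / (D**n + theta**n)`` with a small half-occupancy level,
    so tonic dopamine gives phi slightly below 1 and the phasic range gives
    phi ~ 1.  Accepts scalars or arrays.
    """
    d = np.asarray(dopamine, dtype=float)
    if np.any(d < 0):
        raise ValueError("dopamine level must be non-negative")
    dn = np.power(d, mod.phi_n)
    out = dn / (dn + mod.phi_theta**mod.phi_n)
    return float(out) if out.ndim == 0 else out


def mg_block(v, mg: float = 1.0):
    """Jahr-Stevens voltage-dependent magnesium gate on the NMDA conductance.

    ``B(v) = 1 / (1 + (Mg/3.57) exp(-0.062 v))`` — a monotone increasing
    sigmoid from 0 (hyperpolarised) to 1 (depolarised).
    """
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + (mg / 3.57) * np.exp(-0.062 * v))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ModulatedParams:
    """Effective parameters after dopamine modulation."""

    vr: float
    k: float
    d: float
    ampa_scale: float
    nmda_scale: float


def apply_dopamine(
    occupancy: DopamineOccupancy,
    msn_type: str,
    params: MSNParams,
    mod: DopamineModulation = DopamineModulation(),
) -> ModulatedParams:
    """Linear dopaminergic scalings of the affected parameters.

    A D1-type MSN responds only to ``phi1`` (KIR, L-type Ca, NMDA), a
    D2-type MSN only to ``phi2`` (A-type K, AMPA).  Zero occupancy recovers
    the unmodulated neuron exactly.
    """
    if msn_type == "D1":
        return ModulatedParams(
            vr=params.vr * (1.0 + mod.k_kir * occupancy.phi1),
            k=params.k,
            d=params.d * (1.0 - mod.l_lca * occupancy.phi1),
            ampa_scale=1.0,
            nmda_scale=1.0 + mod.beta_nmda * occupancy.phi1,
        )
    if msn_type == "D2":
        return ModulatedParams(
            vr=params.vr,
            k=params.k * (1.0 - mod.alpha_ka * occupancy.phi2),
            d=params.d,
            ampa_scale=1.0 - mod.beta_ampa * occupancy.phi2,
            nmda_scale=1.0,
        )
    raise ValueError(f"unknown MSN type {msn_type!r}")


@dataclass
class MembraneState:
    v: float
    u: float = 0.0


def step_membrane(
    state: MembraneState,
    i_syn: float,
    params: MSNParams,
    dt: float = 0.1,
    eff: ModulatedParams | None = None,
) -> tuple[MembraneState, bool]:
    """One forward-Euler step of the membrane equations; returns (state, spiked).

    Reference implementation used by the tests; the trial engine in
    ``_engine`` runs the same update compiled.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    vr = params.vr if eff is None else eff.vr
    k = params.k if eff is None else eff.k
    d = params.d if eff is None else eff.d
    v, u = state.v, state.u
    if not (math.isfinite(v) and math.isfinite(u)):
        raise FloatingPointError(f"non-finite membrane state v={v}, u={u}")
    v = v + dt / params.C * (k * (v - vr) * (v - params.vt) - u + i_syn)
    u = u + dt * params.a * (params.b * (v - vr) - u)
    spiked = v >= params.vpeak
    if spiked:
        v = params.vreset
        u = u + d
    return MembraneState(v, u), spiked


@dataclass
class SynapseBank:
    """Per-synapse conductances, channel activations and eligibility traces."""

    g_ampa: np.ndarray           # nS, plastic
    g_nmda: np.ndarray           # nS, fixed
    g_gaba: np.ndarray           # nS, fixed
    z_ampa: np.ndarray | None = None
    z_nmda: np.ndarray | None = None
    z_gaba: np.ndarray | None = None
    c_pos: np.ndarray | None = None   # eligibility traces (per excitatory synapse)
    c_neg: np.ndarray | None = None
    x_pre: np.ndarray | None = None   # pre-spike pairing trace
    y_post: float = 0.0               # post-spike pairing trace (shared)

    def __post_init__(self) -> None:
        n = len(self.g_ampa)
        for name in ("z_ampa", "z_nmda", "c_pos", "c_neg", "x_pre"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(n))
        if self.z_gaba is None:
            self.z_gaba = np.zeros(len(self.g_gaba))

    @classmethod
    def init(cls, syn: SynapseParams, rng: np.random.Generator) -> "SynapseBank":
        g_ampa = init_conductances(
            syn.n_exc, syn.g_ampa_mean, syn.g_cv, syn.g_ceiling, rng
        )
        g_nmda = syn.nmda_ampa_ratio * g_ampa.copy()
        g_gaba = init_conductances(
            syn.n_gaba,
            syn.gaba_ampa_ratio * syn.g_ampa_mean,
            syn.g_cv,
            syn.g_ceiling * syn.gaba_ampa_ratio,
            rng,
        )
        return cls(g_ampa=g_ampa, g_nmda=g_nmda, g_gaba=g_gaba)


def synaptic_current(
    bank: SynapseBank,
    v: float,
    syn: SynapseParams,
    eff: ModulatedParams | None = None,
) -> float:
    """Total synaptic current ``I = sum_type g z (E_type - v)`` in pA.

    NMDA is gated by the magnesium block; receptor-specific dopamine
    scalings are applied when ``eff`` is given.
    """
    asc = 1.0 if eff is None else eff.ampa_scale
    nsc = 1.0 if eff is None else eff.nmda_scale
    i_ampa = asc * float(np.dot(bank.g_ampa, bank.z_ampa)) * (syn.e_ampa - v)
    i_nmda = (
        nsc
        * float(np.dot(bank.g_nmda, bank.z_nmda))
        * mg_block(v, syn.mg)
        * (syn.e_ampa - v)
    )
    i_gaba = float(np.dot(bank.g_gaba, bank.z_gaba)) * (syn.e_gaba - v)
    return i_ampa + i_nmda + i_gaba


def gen_poisson_inputs(
    n_synapses: int,
    rates,
    duration: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Independent homogeneous Poisson spike trains, one per synapse.

    ``rates`` is a scalar or per-synapse array of firing rates in spikes/s;
    ``duration`` is in seconds.  Returns a sorted array of spike times per
    synapse.  Reproducible given the generator.
    """
    rates = np.broadcast_to(np.asarray(rates, dtype=float), (n_synapses,))
    if np.any(rates < 0):
        raise ValueError("firing rates must be non-negative")
    counts = rng.poisson(rates * duration)
    return [np.sort(rng.uniform(0.0, duration, size=c)) for c in counts]


def init_conductances(
    n: int,
    mean: float,
    cv: float,
    ceiling: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian initial conductances; negatives clipped to 0, ceiling enforced."""
    if mean <= 0:
        raise ValueError("mean conductance must be positive")
    g = rng.normal(mean, cv * mean, size=n)
    return np.clip(g, 0.0, ceiling)


def holding_current(
    v_hold: float,
    params: MSNParams,
    eff: ModulatedParams | None = None,
) -> float:
    """Injected current that makes ``v_hold`` an equilibrium of the membrane.

    At equilibrium ``u = b (v - vr)`` and ``I = -k (v - vr)(v - vt) + u``.
    """
    vr = params.vr if eff is None else eff.vr
    k = params.k if eff is None else eff.k
    u_eq = params.b * (v_hold - vr)
    return -k * (v_hold - vr) * (v_hold - params.vt) + u_eq
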