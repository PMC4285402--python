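"""In-vitro induction replication and context-dependent renewal protocols.

Theta-burst induction
---------------------
The plasticity-induction experiment is replicated at a single plastic AMPA
synapse of the spiking MSN, membrane held at -70 mV by current injection.
Eight conditions: MSN type (D1/D2) x dopamine (hi/lo) x timing (pre-post /
post-pre).  Pre-post bursts are three EPSPs spaced 20 ms, each followed by
a fictive postsynaptic spike 5 ms later; post-pre bursts are three fictive
spikes spaced 20 ms, the last followed by an EPSP 10 ms later.  Bursts come
in blocks of five at 5 Hz; ten plastic blocks (2 s apart) are sandwiched
between zero-learning-rate measurement blocks.  The outcome is the ratio of
mean EPSP amplitude after to before induction.

Fictive spikes are forced pairing/reset events at the commanded times (the
held membrane cannot reach threshold, and the protocol requires that no
spontaneous spikes occur).  The dopamine conditions act at the extremes of
the mixing range (hi: m = 1, lo: m = 0), the levels at which the extreme
STDP kernels are defined, with the receptor occupancies set accordingly.

Renewal and reacquisition
-------------------------
Operant context is carried by which afferent subset receives the salient
input.  Context B shares half of context A's 50-synapse set, the other half
drawn from the complement.  After learning (+ intermission) in A, extinction
(dopamine dips) runs under the second context of a sequence (AAA, ABA, ABB)
and reacquisition (bursts reinstated) under the third.  At each test point
the trained MSN pair is converted to rate-coded equivalents and behavioural
performance is the number of key-channel selections over the salience-pair
assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .bg_network import NetworkProfile
from .experiment import (
    DopamineParams,
    ScheduleConfig,
    build_schedule,
    dopamine_step_values,
    run_trial,
)
from .msn import holding_current, phi_of_dopamine
from .plasticity import KernelCoefficients, default_coefficients
from .selection_assay import (
    behavioural_performance,
    fit_rate_equivalent,
    measure_io_curve,
)
from .simulate import MSNSimulation

__all__ = [
    "InductionCondition",
    "INDUCTION_CONDITIONS",
    "ContextSets",
    "shen_induction",
    "make_context_sets",
    "run_context_sequence",
    "SequenceResult",
]


@dataclass(frozen=True)
class InductionCondition:
    msn_type: str   # "D1" | "D2"
    dopamine: str   # "hi" | "lo"
    timing: str     # "pre_post" | "post_pre"

    def __post_init__(self) -> None:
        if self.msn_type not in ("D1", "D2"):
            raise ValueError("msn_type must be D1 or D2")
        if self.dopamine not in ("hi", "lo"):
            raise ValueError("dopamine must be hi or lo")
        if self.timing not in ("pre_post", "post_pre"):
            raise ValueError("timing must be pre_post or post_pre")


INDUCTION_CONDITIONS = tuple(
    InductionCondition(t, d, s)
    for t in ("D1", "D2")
    for d in ("hi", "lo")
    for s in ("pre_post", "post_pre")
)


def _burst_events(timing: str, t0: float) -> tuple[list[float], list[float]]:
    """(EPSP times, fictive spike times) for one burst starting at t0 (s)."""
    if timing == "pre_post":
        epsps = [t0, t0 + 0.020, t0 + 0.040]
        posts = [t + 0.005 for t in epsps]
    else:
        posts = [t0, t0 + 0.020, t0 + 0.040]
        epsps = [posts[-1] + 0.010]
    return epsps, posts


def _block_events(timing: str, t0: float, n_bursts: int = 5, period: float = 0.2):
    epsps, posts = [], []
    for b in range(n_bursts):
        e, p = _burst_events(timing, t0 + b * period)
        epsps += e
        posts += p
    return epsps, posts


def shen_induction(
    condition: InductionCondition,
    coeffs: KernelCoefficients | None = None,
    seed: int = 0,
    n_plastic_blocks: int = 10,
    n_measure_epsps: int = 5,
    block_gap: float = 2.0,
    v_hold: float = -70.0,
    g_initial: float = 0.458,
) -> dict:
    """Run one induction condition; returns the EPSP ratio and details.

    The membrane is held at ``v_hold`` by injected current; the single
    plastic synapse's EPSP amplitude (peak depolarisation from holding) is
    averaged over measurement blocks before and after ten plastic blocks.
    A spontaneous (threshold-crossing) spike aborts the run.
    """
    co = coeffs if coeffs is not None else default_coefficients()
    sim = MSNSimulation(
        msn_type=condition.msn_type,
        coeffs=co,
        rng=np.random.default_rng(seed),
    )
    # single plastic synapse; silence everything else
    sim.bank.g_ampa[:] = 0.0
    sim.bank.g_ampa[0] = g_initial
    sim.bank.g_nmda[:] = 0.0   # held far below the NMDA-unblocking range
    sim.bank.g_gaba[:] = 0.0
    m_override = 1.0 if condition.dopamine == "hi" else 0.0
    d_level = 6.0 if condition.dopamine == "hi" else 0.0
    phi = phi_of_dopamine(d_level, sim.mod)
    # modulated holding current for this condition
    from .msn import DopamineOccupancy, apply_dopamine

    eff = apply_dopamine(
        DopamineOccupancy(phi1=phi if condition.msn_type == "D1" else 0.0,
                          phi2=phi if condition.msn_type == "D2" else 0.0),
        condition.msn_type,
        sim.params,
        sim.mod,
    )
    i_hold = holding_current(v_hold, sim.params, eff)
    sim.v, sim.u = v_hold, sim.params.b * (v_hold - eff.vr)

    def run_block(timing: str, plastic: bool, with_posts: bool = True):
        """One block (5 bursts at 5 Hz) plus the inter-block gap."""
        duration = 5 * 0.2 + block_gap
        epsps, posts = _block_events(timing, 0.05)
        if not with_posts:
            posts = []
        exc = [np.array(epsps)] + [np.array([])] * (sim.syn.n_exc - 1)
        res = sim.run_segment(
            duration,
            exc,
            [np.array([])] * sim.syn.n_gaba,
            d_level,
            plastic=plastic,
            m_override=m_override,
            forced_spike_times=np.array(posts),
            i_inject=i_hold,
            record_v=True,
        )
        if res.n_spikes > 0:
            raise RuntimeError(
                "spontaneous action potential during induction; protocol "
                "assumes a silent held membrane"
            )
        # peak depolarisation from holding after each EPSP
        n_steps = len(res.v_trace)
        amps = []
        for t_e in epsps:
            s0 = int(t_e * 1000 / sim.dt_ms)
            s1 = min(s0 + int(50 / sim.dt_ms), n_steps)
            amps.append(float(np.max(res.v_trace[s0:s1]) - v_hold))
        return amps

    def measure():
        # test EPSPs alone (no pairing, no plasticity), 2 s apart
        amps = []
        for _ in range(n_measure_epsps):
            a = run_block_single_epsp()
            amps.append(a)
        return float(np.mean(amps))

    def run_block_single_epsp():
        duration = 2.0
        exc = [np.array([0.05])] + [np.array([])] * (sim.syn.n_exc - 1)
        res = sim.run_segment(
            duration,
            exc,
            [np.array([])] * sim.syn.n_gaba,
            d_level,
            plastic=False,
            m_override=m_override,
            i_inject=i_hold,
            record_v=True,
        )
        if res.n_spikes > 0:
            raise RuntimeError("spontaneous action potential during measurement")
        s0 = int(0.05 * 1000 / sim.dt_ms)
        s1 = s0 + int(50 / sim.dt_ms)
        return float(np.max(res.v_trace[s0:s1]) - v_hold)

    g0 = float(sim.bank.g_ampa[0])
    epsp_before = measure()
    for _ in range(n_plastic_blocks):
        run_block(condition.timing, plastic=True)
    epsp_after = measure()
    return {
        "condition": condition,
        "epsp_before": epsp_before,
        "epsp_after": epsp_after,
        "ratio": epsp_after / epsp_before,
        "g_before": g0,
        "g_after": float(sim.bank.g_ampa[0]),
    }


@dataclass(frozen=True)
class ContextSets:
    """Afferent index sets for two operant contexts sharing a sensory core."""

    s_a: np.ndarray
    s_b: np.ndarray

    def __post_init__(self) -> None:
        if len(np.intersect1d(self.s_a, self.s_b)) == 0 and len(self.s_a):
            raise ValueError("contexts share no afferents; expected a common core")

    def for_context(self, ctx: str) -> np.ndarray:
        return self.s_a if ctx == "A" else self.s_b


def make_context_sets(
    s_original: np.ndarray,
    shared_fraction: float = 0.5,
    seed: int = 0,
    n_exc: int = 200,
) -> ContextSets:
    """Build context B's afferent set sharing ``shared_fraction`` of A's.

    The shared core models sensory/pre-motor components common across
    contexts; the remainder of B is drawn uniformly from the complement of
    A.  Deterministic under ``seed``.
    """
    s_a = np.sort(np.asarray(s_original, dtype=np.int64))
    if not 0.0 < shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=[seed, 77]))
    n_shared = int(round(shared_fraction * len(s_a)))
    shared = rng.choice(s_a, size=n_shared, replace=False)
    complement = np.setdiff1d(np.arange(n_exc), s_a)
    new = rng.choice(complement, size=len(s_a) - n_shared, replace=False)
    s_b = np.sort(np.concatenate([shared, new]))
    return ContextSets(s_a=s_a, s_b=s_b)


@dataclass
class SequenceResult:
    sequence: str
    acquisition_count: int       # performance in the test context before extinction
    renewal_count: int           # after extinction, in the third context
    reacquisition_count: int     # after re-learning in the third context
    g_trajectory: dict           # mean g of S_A / S_B per trial through ext + reacq
    fitted_units: dict


def _fit_and_score(
    sims: Mapping[str, MSNSimulation],
    salient_set: np.ndarray,
    profile: NetworkProfile | None,
    seed: int,
) -> tuple[int, dict]:
    units = {}
    for mt in ("D1", "D2"):
        x, y = measure_io_curve(sims[mt], salient_set, seed=seed)
        units[mt] = fit_rate_equivalent(x, y)
    count = behavioural_performance(units["D1"], units["D2"], profile=profile)
    return count, units


def run_context_sequence(
    sequence: str,
    trained_sims: Mapping[str, MSNSimulation],
    contexts: ContextSets,
    n_ext: int = 40,
    n_reacq: int = 40,
    seed: int = 0,
    profile: NetworkProfile | None = None,
    schedule_config: ScheduleConfig | None = None,
    dopa: DopamineParams | None = None,
) -> SequenceResult:
    """Extinction and reacquisition of a trained MSN pair under a context sequence.

    ``sequence`` is one of "AAA", "ABA", "ABB" (learning context, extinction
    context, test/reacquisition context).  ``trained_sims`` maps MSN type to
    simulations already trained in context A (deep-copied internally).
    Dips drive extinction; bursts are reinstated at full amplitude for
    reacquisition.
    """
    if sequence not in ("AAA", "ABA", "ABB"):
        raise ValueError("sequence must be AAA, ABA or ABB")
    import copy

    cfg = schedule_config if schedule_config is not None else ScheduleConfig()
    dp = dopa if dopa is not None else DopamineParams()
    ext_ctx, test_ctx = sequence[1], sequence[2]
    sims = {mt: copy.deepcopy(trained_sims[mt]) for mt in ("D1", "D2")}

    # acquisition test: performance in the *test* context before extinction
    acq_count, acq_units = _fit_and_score(
        sims, contexts.for_context(test_ctx), profile, seed
    )

    g_traj = {"S_A": {mt: [] for mt in sims}, "S_B": {mt: [] for mt in sims}}

    def record():
        for mt, sim in sims.items():
            g_traj["S_A"][mt].append(float(np.mean(sim.bank.g_ampa[contexts.s_a])))
            g_traj["S_B"][mt].append(float(np.mean(sim.bank.g_ampa[contexts.s_b])))

    # extinction: dips under the extinction context's afferent set
    ext_cfg = replace(cfg, trials=(0, 0, 0, n_ext, 0))
    ext_sched = build_schedule(
        ext_cfg, dp, seed=seed + 1, fixed_set=contexts.for_context(ext_ctx)
    )
    rngs = {
        mt: np.random.default_rng(np.random.SeedSequence(entropy=[seed, i, 33]))
        for i, mt in enumerate(sims)
    }
    for t in range(ext_sched.n_trials):
        for mt, sim in sims.items():
            run_trial(sim, ext_sched, t, rngs[mt])
        record()

    renew_count, renew_units = _fit_and_score(
        sims, contexts.for_context(test_ctx), profile, seed
    )

    # reacquisition: bursts reinstated at full amplitude under the test context
    reacq_cfg = replace(cfg, trials=(0, n_reacq, 0, 0, 0))
    reacq_dp = replace(dp, tau_envelope=1e9)  # reinforcement on every trial
    reacq_sched = build_schedule(
        reacq_cfg, reacq_dp, seed=seed + 2, fixed_set=contexts.for_context(test_ctx)
    )
    for t in range(reacq_sched.n_trials):
        for mt, sim in sims.items():
            run_trial(sim, reacq_sched, t, rngs[mt])
        record()

    reacq_count, reacq_units = _fit_and_score(
        sims, contexts.for_context(test_ctx), profile, seed
    )

    return SequenceResult(
        sequence=sequence,
        acquisition_count=acq_count,
        renewal_count=renew_count,
        reacquisition_count=reacq_count,
        g_trajectory=g_traj,
        fitted_units={
            "acquisition": acq_units,
            "renewal": renew_units,
            "reacquisition": reacq_units,
        },
    )
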