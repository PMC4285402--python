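"""The simulated operant-conditioning experiment.

A multi-epoch experiment (baseline, learning, intermission, extinction,
post-extinction; 15/40/30/40/30 trials by default) drives a single spiking
MSN.  Every 2.4 s trial contains a 0.4 s bout of high-salience cortical
input ("action request") to a 50-synapse subset S of the 200 excitatory
afferents: 25 spikes/s inside the bout, 3 spikes/s background elsewhere and
at the 84 GABA synapses.  During learning and extinction the same subset S
is used on every trial (the reinforced action); in the other epochs S is
redrawn uniformly at random each trial (free action choice).

Dopamine is tonic (level 3) except on reinforced/extinguished trials, where
a phasic event (burst in learning, dip in extinction) arrives 150 ms after
the salient bout with an onset amplitude drawn from a Gaussian around the
across-trial envelope Gamma (s.d. 0.55) and decays with a 20 ms constant.
Gamma decays exponentially from its maximum across the learning epoch
(time constant ~20.8 s, i.e. below 1% of maximum by the epoch's end) and
rises from its most negative value back toward zero across extinction; the
dopamine level itself is floored at zero.

AMPA conductances are updated by the STDE rule throughout every trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .msn import DopamineModulation, MSNParams, SynapseParams
from .plasticity import (
    KernelCoefficients,
    MixingParams,
    TimingParams,
    default_coefficients,
    default_mixing,
)
from .simulate import MSNSimulation

__all__ = [
    "EPOCHS",
    "ScheduleConfig",
    "DopamineParams",
    "ExperimentSchedule",
    "ActivityProfile",
    "build_schedule",
    "gamma_envelope",
    "dopamine_step_values",
    "run_trial",
    "run_experiment",
    "summarize_profiles",
]

EPOCHS = ("baseline", "learning", "intermission", "extinction", "post_extinction")
DEFAULT_TRIALS = (15, 40, 30, 40, 30)


@dataclass(frozen=True)
class ScheduleConfig:
    """Trial structure and input-rate parameters."""

    trials: tuple = DEFAULT_TRIALS
    trial_duration: float = 2.4      # s
    salient_duration: float = 0.4    # s
    salient_onset: float = 1.0       # s into the trial
    salient_rate: float = 25.0       # spikes/s at synapses in S during the bout
    background_rate: float = 3.0     # spikes/s otherwise
    gaba_rate: float = 3.0           # spikes/s at GABA synapses throughout
    subset_size: int = 50
    n_exc: int = 200

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.trials):
            raise ValueError("trial counts must be non-negative")
        if self.subset_size > self.n_exc:
            raise ValueError("salient subset larger than the afferent population")


@dataclass(frozen=True)
class DopamineParams:
    """Tonic level, phasic-event shape and across-trial envelope."""

    tonic: float = 3.0
    burst_max: float = 3.0       # Gamma_max: burst onset envelope at learning start
    dip_min: float = -6.0        # envelope at extinction start (deep dips clip D at 0)
    onset_sd: float = 0.55       # trial-to-trial s.d. of the onset amplitude
    tau_event: float = 0.02      # s, within-trial decay of a phasic event
    delivery_delay: float = 0.15  # s after the end of the salient bout
    tau_envelope: float = 20.8   # s, across-trial decay of |Gamma|


@dataclass
class ExperimentSchedule:
    """A fully realised, deterministic experiment plan."""

    config: ScheduleConfig
    dopa: DopamineParams
    seed: int
    epoch: np.ndarray          # epoch index per trial
    salient_sets: np.ndarray   # (n_trials, subset_size) int synapse indices
    reinforcement: np.ndarray  # +1 burst, -1 dip, 0 none, per trial
    gamma: np.ndarray          # envelope value per trial (signed)
    onset_amplitude: np.ndarray  # sampled phasic onset per trial (0 where no event)

    @property
    def n_trials(self) -> int:
        return len(self.epoch)

    def learning_set(self) -> np.ndarray:
        """The fixed subset S used during learning and extinction."""
        idx = np.flatnonzero(self.epoch == 1)
        if len(idx) == 0:
            idx = np.flatnonzero(self.epoch == 3)
        if len(idx) == 0:
            raise ValueError("schedule has neither learning nor extinction trials")
        return self.salient_sets[idx[0]]


def gamma_envelope(
    trial_in_epoch: int,
    epoch: str,
    config: ScheduleConfig,
    dopa: DopamineParams,
) -> float:
    """Across-trial phasic-amplitude envelope Gamma at a trial's onset.

    Decays exponentially from ``burst_max`` over the learning epoch, rises
    exponentially from ``dip_min`` toward zero over extinction, and is zero
    in the tonic-only epochs.
    """
    elapsed = trial_in_epoch * config.trial_duration
    decay = np.exp(-elapsed / dopa.tau_envelope)
    if epoch == "learning":
        return dopa.burst_max * decay
    if epoch == "extinction":
        return dopa.dip_min * decay
    return 0.0


def build_schedule(
    config: ScheduleConfig = ScheduleConfig(),
    dopa: DopamineParams = DopamineParams(),
    seed: int = 0,
    fixed_set: np.ndarray | None = None,
) -> ExperimentSchedule:
    """Realise a schedule: epochs, salient subsets, envelopes, onset amplitudes.

    Deterministic under ``seed``.  ``fixed_set`` overrides the subset used
    in the learning/extinction epochs (the context-manipulation protocols
    use this to re-run extinction with a different afferent set).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=[seed, 911]))
    n_trials = int(np.sum(config.trials))
    epoch = np.repeat(np.arange(len(config.trials)), config.trials)

    # fixed subset for learning and extinction, redrawn elsewhere
    s_fixed = (
        np.asarray(fixed_set, dtype=np.int64)
        if fixed_set is not None
        else np.sort(rng.choice(config.n_exc, size=config.subset_size, replace=False))
    )
    if len(s_fixed) != config.subset_size:
        raise ValueError("fixed subset has the wrong size")
    sets = np.empty((n_trials, config.subset_size), dtype=np.int64)
    reinf = np.zeros(n_trials, dtype=np.int64)
    gamma = np.zeros(n_trials)
    onset = np.zeros(n_trials)

    trial_in_epoch = 0
    prev_epoch = -1
    for t in range(n_trials):
        e = int(epoch[t])
        trial_in_epoch = trial_in_epoch + 1 if e == prev_epoch else 0
        prev_epoch = e
        name = EPOCHS[e]
        if name in ("learning", "extinction"):
            sets[t] = s_fixed
            reinf[t] = 1 if name == "learning" else -1
            gamma[t] = gamma_envelope(trial_in_epoch, name, config, dopa)
            onset[t] = rng.normal(gamma[t], dopa.onset_sd)
        else:
            sets[t] = np.sort(
                rng.choice(config.n_exc, size=config.subset_size, replace=False)
            )
    return ExperimentSchedule(
        config=config,
        dopa=dopa,
        seed=seed,
        epoch=epoch,
        salient_sets=sets,
        reinforcement=reinf,
        gamma=gamma,
        onset_amplitude=onset,
    )


def dopamine_step_values(
    schedule: ExperimentSchedule, trial: int, dt_ms: float
) -> np.ndarray:
    """Per-step dopamine level D(t) >= 0 for one trial.

    Tonic everywhere except after the phasic onset (salient-bout end plus
    the 150 ms delivery delay), where the sampled onset amplitude decays
    with the 20 ms event constant; dips are negative amplitudes and the
    total level is floored at zero.
    """
    cfg, dopa = schedule.config, schedule.dopa
    n_steps = int(round(cfg.trial_duration * 1000.0 / dt_ms))
    t = np.arange(n_steps) * dt_ms / 1000.0
    d = np.full(n_steps, dopa.tonic)
    if schedule.reinforcement[trial] != 0:
        t0 = cfg.salient_onset + cfg.salient_duration + dopa.delivery_delay
        amp = schedule.onset_amplitude[trial]
        after = t >= t0
        d[after] += amp * np.exp(-(t[after] - t0) / dopa.tau_event)
    np.clip(d, 0.0, None, out=d)
    return d


@dataclass
class ActivityProfile:
    """Per-trial spike counts and mean conductance of the learning set."""

    msn_type: str
    repeat: int
    spike_count: np.ndarray
    mean_g_learning_set: np.ndarray
    epoch: np.ndarray
    trials: tuple

    def epoch_slice(self, name: str) -> slice:
        e = EPOCHS.index(name)
        idx = np.flatnonzero(self.epoch == e)
        return slice(int(idx[0]), int(idx[-1]) + 1)


def _trial_spike_inputs(
    sim: MSNSimulation,
    schedule: ExperimentSchedule,
    trial: int,
    rng: np.random.Generator,
):
    """Poisson input spike (step, synapse) arrays for one trial."""
    cfg = schedule.config
    dt_ms = sim.dt_ms
    n_steps = int(round(cfg.trial_duration * 1000.0 / dt_ms))
    rates_bg = np.full(cfg.n_exc, cfg.background_rate)
    rates_hi = rates_bg.copy()
    rates_hi[schedule.salient_sets[trial]] = cfg.salient_rate
    segs = [
        (0.0, cfg.salient_onset, rates_bg),
        (cfg.salient_onset, cfg.salient_onset + cfg.salient_duration, rates_hi),
        (cfg.salient_onset + cfg.salient_duration, cfg.trial_duration, rates_bg),
    ]
    steps_all, syn_all = [], []
    for t0, t1, rates in segs:
        counts = rng.poisson(rates * (t1 - t0))
        total = int(counts.sum())
        times = rng.uniform(t0, t1, size=total)
        syn = np.repeat(np.arange(cfg.n_exc, dtype=np.int64), counts)
        steps_all.append(np.floor(times * 1000.0 / dt_ms).astype(np.int64))
        syn_all.append(syn)
    # GABA background
    g_counts = rng.poisson(np.full(sim.syn.n_gaba, cfg.gaba_rate) * cfg.trial_duration)
    g_times = rng.uniform(0.0, cfg.trial_duration, size=int(g_counts.sum()))
    g_syn = np.repeat(np.arange(sim.syn.n_gaba, dtype=np.int64), g_counts)

    e_step = np.concatenate(steps_all)
    e_syn = np.concatenate(syn_all)
    keep = e_step < n_steps
    e_step, e_syn = e_step[keep], e_syn[keep]
    order = np.argsort(e_step, kind="stable")
    g_step = np.floor(g_times * 1000.0 / dt_ms).astype(np.int64)
    keep = g_step < n_steps
    g_step, g_syn = g_step[keep], g_syn[keep]
    g_order = np.argsort(g_step, kind="stable")
    return (e_step[order], e_syn[order]), (g_step[g_order], g_syn[g_order])


def run_trial(
    sim: MSNSimulation,
    schedule: ExperimentSchedule,
    trial: int,
    rng: np.random.Generator,
    plastic: bool = True,
) -> int:
    """Simulate one trial, updating the AMPA conductances in place.

    Returns the trial's spike count.  Deterministic given the generator
    state and the simulation state.
    """
    exc, gab = _trial_spike_inputs(sim, schedule, trial, rng)
    d = dopamine_step_values(schedule, trial, sim.dt_ms)
    res = sim.run_segment(
        schedule.config.trial_duration, exc, gab, d, plastic=plastic
    )
    return res.n_spikes


def run_experiment(
    msn_type: str,
    schedule: ExperimentSchedule | None = None,
    n_repeats: int = 1,
    seed: int = 0,
    *,
    coeffs: KernelCoefficients | None = None,
    mixing: Mapping[str, MixingParams] | None = None,
    timing: TimingParams | None = None,
    msn_params: MSNParams | None = None,
    syn_params: SynapseParams | None = None,
    mod: DopamineModulation | None = None,
    dt_ms: float = 0.025,
    schedule_config: ScheduleConfig | None = None,
    dopa_params: DopamineParams | None = None,
    return_sims: bool = False,
):
    """Run the full multi-epoch experiment for one MSN type.

    Each repeat uses its own schedule realisation and input streams,
    deterministic in ``(seed, repeat)``; D1 and D2 runs at the same seed
    share schedules, as when comparing the two types on the same task.
    Returns a list of :class:`ActivityProfile`, one per repeat (plus the
    simulations when ``return_sims``).
    """
    profiles = []
    sims = []
    for rep in range(n_repeats):
        if schedule is not None:
            sched = schedule
        else:
            # one independent schedule per repeat, deterministic in (seed, rep);
            # D1 and D2 runs at the same seed therefore share schedules
            sched = build_schedule(
                config=schedule_config if schedule_config is not None else ScheduleConfig(),
                dopa=dopa_params if dopa_params is not None else DopamineParams(),
                seed=(seed * 1009 + rep) % (2**31 - 1),
            )
        ss = np.random.SeedSequence(entropy=[seed, rep, 202])
        r_init, r_trial = [np.random.default_rng(s) for s in ss.spawn(2)]
        kw = {}
        if msn_params is not None:
            kw["params"] = msn_params
        if syn_params is not None:
            kw["syn"] = syn_params
        if mod is not None:
            kw["mod"] = mod
        if timing is not None:
            kw["timing"] = timing
        if mixing is not None:
            kw["mixing"] = mixing
        sim = MSNSimulation(
            msn_type=msn_type,
            coeffs=coeffs if coeffs is not None else default_coefficients(),
            dt_ms=dt_ms,
            rng=r_init,
            **kw,
        )
        s_learn = sched.learning_set()
        counts = np.zeros(sched.n_trials, dtype=np.int64)
        mean_g = np.zeros(sched.n_trials)
        for t in range(sched.n_trials):
            counts[t] = run_trial(sim, sched, t, r_trial)
            mean_g[t] = float(np.mean(sim.bank.g_ampa[s_learn]))
        profiles.append(
            ActivityProfile(
                msn_type=msn_type,
                repeat=rep,
                spike_count=counts,
                mean_g_learning_set=mean_g,
                epoch=sched.epoch.copy(),
                trials=sched.config.trials,
            )
        )
        sims.append(sim)
    if return_sims:
        return profiles, sims
    return profiles


def summarize_profiles(profiles: list[ActivityProfile], window: int = 3):
    """Ensemble mean over repeats, then centred moving average of width ``window``.

    Edges are truncated (the average runs over the in-range part of the
    window).  Returns (smoothed spike counts, smoothed mean conductances).
    """
    if not profiles:
        raise ValueError("no profiles to summarise")
    n = len(profiles[0].spike_count)
    if any(len(p.spike_count) != n for p in profiles):
        raise ValueError("profiles have unequal lengths")
    counts = np.mean([p.spike_count for p in profiles], axis=0)
    gs = np.mean([p.mean_g_learning_set for p in profiles], axis=0)
    return _moving_average(counts, window), _moving_average(gs, window)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return x.copy()
    half = window // 2
    csum = np.cumsum(np.concatenate(([0.0], x)))
    n = len(x)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)
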