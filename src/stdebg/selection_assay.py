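"""Ideal-selector templates, responsiveness sweeps, and rate-coded fits.

The basal ganglia network's selection competence is scored against an
*ideal selector template*: over a 10 x 10 grid of salience pairs driven
into the experimental (channel 1) and control (channel 2) channels, the
ideal outcome of each competition is

* selection mode (end of learning): no selection when both saliences are at
  or below the MSN output threshold; otherwise the larger salience's
  channel is selected (exact ties: no selection);
* suppression mode (end of extinction): the experimental channel is never
  selected; the control channel is selected iff its salience exceeds the
  threshold.

The model's outcomes over the same grid are summarised as a percentage
match.  Sweeping the experimental channel's D1 and D2 input weights
("responsiveness" — the input:output ratio of the MSN population, with the
dopamine factors folded into the swept weights and the MSN output
saturation dropped) maps where in the (w_D1, w_D2) plane selection and
suppression are best achieved.

Trained spiking MSNs are carried into the network by measuring their
normalised input-output firing curve (output 1 == 40 spikes/s; input 1 ==
all 50 salient afferents at 40 spikes/s) and least-squares fitting a
piecewise-linear rate unit ``y = max(0, w x - eps)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .bg_network import NetworkProfile, integrate
from .simulate import MSNSimulation

__all__ = [
    "SelectorTemplate",
    "SweepResult",
    "default_salience_grid",
    "build_template",
    "template_match",
    "run_competitions",
    "sweep_responsiveness",
    "measure_io_curve",
    "fit_rate_equivalent",
    "behavioural_performance",
]

#: outcome codes: 0 none, 1 ch1, 2 ch2, 3 both
NONE, CH1, CH2, BOTH = 0, 1, 2, 3


def default_salience_grid(n: int = 10, lo: float = 0.1, hi: float = 1.0) -> np.ndarray:
    return np.linspace(lo, hi, n)


@dataclass(frozen=True)
class SelectorTemplate:
    mode: str                 # "selection" or "suppression"
    grid: np.ndarray          # salience values per axis
    labels: np.ndarray        # (n, n) outcome codes; [i, j] = (s1=grid[i], s2=grid[j])

    def __post_init__(self) -> None:
        n = len(self.grid)
        if self.labels.shape != (n, n):
            raise ValueError("label grid must be n x n")


def build_template(
    mode: str,
    eps_msn: float = 0.2,
    grid: np.ndarray | None = None,
) -> SelectorTemplate:
    """Ideal outcomes over all salience pairs (see module docstring)."""
    if mode not in ("selection", "suppression"):
        raise ValueError("mode must be 'selection' or 'suppression'")
    g = default_salience_grid() if grid is None else np.asarray(grid, dtype=float)
    n = len(g)
    labels = np.full((n, n), NONE, dtype=np.int64)
    for i, s1 in enumerate(g):
        for j, s2 in enumerate(g):
            if s1 <= eps_msn and s2 <= eps_msn:
                labels[i, j] = NONE
            elif mode == "selection":
                if s1 > s2:
                    labels[i, j] = CH1
                elif s2 > s1:
                    labels[i, j] = CH2
                else:
                    labels[i, j] = NONE
            else:  # suppression: ch1 never selected
                labels[i, j] = CH2 if s2 > eps_msn else NONE
    return SelectorTemplate(mode=mode, grid=g, labels=labels)


def template_match(model_outcomes: np.ndarray, template: SelectorTemplate) -> float:
    """Percentage of salience pairs whose outcome matches the template."""
    out = np.asarray(model_outcomes)
    if out.shape != template.labels.shape:
        raise ValueError("outcome grid does not match the template grid")
    return 100.0 * float(np.mean(out == template.labels))


def run_competitions(
    profile: NetworkProfile,
    grid: np.ndarray,
    duration_s: float = 3.5,
    dt_s: float = 0.005,
) -> np.ndarray:
    """Outcome codes over all salience pairs (experimental ch 1 at t=1 s,
    control ch 2 at t=2 s, equilibrium readout)."""
    n = len(grid)
    s1, s2 = np.meshgrid(grid, grid, indexing="ij")
    sal = np.zeros((n * n, profile.n_channels))
    sal[:, 0] = s1.ravel()
    sal[:, 1] = s2.ravel()
    onsets = np.zeros(profile.n_channels)
    onsets[0], onsets[1] = 1.0, 2.0
    st = integrate(profile, sal, dt_s=dt_s, duration_s=duration_s, input_onsets=onsets)
    gpi = st.y["gpi"]
    sel1 = gpi[:, 0] < profile.theta_sel
    sel2 = gpi[:, 1] < profile.theta_sel
    return (sel1.astype(np.int64) + 2 * sel2.astype(np.int64)).reshape(n, n)


@dataclass
class SweepResult:
    mode: str
    w_d1: np.ndarray
    w_d2: np.ndarray
    match: np.ndarray  # (len(w_d1), len(w_d2)) percent match

    @property
    def argmax(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.match), self.match.shape)
        return float(self.w_d1[i]), float(self.w_d2[j])


def sweep_responsiveness(
    mode: str,
    w_d1_range: np.ndarray | None = None,
    w_d2_range: np.ndarray | None = None,
    profile: NetworkProfile | None = None,
    grid: np.ndarray | None = None,
    eps_msn: float = 0.2,
) -> SweepResult:
    """Template match over a grid of experimental-channel D1/D2 weights.

    Control-channel weights are 1; the experimental channel's dopamine
    factors are folded into the swept weights and its MSN outputs are not
    saturated.
    """
    w1s = np.linspace(1.0, 2.0, 21) if w_d1_range is None else np.asarray(w_d1_range)
    w2s = np.linspace(1.0, 2.0, 21) if w_d2_range is None else np.asarray(w_d2_range)
    base = profile if profile is not None else NetworkProfile()
    g = default_salience_grid() if grid is None else np.asarray(grid, dtype=float)
    template = build_template(mode, eps_msn=eps_msn, grid=g)
    n, nc = len(g), base.n_channels
    # one batched integration over (w1, w2, salience pair): the weights enter
    # the dynamics linearly, so they ride along as per-row channel weights
    s1, s2 = np.meshgrid(g, g, indexing="ij")
    sal = np.zeros((n * n, nc))
    sal[:, 0] = s1.ravel()
    sal[:, 1] = s2.ravel()
    k1, k2 = len(w1s), len(w2s)
    big_sal = np.tile(sal, (k1 * k2, 1))
    w1_col = np.repeat(w1s, k2 * n * n)
    w2_col = np.tile(np.repeat(w2s, n * n), k1)
    w_d1 = np.ones((k1 * k2 * n * n, nc))
    w_d2 = np.ones_like(w_d1)
    w_d1[:, 0] = w1_col
    w_d2[:, 0] = w2_col
    # dopamine efficacy factors are folded into the swept and control weights:
    # "responsiveness" is the net input:output ratio, so the factors are
    # removed from the whole network for the duration of the sweep
    prof = replace(
        base,
        w_cs_d1=w_d1,
        w_cs_d2=w_d2,
        unsaturated_msn=(0,),
        lam_d1=0.0,
        lam_d2=0.0,
    )
    onsets = np.zeros(nc)
    onsets[0], onsets[1] = 1.0, 2.0
    st = integrate(prof, big_sal, dt_s=0.005, duration_s=3.5, input_onsets=onsets)
    gpi = st.y["gpi"]
    codes = (
        (gpi[:, 0] < base.theta_sel).astype(np.int64)
        + 2 * (gpi[:, 1] < base.theta_sel).astype(np.int64)
    ).reshape(k1, k2, n, n)
    match = 100.0 * np.mean(
        codes == template.labels[None, None, :, :], axis=(2, 3)
    )
    return SweepResult(mode=mode, w_d1=w1s, w_d2=w2s, match=match)


def measure_io_curve(
    sim: MSNSimulation,
    salient_set: np.ndarray,
    levels: np.ndarray | None = None,
    duration_s: float = 2.0,
    background_rate: float = 3.0,
    gaba_rate: float = 3.0,
    max_rate: float = 40.0,
    tonic_dopamine: float = 3.0,
    seed: int = 0,
    n_repeats: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised input-output firing curve of a (trained) spiking MSN.

    Input level x drives the salient set at ``x * max_rate`` spikes/s (the
    rest at background); output is the firing rate over the window divided
    by ``max_rate``.  Plasticity is off during measurement.
    """
    x = np.linspace(0.0, 1.0, 11) if levels is None else np.asarray(levels, dtype=float)
    y = np.zeros_like(x)
    n_exc, n_gaba = sim.syn.n_exc, sim.syn.n_gaba
    for rep in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=[seed, rep, 404]))
        for i, level in enumerate(x):
            rates = np.full(n_exc, background_rate)
            rates[salient_set] = level * max_rate
            counts = rng.poisson(rates * duration_s)
            times = rng.uniform(0, duration_s, int(counts.sum()))
            syn = np.repeat(np.arange(n_exc, dtype=np.int64), counts)
            gc = rng.poisson(np.full(n_gaba, gaba_rate) * duration_s)
            gt = rng.uniform(0, duration_s, int(gc.sum()))
            gs = np.repeat(np.arange(n_gaba, dtype=np.int64), gc)
            # run on a copy of the state so measurements don't perturb it
            sim_v, sim_u = sim.v, sim.u
            n_steps = int(round(duration_s * 1000 / sim.dt_ms))
            steps = np.floor(times * 1000 / sim.dt_ms).astype(np.int64)
            keep = steps < n_steps
            order = np.argsort(steps[keep], kind="stable")
            gsteps = np.floor(gt * 1000 / sim.dt_ms).astype(np.int64)
            gkeep = gsteps < n_steps
            gorder = np.argsort(gsteps[gkeep], kind="stable")
            res = sim.run_segment(
                duration_s,
                (steps[keep][order], syn[keep][order]),
                (gsteps[gkeep][gorder], gs[gkeep][gorder]),
                tonic_dopamine,
                plastic=False,
            )
            y[i] += res.n_spikes / duration_s / max_rate / n_repeats
            sim.v, sim.u = sim_v, sim_u
    return x, y


def fit_rate_equivalent(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Least-squares fit of ``y = max(0, w x - eps)`` to a normalised curve.

    Returns ``(w, eps)``.  A flat all-zero curve yields ``w = 0`` with a
    warning (the unit is unresponsive over the tested range).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-d arrays")
    if np.all(y == 0.0):
        warnings.warn("flat input-output curve; returning w = 0", stacklevel=2)
        return 0.0, 0.0

    def resid(p):
        w, eps = p
        return np.maximum(0.0, w * x - eps) - y

    # initial guess from the active part of the curve
    act = y > 1e-12
    if act.sum() >= 2:
        w0, i0 = np.polyfit(x[act], y[act], 1)
        w0 = max(w0, 1e-3)
        e0 = -i0
    else:
        w0, e0 = 1.0, 0.2
    sol = least_squares(resid, x0=[w0, e0])
    return float(sol.x[0]), float(sol.x[1])


def behavioural_performance(
    d1_unit: tuple[float, float],
    d2_unit: tuple[float, float],
    profile: NetworkProfile | None = None,
    grid: np.ndarray | None = None,
) -> int:
    """Number of salience pairs (out of 100) selecting the key channel.

    The fitted rate-coded D1/D2 units ``(w, eps)`` are embedded in the
    experimental channel (dopamine factors folded into the fitted weights);
    the control channel keeps unit weights.  A pair counts whenever channel
    1 is selected, alone or jointly.
    """
    base = profile if profile is not None else NetworkProfile()
    g = default_salience_grid() if grid is None else np.asarray(grid, dtype=float)
    w1, e1 = d1_unit
    w2, e2 = d2_unit
    prof = replace(
        base,
        w_cs_d1=(w1,) + (1.0,) * (base.n_channels - 1),
        w_cs_d2=(w2,) + (1.0,) * (base.n_channels - 1),
        eps_cs_d1=(e1,) + (base.eps_d1,) * (base.n_channels - 1),
        eps_cs_d2=(e2,) + (base.eps_d2,) * (base.n_channels - 1),
        lam_off=(0,),
    )
    out = run_competitions(prof, g)
    return int(np.sum((out == CH1) | (out == BOTH)))
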