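"""Six-channel rate-coded basal ganglia action-selection network.

Each candidate action occupies a discrete "channel" through every nucleus
(D1 striatum, D2 striatum, STN, GPe, GPi/SNr); each channel in each nucleus
is a leaky-integrator unit

    tau da/dt = -a + u,        y = clip(a - eps, 0, 1)

with a piecewise-linear output and per-nucleus threshold ``eps`` (negative
for STN, GPe and GPi, giving those nuclei tonic output at rest).  The wiring
is the off-centre on-surround selection architecture: cortical salience
excites the D1, D2 and STN populations of its channel; D1 inhibits GPi
channel-wise (the direct, selection pathway); D2 inhibits GPe channel-wise;
STN excites GPe and GPi diffusely; GPe inhibits STN and GPi channel-wise.
Tonic dopamine facilitates cortical efficacy at D1 inputs by ``(1 + lam1)``
and attenuates it at D2 inputs by ``(1 - lam2)``.

An action is read out as selected when its GPi output falls below a small
threshold — a sufficient drop in the output nuclei's tonic inhibition.

Connection weights and thresholds default to the values of the classic
selection-network model this architecture derives from, shipped as the
``"gpr"`` profile; every value can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkProfile",
    "SalienceInput",
    "ChannelState",
    "net_inputs",
    "integrate",
    "selection_readout",
    "OUTCOMES",
]

NUCLEI = ("d1", "d2", "stn", "gpe", "gpi")
OUTCOMES = ("none", "ch1", "ch2", "both")


@dataclass(frozen=True)
class NetworkProfile:
    """Weights, thresholds and dopamine parameters of the rate model."""

    n_channels: int = 6
    tau_ms: float = 25.0
    # per-nucleus output thresholds
    eps_d1: float = 0.2
    eps_d2: float = 0.2
    eps_stn: float = -0.25
    eps_gpe: float = -0.2
    eps_gpi: float = -0.2
    # projection weights (all positive; sign set by the wiring)
    w_stn_gpe: float = 0.9   # diffuse STN -> GPe
    w_stn_gpi: float = 0.9   # diffuse STN -> GPi
    w_gpe_stn: float = 1.0
    w_gpe_gpi: float = 0.5
    w_d2_gpe: float = 0.8
    w_d1_gpi: float = 1.0
    # tonic dopamine efficacy factors at the striatal input
    lam_d1: float = 0.2
    lam_d2: float = 0.2
    # per-channel cortico-striatal input weights ("responsiveness")
    w_cs_d1: tuple = (1.0,) * 6
    w_cs_d2: tuple = (1.0,) * 6
    # per-channel MSN threshold overrides (None -> eps_d1/eps_d2)
    eps_cs_d1: tuple | None = None
    eps_cs_d2: tuple | None = None
    # channels whose MSN outputs are not clipped at 1 (sweep mode)
    unsaturated_msn: tuple = ()
    # channels where the dopamine factors are folded into the weights
    lam_off: tuple = ()
    # selection threshold on GPi output
    theta_sel: float = 0.1

    def channel_array(self, values, default) -> np.ndarray:
        if values is None:
            return np.full(self.n_channels, default)
        return np.asarray(values, dtype=float)


@dataclass
class SalienceInput:
    """Per-channel scalar salience, routed to D1, D2 and STN of that channel."""

    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if np.any(self.c < 0):
            raise ValueError("saliences must be non-negative")


@dataclass
class ChannelState:
    """Activations ``a`` and outputs ``y`` per nucleus; shape (..., n_channels)."""

    a: dict
    y: dict
    converged: bool = True

    @classmethod
    def zeros(cls, profile: NetworkProfile, batch: tuple = ()) -> "ChannelState":
        shape = batch + (profile.n_channels,)
        return cls(
            a={n: np.zeros(shape) for n in NUCLEI},
            y={n: np.zeros(shape) for n in NUCLEI},
        )


def _outputs(profile: NetworkProfile, a: dict) -> dict:
    y = {}
    for n in NUCLEI:
        eps = getattr(profile, f"eps_{n}")
        if n in ("d1", "d2"):
            key = "eps_cs_" + n
            eps_ch = getattr(profile, key)
            eps = profile.channel_array(eps_ch, eps)
        out = a[n] - eps
        np.clip(out, 0.0, None, out=out)
        if n in ("d1", "d2") and profile.unsaturated_msn:
            # unsaturated channels have no upper clip
            mask = np.zeros(profile.n_channels, dtype=bool)
            mask[list(profile.unsaturated_msn)] = True
            out = np.where(mask, out, np.minimum(out, 1.0))
        else:
            np.clip(out, None, 1.0, out=out)
        y[n] = out
    return y


def net_inputs(profile: NetworkProfile, y: dict, saliences: np.ndarray) -> dict:
    """Summed, weighted input per nucleus given current outputs and saliences."""
    c = np.asarray(saliences, dtype=float)
    w1 = np.asarray(profile.w_cs_d1, dtype=float)
    w2 = np.asarray(profile.w_cs_d2, dtype=float)
    lam1 = np.full(profile.n_channels, profile.lam_d1)
    lam2 = np.full(profile.n_channels, profile.lam_d2)
    if profile.lam_off:
        idx = list(profile.lam_off)
        lam1[idx] = 0.0
        lam2[idx] = 0.0
    u = {}
    u["d1"] = c * w1 * (1.0 + lam1)
    u["d2"] = c * w2 * (1.0 - lam2)
    u["stn"] = c - profile.w_gpe_stn * y["gpe"]
    stn_sum = np.sum(y["stn"], axis=-1, keepdims=True)
    u["gpe"] = profile.w_stn_gpe * stn_sum - profile.w_d2_gpe * y["d2"]
    u["gpi"] = (
        profile.w_stn_gpi * stn_sum
        - profile.w_d1_gpi * y["d1"]
        - profile.w_gpe_gpi * y["gpe"]
    )
    return u


def integrate(
    profile: NetworkProfile,
    saliences: np.ndarray,
    dt_s: float = 0.005,
    duration_s: float = 3.0,
    tol: float = 1e-6,
    state: ChannelState | None = None,
    input_onsets: np.ndarray | None = None,
    return_trajectory: bool = False,
):
    """Euler-integrate the network to equilibrium.

    ``saliences`` has shape (..., n_channels): a batch of competitions is
    integrated at once.  ``input_onsets`` (seconds, per channel) gates each
    channel's salience on at the given time (default: all at t = 0).
    Returns the final :class:`ChannelState` (with ``converged`` flagging
    whether ``max |da/dt| < tol`` was reached) and optionally the GPi
    output trajectory.
    """
    tau_s = profile.tau_ms / 1000.0
    if dt_s > tau_s / 2:
        raise ValueError("integration step must satisfy dt <= tau/2")
    c = np.asarray(saliences, dtype=float)
    batch = c.shape[:-1]
    st = state if state is not None else ChannelState.zeros(profile, batch)
    n_steps = int(round(duration_s / dt_s))
    onsets = np.zeros(profile.n_channels) if input_onsets is None else input_onsets
    traj = [] if return_trajectory else None
    max_d = np.inf
    for s in range(n_steps):
        t = s * dt_s
        c_t = np.where(onsets <= t, c, 0.0)
        y = _outputs(profile, st.a)
        u = net_inputs(profile, y, c_t)
        max_d = 0.0
        for n in NUCLEI:
            da = (u[n] - st.a[n]) / tau_s
            st.a[n] = st.a[n] + dt_s * da
            md = float(np.max(np.abs(da)))
            max_d = md if md > max_d else max_d
        if return_trajectory:
            traj.append(_outputs(profile, st.a)["gpi"].copy())
    st.y = _outputs(profile, st.a)
    # convergence: check the equilibrium condition a = u directly
    y = st.y
    u = net_inputs(profile, y, np.where(onsets <= (n_steps - 1) * dt_s, c, 0.0))
    resid = max(float(np.max(np.abs(u[n] - st.a[n]))) for n in NUCLEI)
    st.converged = resid < max(tol, 1e-4)
    if return_trajectory:
        return st, np.array(traj)
    return st


def selection_readout(
    gpi_outputs: np.ndarray,
    theta_sel: float = 0.1,
    driven: tuple[int, int] = (0, 1),
) -> str:
    """Outcome of a two-channel competition from equilibrium GPi outputs.

    A channel is selected iff its GPi output has fallen below ``theta_sel``.
    """
    gpi = np.asarray(gpi_outputs)
    if gpi.ndim != 1:
        raise ValueError("selection_readout takes a single competition's outputs")
    s1 = bool(gpi[driven[0]] < theta_sel)
    s2 = bool(gpi[driven[1]] < theta_sel)
    return OUTCOMES[int(s1) + 2 * int(s2)]
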