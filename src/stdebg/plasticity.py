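"""Three-factor cortico-striatal plasticity: dopamine-modulated STDP and STDE.

The plasticity of a cortico-striatal synapse depends on three factors:

1. the postsynaptic neuron type (D1- or D2-receptor expressing MSN),
2. the striatal dopamine level ``D``,
3. the sign of the pre/post spike-pair timing ``dt = t_post - t_pre``.

At the extremes of the dopamine scale the rule is a pair-based STDP with
exponential kernels ``f(dt) = A * exp(-|dt| / tau)``; a separate amplitude
``A`` exists for each (MSN type, dopamine extreme, timing sign) combination,
eight amplitudes in total (:class:`KernelCoefficients`).  Arbitrary dopamine
levels are handled by linearly blending the high- and low-dopamine
amplitudes with a saturating Naka-Rushton mixing function ``m(D)``
(:func:`mixing_value`); the blended amplitude ``P(D)`` is called a
*plasticity factor* (:func:`blended_amplitude`).

To bridge the gap between the STDP timescale (tens of ms) and the arrival
of reinforcement-locked phasic dopamine (hundreds of ms later), spike pairs
do not change the weight directly.  Each pair deposits a unit-normalised
kernel value into one of two exponentially decaying eligibility traces
(``c+`` for positive timing, ``c-`` for negative timing); the weight then
integrates the product of each trace with the instantaneous plasticity
factor ``P(D(t))``:

    dw/dt = (alpha / tau_e) * [ P+(D(t)) c+(t) + P-(D(t)) c-(t) ]

This is the spike-timing-dependent eligibility (STDE) rule.  The
``alpha/tau_e`` scaling is chosen so that for *constant* dopamine the total
weight change from a single pair, integrated to infinity, is exactly the
STDP change ``alpha * P(D) * exp(-|dt|/tau)`` (the "reduction theorem",
checked to machine precision by the exact piecewise-exponential quadrature
used in :func:`stde_integrate`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping

import numpy as np

__all__ = [
    "MSN_TYPES",
    "DOPA_LEVELS",
    "TIMING_SIGNS",
    "DEFAULT_SIGN_MASK",
    "KernelCoefficients",
    "MixingParams",
    "TimingParams",
    "SpikePair",
    "EligibilityState",
    "kernel_value",
    "mixing_value",
    "blended_amplitude",
    "stdp_weight_change",
    "eligibility_apply_pair",
    "stde_integrate",
    "default_coefficients",
    "default_mixing",
]

MSN_TYPES = ("D1", "D2")
DOPA_LEVELS = ("hi", "lo")
TIMING_SIGNS = ("pos", "neg")

#: Allowed sign per amplitude, as read off the in-vitro induction outcomes:
#: +1 means LTP-only, -1 LTD-only, 0 unconstrained.  Standard STDP (LTP for
#: positive, LTD for negative timing) holds only for D2 MSNs at high
#: dopamine; the two negative-timing entries D1/hi and D2/lo are left free.
DEFAULT_SIGN_MASK: dict[tuple[str, str, str], int] = {
    ("D1", "hi", "pos"): +1,
    ("D1", "hi", "neg"): 0,
    ("D1", "lo", "pos"): -1,
    ("D1", "lo", "neg"): +1,
    ("D2", "hi", "pos"): +1,
    ("D2", "hi", "neg"): -1,
    ("D2", "lo", "pos"): +1,
    ("D2", "lo", "neg"): 0,
}


def _check_key(msn_type: str, dopa: str, sign: str) -> None:
    if msn_type not in MSN_TYPES:
        raise ValueError(f"unknown MSN type {msn_type!r}")
    if dopa not in DOPA_LEVELS:
        raise ValueError(f"unknown dopamine level {dopa!r}")
    if sign not in TIMING_SIGNS:
        raise ValueError(f"unknown timing sign {sign!r}")


@dataclass(frozen=True)
class KernelCoefficients:
    """The eight STDP kernel amplitudes, indexed by (type, dopamine, sign).

    Parameters
    ----------
    a
        Mapping ``(msn_type, dopa, sign) -> amplitude`` with
        ``msn_type in {"D1","D2"}``, ``dopa in {"hi","lo"}``,
        ``sign in {"pos","neg"}``.  All eight entries must be present
        and finite.
    sign_mask
        Optional per-entry allowed sign (+1/-1/0); when given, each
        constrained amplitude must match it (zero amplitudes always pass).
    """

    a: Mapping[tuple[str, str, str], float]
    sign_mask: Mapping[tuple[str, str, str], int] | None = None

    def __post_init__(self) -> None:
        vals = {}
        for t in MSN_TYPES:
            for d in DOPA_LEVELS:
                for s in TIMING_SIGNS:
                    key = (t, d, s)
                    if key not in self.a:
                        raise ValueError(f"missing amplitude for {key}")
                    v = float(self.a[key])
                    if not math.isfinite(v):
                        raise ValueError(f"non-finite amplitude for {key}")
                    vals[key] = v
        object.__setattr__(self, "a", vals)
        if self.sign_mask is not None:
            for key, m in self.sign_mask.items():
                _check_key(*key)
                if m not in (-1, 0, 1):
                    raise ValueError(f"sign mask entry for {key} must be -1, 0 or +1")
                v = vals[key]
                if m != 0 and v != 0.0 and math.copysign(1.0, v) != m:
                    raise ValueError(
                        f"amplitude {v} for {key} violates sign constraint {m:+d}"
                    )

    def amplitude(self, msn_type: str, dopa: str, sign: str) -> float:
        _check_key(msn_type, dopa, sign)
        return self.a[(msn_type, dopa, sign)]

    def satisfies_mask(
        self, mask: Mapping[tuple[str, str, str], int] | None = None
    ) -> bool:
        """True if every constrained amplitude has the mask's sign."""
        mask = DEFAULT_SIGN_MASK if mask is None else mask
        for key, m in mask.items():
            if m == 0:
                continue
            v = self.a[key]
            if v == 0.0 or math.copysign(1.0, v) != m:
                return False
        return True

    # -- flat config representation: keys like "A.D1.hi.pos" ---------------
    def to_flat(self) -> dict[str, float]:
        return {f"A.{t}.{d}.{s}": self.a[(t, d, s)] for (t, d, s) in sorted(self.a)}

    @classmethod
    def from_flat(cls, flat: Mapping[str, float], **kw) -> "KernelCoefficients":
        a = {}
        for key, v in flat.items():
            parts = key.split(".")
            if len(parts) != 4 or parts[0] != "A":
                raise ValueError(f"bad coefficient key {key!r}")
            a[(parts[1], parts[2], parts[3])] = float(v)
        return cls(a=a, **kw)

    def with_values(self, msn_type: str, values: Iterable[float]) -> "KernelCoefficients":
        """Replace the four amplitudes of one MSN type.

        ``values`` is ordered (hi/pos, hi/neg, lo/pos, lo/neg).
        """
        hp, hn, lp, ln = values
        a = dict(self.a)
        a[(msn_type, "hi", "pos")] = hp
        a[(msn_type, "hi", "neg")] = hn
        a[(msn_type, "lo", "pos")] = lp
        a[(msn_type, "lo", "neg")] = ln
        return KernelCoefficients(a=a, sign_mask=self.sign_mask)


@dataclass(frozen=True)
class MixingParams:
    """Naka-Rushton mixing function parameters, one instance per MSN type.

    ``m(D) = M * D**n / (D**n + theta**n)`` — a rapidly increasing then
    saturating monotone function of the dopamine level.  ``M`` may exceed 1
    (D1 default M=1.2), in which case the blend extrapolates beyond the
    high-dopamine amplitude by design.
    """

    n: float = 1.2
    theta: float = 6.0
    m_max: float = 1.2

    def __post_init__(self) -> None:
        if not (self.n > 0 and self.theta > 0 and self.m_max > 0):
            raise ValueError("MixingParams require n > 0, theta > 0, m_max > 0")


def default_mixing() -> dict[str, MixingParams]:
    """Per-type mixing defaults (D1: n=1.2, theta=6.0, M=1.2; D2: n=1.4, theta=1.8, M=1.0)."""
    return {
        "D1": MixingParams(n=1.2, theta=6.0, m_max=1.2),
        "D2": MixingParams(n=1.4, theta=1.8, m_max=1.0),
    }


@dataclass(frozen=True)
class TimingParams:
    """Kernel and eligibility time constants (seconds) and learning rate."""

    tau_plus: float = 0.02
    tau_minus: float = 0.02
    tau_e: float = 0.3
    alpha: float = 0.65

    def __post_init__(self) -> None:
        if min(self.tau_plus, self.tau_minus, self.tau_e) <= 0 or self.alpha < 0:
            raise ValueError("time constants must be positive, alpha non-negative")
        if self.tau_e <= max(self.tau_plus, self.tau_minus):
            raise ValueError(
                "eligibility constant tau_e must exceed the kernel constants "
                "(it bridges the pairing event to the delayed dopamine signal)"
            )

    def tau_for(self, sign: str) -> float:
        return self.tau_plus if sign == "pos" else self.tau_minus


@dataclass(frozen=True)
class SpikePair:
    """A pre/post spike pair; ``dt = t_post - t_pre`` in seconds, never 0."""

    dt: float

    def __post_init__(self) -> None:
        if self.dt == 0.0:
            raise ValueError(
                "coincident pair (dt = 0) is undefined at the kernel discontinuity"
            )

    @property
    def sign(self) -> str:
        return "pos" if self.dt > 0 else "neg"


@dataclass
class EligibilityState:
    """Per-synapse pair of eligibility traces and their last update time."""

    c_pos: float = 0.0
    c_neg: float = 0.0
    last_update: float = 0.0

    def decayed_to(self, t: float, timing: TimingParams) -> "EligibilityState":
        """Return the state freely decayed to time ``t`` (t >= last_update)."""
        if t < self.last_update:
            raise ValueError("cannot decay eligibility backwards in time")
        f = math.exp(-(t - self.last_update) / timing.tau_e)
        return EligibilityState(self.c_pos * f, self.c_neg * f, t)


def kernel_value(dt: float, tau: float, amplitude: float) -> float:
    """STDP kernel ``A * exp(-|dt| / tau)``; rejects the dt = 0 discontinuity."""
    if tau <= 0:
        raise ValueError("kernel time constant must be positive")
    if dt == 0.0:
        raise ValueError("kernel undefined at dt = 0")
    return amplitude * math.exp(-abs(dt) / tau)


def mixing_value(dopamine, params: MixingParams):
    """Naka-Rushton mixing weight ``m(D)``; accepts scalars or arrays, D >= 0."""
    d = np.asarray(dopamine, dtype=float)
    if np.any(d < 0):
        raise ValueError("dopamine level must be non-negative")
    dn = np.power(d, params.n)
    out = params.m_max * dn / (dn + params.theta**params.n)
    return float(out) if np.isscalar(dopamine) or out.ndim == 0 else out


def blended_amplitude(
    msn_type: str,
    sign: str,
    dopamine,
    coeffs: KernelCoefficients,
    mixing: Mapping[str, MixingParams],
):
    """Plasticity factor ``P(D) = m(D) A_hi + (1 - m(D)) A_lo``.

    Continuous and monotone in ``D`` between the two extreme amplitudes
    (extrapolating beyond ``A_hi`` where the mixing maximum exceeds 1).
    Accepts scalar or array dopamine.
    """
    _check_key(msn_type, "hi", sign)
    m = mixing_value(dopamine, mixing[msn_type])
    a_hi = coeffs.amplitude(msn_type, "hi", sign)
    a_lo = coeffs.amplitude(msn_type, "lo", sign)
    return m * a_hi + (1.0 - m) * a_lo


def stdp_weight_change(
    pair: SpikePair,
    dopamine: float,
    msn_type: str,
    coeffs: KernelCoefficients,
    mixing: Mapping[str, MixingParams],
    timing: TimingParams,
) -> float:
    """Weight change for a single pair at constant dopamine (pure STDP).

    ``dw = alpha * P_sign(D) * exp(-|dt| / tau_sign)``; equal to the STDE
    rule integrated to infinity at the same constant dopamine level.
    """
    p = blended_amplitude(msn_type, pair.sign, dopamine, coeffs, mixing)
    return timing.alpha * p * math.exp(-abs(pair.dt) / timing.tau_for(pair.sign))


def eligibility_apply_pair(
    state: EligibilityState, pair: SpikePair, timing: TimingParams, t: float | None = None
) -> EligibilityState:
    """Deposit a pair's unit-normalised kernel value into the matching trace.

    The trace carries only the timing factor ``exp(-|dt|/tau)``; the
    dopamine-dependent amplitude enters later through ``P(D(t))`` during
    integration.  Contributions from multiple pairs add linearly.
    """
    if t is None:
        t = state.last_update
    st = state.decayed_to(t, timing)
    step = math.exp(-abs(pair.dt) / timing.tau_for(pair.sign))
    if pair.sign == "pos":
        st.c_pos += step
    else:
        st.c_neg += step
    return st


def stde_integrate(
    state: EligibilityState,
    d_trace: Callable[[np.ndarray], np.ndarray],
    window: tuple[float, float],
    msn_type: str,
    coeffs: KernelCoefficients,
    mixing: Mapping[str, MixingParams],
    timing: TimingParams,
    step: float = 1e-3,
    domain: tuple[float, float] | None = None,
) -> float:
    """Integrate the STDE rule over ``window`` for freely decaying traces.

    ``dw = (alpha/tau_e) * Int[ P+(D(t)) c+(t) + P-(D(t)) c-(t) ] dt``.

    ``d_trace`` is any callable mapping an array of times to dopamine
    levels; it is sampled once per quadrature step and treated as
    piecewise-constant.  The trace decay inside each step is integrated
    exactly (piecewise-exponential quadrature), so for constant dopamine
    the result reduces to :func:`stdp_weight_change` to machine precision
    as the window grows.
    """
    t0, t1 = window
    if t1 < t0:
        raise ValueError("empty integration window")
    if domain is not None and (t0 < domain[0] or t1 > domain[1]):
        raise ValueError("integration window outside the dopamine trace domain")
    if t0 < state.last_update:
        raise ValueError("window starts before the eligibility state's time")
    st = state.decayed_to(t0, timing)
    if st.c_pos == 0.0 and st.c_neg == 0.0:
        return 0.0
    n = max(1, int(math.ceil((t1 - t0) / step)))
    edges = np.linspace(t0, t1, n + 1)
    mid_d = np.asarray(d_trace(edges[:-1]), dtype=float)
    p_pos = blended_amplitude(msn_type, "pos", mid_d, coeffs, mixing)
    p_neg = blended_amplitude(msn_type, "neg", mid_d, coeffs, mixing)
    # Exact integral of exp(-(t - t0)/tau_e) over each step, times P there.
    decay_edges = np.exp(-(edges - t0) / timing.tau_e)
    seg = timing.tau_e * (decay_edges[:-1] - decay_edges[1:])
    total = st.c_pos * float(np.dot(p_pos, seg)) + st.c_neg * float(np.dot(p_neg, seg))
    return (timing.alpha / timing.tau_e) * total


# ---------------------------------------------------------------------------
# Shipped default coefficients.
#
# The four amplitudes per MSN type are the model's free parameters; the
# shipped values are a well-scoring set from the coefficient search
# (search.run_search) under the default sign mask, satisfying (i) the
# in-vitro sign pattern, (ii) near-zero net drift at tonic dopamine, and
# (iii) the target activity profiles over the operant experiment.
# ---------------------------------------------------------------------------

DEFAULT_COEFFICIENT_VALUES = {
    "A.D1.hi.pos": 0.7,
    "A.D1.hi.neg": -0.2602,
    "A.D1.lo.pos": -0.3928,
    "A.D1.lo.neg": 0.14,
    "A.D2.hi.pos": 0.026,
    "A.D2.hi.neg": -0.0616,
    "A.D2.lo.pos": 0.065,
    "A.D2.lo.neg": -0.016,
}


def default_coefficients(enforce_mask: bool = True) -> KernelCoefficients:
    """The shipped coefficient set (see module docstring and docs/methods.md)."""
    return KernelCoefficients.from_flat(
        DEFAULT_COEFFICIENT_VALUES,
        sign_mask=DEFAULT_SIGN_MASK if enforce_mask else None,
    )
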