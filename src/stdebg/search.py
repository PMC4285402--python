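"""Exhaustive lattice search over the plasticity coefficients.

The four kernel amplitudes of one MSN type span a 4-D box, discretised
into a regular lattice (five points per axis, 625 points, in the full
configuration), optionally augmented with explicit candidate sets.  Each
lattice point is evaluated by running a reduced-epoch operant experiment
(three seeded repeats), smoothing the ensemble-mean spike-count profile
over a three-trial window, and scoring its match to the target profile
shape with a feature-based metric:

* baseline flatness — squared difference between the means of the first
  and last five baseline trials;
* learning rise — squared shortfall of the learning-epoch rise below a
  configured minimum;
* intermission stability — squared drift between the start and end of
  the intermission beyond a tolerance (the level shift at the
  learning/intermission boundary is a property of the task — the salient
  subset is redrawn each trial — and is not penalised);
* extinction direction — squared shortfall of the within-epoch extinction
  change in the type-appropriate direction (down for D1, up for D2);
* post-extinction flatness — as baseline.

The total score is a weighted sum (lower is better; zero only when every
feature meets its target).  A second, focused search spans the bounding
box of the first stage's best sets.  "Accepted" sets are those whose every
feature passes a hard threshold, mimicking the final visual-inspection
step of profile selection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .experiment import (
    EPOCHS,
    ScheduleConfig,
    run_experiment,
    summarize_profiles,
)
from .plasticity import (
    DEFAULT_SIGN_MASK,
    KernelCoefficients,
    MixingParams,
    blended_amplitude,
    default_coefficients,
    default_mixing,
)

__all__ = [
    "LatticeSpec",
    "ProfileTargets",
    "ProfileScore",
    "SearchResult",
    "REDUCED_TRIALS",
    "build_lattice",
    "score_profile",
    "run_search",
    "aggregate_summaries",
]

#: reduced per-epoch trial counts used during the search
REDUCED_TRIALS = {"D1": (15, 30, 30, 20, 15), "D2": (15, 40, 30, 20, 15)}

#: coefficient axis order within a lattice point
AXES = ("hi.pos", "hi.neg", "lo.pos", "lo.neg")


@dataclass(frozen=True)
class LatticeSpec:
    """Per-axis intervals and resolution of one MSN type's search lattice."""

    intervals: tuple = ((-1.0, 1.0),) * 4  # (hi+, hi-, lo+, lo-)
    points_per_axis: int = 5
    augmentation: tuple = ()  # explicit 4-tuples to append

    def __post_init__(self) -> None:
        if len(self.intervals) != 4:
            raise ValueError("need one interval per coefficient axis")
        for lo, hi in self.intervals:
            if hi < lo:
                raise ValueError("empty lattice interval")

    @property
    def size(self) -> int:
        return self.points_per_axis ** 4 + len(self.augmentation)


def build_lattice(spec: LatticeSpec) -> list[tuple[float, float, float, float]]:
    """Cartesian-product lattice in deterministic order, augmentation appended."""
    axes = [
        np.linspace(lo, hi, spec.points_per_axis) for lo, hi in spec.intervals
    ]
    points = [tuple(float(v) for v in p) for p in itertools.product(*axes)]
    points.extend(tuple(map(float, a)) for a in spec.augmentation)
    return points


@dataclass(frozen=True)
class ProfileTargets:
    """Feature targets for one MSN type's spike-count profile.

    The targets encode the shape of the required response profile: flat
    baseline, a rise across learning (marked for D1, slight for D2),
    stability through the intermission, a change across extinction in the
    type's direction (down for D1, up for D2), and a flat post-extinction
    epoch.  Epoch-boundary level shifts (e.g. the drop from the end of
    learning into the intermission, where the salient subset is redrawn
    every trial) are properties of the task, not of the profile, and are
    deliberately not penalised.
    """

    min_learning_rise: float = 3.0      # spikes/trial
    min_extinction_change: float = 2.0  # spikes/trial, in the type's direction
    extinction_sign: float = -1.0       # -1: down (D1), +1: up (D2)
    flatness_tolerance: float = 2.0     # spikes/trial allowed drift within flat epochs
    stability_tolerance: float = 3.0    # spikes/trial allowed drift within intermission
    weights: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)

    @classmethod
    def for_type(cls, msn_type: str) -> "ProfileTargets":
        if msn_type == "D1":
            return cls(extinction_sign=-1.0, min_learning_rise=3.0,
                       min_extinction_change=2.0)
        # the D2 learning-epoch rise is slight (a fraction of a spike per
        # trial) and sits within the noise of a three-repeat search run, so
        # the feature only rejects profiles that decline over learning
        return cls(extinction_sign=+1.0, min_learning_rise=-1.0,
                   min_extinction_change=0.25)


@dataclass
class ProfileScore:
    components: dict  # feature name -> non-negative error
    total: float
    passed: bool      # every component within its hard threshold


def _epoch_windows(profile: np.ndarray, epoch: np.ndarray, width: int = 5):
    win = {}
    for e, name in enumerate(EPOCHS):
        idx = np.flatnonzero(epoch == e)
        if len(idx) == 0:
            continue
        k = min(width, len(idx))
        win[name] = (float(profile[idx[:k]].mean()), float(profile[idx[-k:]].mean()))
    return win


def score_profile(
    smoothed_profile: np.ndarray,
    epoch: np.ndarray,
    targets: ProfileTargets,
) -> ProfileScore:
    """Feature-based score of a smoothed ensemble-mean spike-count profile."""
    w = _epoch_windows(smoothed_profile, epoch)
    comp = {}
    # flat epochs: squared drift beyond the tolerance
    for name, key in (("baseline", "baseline"), ("post_extinction", "post_extinction")):
        first, last = w[key]
        drift = abs(last - first)
        comp[name + "_flat"] = max(0.0, drift - targets.flatness_tolerance) ** 2
    lf, ll = w["learning"]
    rise = ll - lf
    comp["learning_rise"] = max(0.0, targets.min_learning_rise - rise) ** 2
    inter_first, inter_last = w["intermission"]
    drift = abs(inter_last - inter_first)
    comp["intermission_stability"] = max(0.0, drift - targets.stability_tolerance) ** 2
    ef, el = w["extinction"]
    change = (el - ef) * targets.extinction_sign
    comp["extinction_change"] = max(0.0, targets.min_extinction_change - change) ** 2
    total = float(np.dot(targets.weights, list(comp.values())))
    passed = all(v == 0.0 for v in comp.values())
    return ProfileScore(components=comp, total=total, passed=passed)


@dataclass
class SearchResult:
    msn_type: str
    points: list          # coefficient 4-tuples, stage-2 (or stage-1 if single stage)
    scores: list          # ProfileScore per point, same order
    ranking: np.ndarray   # indices sorted by ascending total score
    accepted: list        # coefficient 4-tuples passing every hard threshold
    stage1_points: list | None = None
    stage1_totals: np.ndarray | None = None

    def best(self) -> tuple[float, float, float, float]:
        return self.points[int(self.ranking[0])]

    def coefficients(self, point) -> KernelCoefficients:
        co = default_coefficients(enforce_mask=False)
        return co.with_values(self.msn_type, point)


def run_search(
    msn_type: str,
    stage1: LatticeSpec | None = None,
    n_repeats: int = 3,
    seed: int = 0,
    targets: ProfileTargets | None = None,
    two_stage: bool = True,
    stage2_points: int = 5,
    stage2_top: int = 5,
    stage2_expand: float = 0.1,
    window: int = 3,
    trials: tuple | None = None,
    progress: bool = False,
) -> SearchResult:
    """Exhaustive (optionally two-stage) search for one MSN type.

    Every lattice point is scored with ``n_repeats`` seeded repeats of the
    reduced-epoch experiment; stage 2 spans the bounding box of the best
    stage-1 sets, expanded by ``stage2_expand`` per side.  Deterministic
    given ``seed``.
    """
    spec = stage1 if stage1 is not None else LatticeSpec()
    tg = targets if targets is not None else ProfileTargets.for_type(msn_type)
    tr = trials if trials is not None else REDUCED_TRIALS[msn_type]
    cfg = ScheduleConfig(trials=tr)

    def evaluate(points):
        scores = []
        for i, pt in enumerate(points):
            co = default_coefficients(enforce_mask=False).with_values(msn_type, pt)
            profs = run_experiment(
                msn_type, n_repeats=n_repeats, seed=seed, coeffs=co,
                schedule_config=cfg,
            )
            sc, _ = summarize_profiles(profs, window=window)
            scores.append(score_profile(sc, profs[0].epoch, tg))
            if progress and (i + 1) % 25 == 0:
                print(f"  scored {i + 1}/{len(points)}", flush=True)
        return scores

    pts1 = build_lattice(spec)
    sc1 = evaluate(pts1)
    totals1 = np.array([s.total for s in sc1])
    order1 = np.argsort(totals1, kind="stable")

    if not two_stage:
        accepted = [pts1[i] for i in range(len(pts1)) if sc1[i].passed]
        return SearchResult(
            msn_type=msn_type, points=pts1, scores=sc1, ranking=order1,
            accepted=accepted,
        )

    top = [pts1[i] for i in order1[:stage2_top]]
    arr = np.array(top)
    lo, hi = arr.min(axis=0), arr.max(axis=0)
    span = np.maximum(hi - lo, 1e-3)
    lo2, hi2 = lo - stage2_expand * span, hi + stage2_expand * span
    spec2 = LatticeSpec(
        intervals=tuple((float(a), float(b)) for a, b in zip(lo2, hi2)),
        points_per_axis=stage2_points,
        augmentation=tuple(top),
    )
    pts2 = build_lattice(spec2)
    sc2 = evaluate(pts2)
    totals2 = np.array([s.total for s in sc2])
    order2 = np.argsort(totals2, kind="stable")
    accepted = [pts2[i] for i in range(len(pts2)) if sc2[i].passed]
    return SearchResult(
        msn_type=msn_type, points=pts2, scores=sc2, ranking=order2,
        accepted=accepted, stage1_points=pts1, stage1_totals=totals1,
    )


def aggregate_summaries(
    found_sets: Mapping[str, Sequence],
    d_grid: np.ndarray | None = None,
    dt_grid: np.ndarray | None = None,
    mixing: Mapping[str, MixingParams] | None = None,
) -> dict:
    """Kernel envelopes, amplitude sums and overall-weight-change curves.

    ``found_sets`` maps MSN type to a sequence of coefficient 4-tuples
    (hi+, hi-, lo+, lo-).  Returns, per type: min/mean/max kernel envelopes
    per (dopamine, sign) condition over ``dt_grid``; the LTP/LTD balance
    ``A+ + A-`` per (type, dopamine); and the expected overall weight
    change ``sum_sign P_sign(D)`` over ``d_grid`` (mean and range per type,
    plus the sum over types).
    """
    mix = mixing if mixing is not None else default_mixing()
    d = np.linspace(0.0, 12.0, 49) if d_grid is None else np.asarray(d_grid)
    dts = (
        np.linspace(0.001, 0.1, 50) if dt_grid is None else np.asarray(dt_grid)
    )
    out: dict = {"d_grid": d, "dt_grid": dts, "types": {}}
    total_mean = np.zeros_like(d)
    total_lo = np.zeros_like(d)
    total_hi = np.zeros_like(d)
    for msn_type, sets in found_sets.items():
        if len(sets) == 0:
            raise ValueError(f"no coefficient sets for {msn_type}")
        arr = np.array(sets)  # (n, 4) in AXES order
        env = {}
        kern = np.exp(-dts / 0.02)
        for k, name in enumerate(AXES):
            vals = arr[:, k][:, None] * kern[None, :]
            env[name] = {
                "min": vals.min(axis=0),
                "mean": vals.mean(axis=0),
                "max": vals.max(axis=0),
            }
        sums = {
            "hi": arr[:, 0] + arr[:, 1],
            "lo": arr[:, 2] + arr[:, 3],
        }
        curves = []
        for hp, hn, lp, ln in arr:
            co = default_coefficients(enforce_mask=False).with_values(
                msn_type, (hp, hn, lp, ln)
            )
            p = blended_amplitude(msn_type, "pos", d, co, mix) + blended_amplitude(
                msn_type, "neg", d, co, mix
            )
            curves.append(p)
        curves = np.array(curves)
        out["types"][msn_type] = {
            "envelopes": env,
            "amplitude_sums": sums,
            "overall_change": {
                "mean": curves.mean(axis=0),
                "min": curves.min(axis=0),
                "max": curves.max(axis=0),
            },
        }
        total_mean += curves.mean(axis=0)
        total_lo += curves.min(axis=0)
        total_hi += curves.max(axis=0)
    out["combined_overall_change"] = {
        "mean": total_mean,
        "min": total_lo,
        "max": total_hi,
    }
    return out
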