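"""Tests of the coefficient lattice search and its scoring metric."""

import numpy as np
import pytest

from stdebg.experiment import EPOCHS
from stdebg.search import (
    LatticeSpec,
    ProfileTargets,
    aggregate_summaries,
    build_lattice,
    run_search,
    score_profile,
)


class TestLattice:
    def test_default_size_625(self):
        assert LatticeSpec().size == 625
        assert len(build_lattice(LatticeSpec())) == 625

    def test_two_points_per_axis(self):
        spec = LatticeSpec(points_per_axis=2)
        assert len(build_lattice(spec)) == 16

    def test_augmentation_appended(self):
        spec = LatticeSpec(points_per_axis=2, augmentation=((0.1, -0.1, 0.2, -0.2),))
        pts = build_lattice(spec)
        assert len(pts) == 17
        assert pts[-1] == (0.1, -0.1, 0.2, -0.2)

    def test_deterministic_order(self):
        assert build_lattice(LatticeSpec()) == build_lattice(LatticeSpec())

    def test_rejects_bad_interval(self):
        with pytest.raises(ValueError):
            LatticeSpec(intervals=((1.0, -1.0),) * 4)


def _target_profile(epoch, targets):
    """Synthetic spike-count profile exactly matching every feature target."""
    prof = np.zeros(len(epoch))
    base = 5.0
    prof[epoch == 0] = base
    learn = np.flatnonzero(epoch == 1)
    prof[learn] = np.linspace(base, base + targets.min_learning_rise + 2, len(learn))
    top = prof[learn[-1]]
    prof[epoch == 2] = top
    ext = np.flatnonzero(epoch == 3)
    end = top + targets.extinction_sign * (targets.min_extinction_change + 2)
    prof[ext] = np.linspace(top, end, len(ext))
    prof[epoch == 4] = end
    return prof


class TestScoreProfile:
    @pytest.fixture
    def epoch(self):
        return np.repeat(np.arange(5), (15, 30, 30, 20, 15))

    def test_target_profile_scores_zero(self, epoch):
        tg = ProfileTargets.for_type("D1")
        score = score_profile(_target_profile(epoch, tg), epoch, tg)
        assert score.total == 0.0
        assert score.passed

    def test_flat_zero_profile_scores_worse(self, epoch):
        tg = ProfileTargets.for_type("D1")
        flat = score_profile(np.zeros(len(epoch)), epoch, tg)
        shaped = score_profile(_target_profile(epoch, tg), epoch, tg)
        assert flat.total > shaped.total
        assert not flat.passed

    def test_single_feature_perturbation_isolated(self, epoch):
        """Suppressing only the learning rise leaves exactly one component.

        Oracle: a profile flat through learning misses the minimum rise R
        entirely, so the component equals R^2 and the total equals its
        weight times R^2.
        """
        tg = ProfileTargets.for_type("D1")
        prof = _target_profile(epoch, tg)
        learn = np.flatnonzero(epoch == 1)
        prof[learn] = prof[learn[0]]
        # keep later epochs consistent with the (now flat) learning level
        top = prof[learn[-1]]
        prof[epoch == 2] = top
        ext = np.flatnonzero(epoch == 3)
        end = top - (tg.min_extinction_change + 2)
        prof[ext] = np.linspace(top, end, len(ext))
        prof[epoch == 4] = end
        score = score_profile(prof, epoch, tg)
        expected = tg.min_learning_rise ** 2
        assert score.components["learning_rise"] == pytest.approx(expected)
        others = [v for k, v in score.components.items() if k != "learning_rise"]
        assert all(v == 0.0 for v in others)
        assert score.total == pytest.approx(tg.weights[0] * 0 + expected)

    def test_extinction_direction_is_type_specific(self, epoch):
        tg1 = ProfileTargets.for_type("D1")
        tg2 = ProfileTargets.for_type("D2")
        prof = _target_profile(epoch, tg1)  # extinction goes down
        assert score_profile(prof, epoch, tg1).passed
        assert not score_profile(prof, epoch, tg2).passed


class TestRunSearchSmall:
    def test_tiny_search_deterministic_and_ranked(self):
        spec = LatticeSpec(
            intervals=((0.0, 0.7), (-0.3, 0.0), (-0.4, 0.0), (0.0, 0.2)),
            points_per_axis=2,
        )
        tiny = (4, 6, 5, 5, 4)
        res1 = run_search("D1", stage1=spec, n_repeats=2, seed=3, two_stage=False,
                          trials=tiny)
        res2 = run_search("D1", stage1=spec, n_repeats=2, seed=3, two_stage=False,
                          trials=tiny)
        assert np.array_equal(res1.ranking, res2.ranking)
        totals = [res1.scores[i].total for i in res1.ranking]
        assert totals == sorted(totals)


class TestAggregates:
    def test_single_set_envelope_collapses(self):
        sets = {"D1": [(0.7, -0.26, -0.39, 0.14)]}
        agg = aggregate_summaries(sets)
        env = agg["types"]["D1"]["envelopes"]["hi.pos"]
        assert np.allclose(env["min"], env["max"])
        assert np.allclose(env["mean"], 0.7 * np.exp(-agg["dt_grid"] / 0.02))

    def test_amplitude_sums(self):
        sets = {
            "D1": [(0.7, -0.26, -0.39, 0.14), (0.5, -0.1, -0.3, 0.1)],
        }
        agg = aggregate_summaries(sets)
        sums = agg["types"]["D1"]["amplitude_sums"]
        assert np.allclose(sums["hi"], [0.44, 0.4])
        assert np.allclose(sums["lo"], [-0.25, -0.2])

    def test_combined_curve_is_sum_of_types(self):
        sets = {
            "D1": [(0.7, -0.26, -0.39, 0.14)],
            "D2": [(0.026, -0.06, 0.065, -0.016)],
        }
        agg = aggregate_summaries(sets)
        total = agg["combined_overall_change"]["mean"]
        parts = (
            agg["types"]["D1"]["overall_change"]["mean"]
            + agg["types"]["D2"]["overall_change"]["mean"]
        )
        assert np.allclose(total, parts)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            aggregate_summaries({"D1": []})
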