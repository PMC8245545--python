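"""Cooperative decision rules: voting, percentage limit, trustiness, confusion."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import erythroflow as ef
from erythroflow.classify import ScoredPrediction


def _pred(label, scores, video="v0", roi="r"):
    return ScoredPrediction(roi_id=roi, video_id=video, label=label,
                            scores=np.asarray(scores, dtype=float))


def _two_class(labels, video="v0"):
    return [_pred(l, (1 - l * 0.8 - 0.1, l * 0.8 + 0.1), video, f"r{i}")
            for i, l in enumerate(labels)]


class TestMajority:
    def test_modal_label_wins(self):
        d = ef.majority_vote(_two_class([1, 1, 0]))
        assert d.decided_class == 1
        assert d.evidence == {0: 1, 1: 2}
        assert d.n_rois == 3

    def test_vote_tie_broken_by_total_score(self):
        preds = [_pred(0, (0.55, 0.45), roi="a"), _pred(1, (0.25, 0.75), roi="b")]
        # votes tied 1-1; score sums (0.8, 1.2) favour class 1
        assert ef.majority_vote(preds).decided_class == 1

    def test_full_tie_goes_to_lowest_class(self):
        preds = [_pred(0, (0.6, 0.4)), _pred(1, (0.4, 0.6))]
        assert ef.majority_vote(preds).decided_class == 0

    def test_empty_video_is_decision_error(self):
        with pytest.raises(ef.DecisionError):
            ef.majority_vote([])


class TestPercentageLimit:
    def test_just_above_limit_flags_unhealthy(self):
        d = ef.percentage_limit(_two_class([1] * 31 + [0] * 69), limit=0.30)
        assert d.decided_class == 1
        assert d.evidence == {0: 69, 1: 31}

    def test_exactly_at_limit_stays_healthy(self):
        # strict exceedance: 30 of 100 at the 30% limit is not enough
        d = ef.percentage_limit(_two_class([1] * 30 + [0] * 70), limit=0.30)
        assert d.decided_class == 0

    def test_no_unhealthy_rois_is_healthy_at_any_limit(self):
        for limit in (0.05, 0.3, 0.9):
            assert ef.percentage_limit(_two_class([0] * 10),
                                       limit=limit).decided_class == 0

    def test_four_class_input_rejected(self):
        preds = [_pred(2, (0.1, 0.2, 0.6, 0.1))]
        with pytest.raises(ef.DecisionError):
            ef.percentage_limit(preds, limit=0.3)

    def test_degenerate_limit_rejected(self):
        with pytest.raises(ef.DecisionError):
            ef.percentage_limit(_two_class([0]), limit=1.0)


class TestMaxTrustiness:
    def test_single_roi(self):
        d = ef.max_trustiness([_pred(0, (0.7, 0.1, 0.1, 0.1))])
        assert d.decided_class == 0
        assert d.normalized_score == pytest.approx(0.7)

    def test_hand_summed_two_rois(self):
        preds = [_pred(0, (0.6, 0.4, 0, 0)), _pred(1, (0.3, 0.7, 0, 0))]
        d = ef.max_trustiness(preds)
        assert d.decided_class == 1  # sums (0.9, 1.1, 0, 0)
        assert d.evidence[1] == pytest.approx(1.1)
        assert d.normalized_score == pytest.approx(0.55)

    def test_uniform_scores_tie_to_class_zero(self):
        preds = [_pred(0, (0.25,) * 4) for _ in range(3)]
        d = ef.max_trustiness(preds)
        assert d.decided_class == 0
        assert d.normalized_score == pytest.approx(0.25)

    def test_invariant_to_roi_ordering(self):
        rng = np.random.default_rng(0)
        scores = rng.dirichlet(np.ones(4), size=25)
        preds = [_pred(int(s.argmax()), s, roi=f"r{i}")
                 for i, s in enumerate(scores)]
        d1 = ef.max_trustiness(preds)
        d2 = ef.max_trustiness([preds[i] for i in rng.permutation(25)])
        assert d1.decided_class == d2.decided_class
        assert d1.normalized_score == pytest.approx(d2.normalized_score)

    def test_score_sums_total_roi_count(self):
        rng = np.random.default_rng(1)
        preds = [_pred(0, s) for s in rng.dirichlet(np.ones(4), size=12)]
        d = ef.max_trustiness(preds)
        assert sum(d.evidence.values()) == pytest.approx(d.n_rois)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(labels=st.lists(st.integers(0, 1), min_size=1, max_size=60))
def test_majority_agrees_with_half_limit_except_exact_ties(labels):
    """For two classes, majority voting and a 50% limit coincide whenever the
    vote is not exactly tied (brute-force oracle)."""
    preds = _two_class(labels)
    counts = Counter(labels)
    maj = ef.majority_vote(preds).decided_class
    lim = ef.percentage_limit(preds, limit=0.5).decided_class
    if counts[0] != counts[1]:
        assert maj == lim == (1 if counts[1] > counts[0] else 0)
    else:
        assert lim == 0  # strict exceedance never flags an exact tie


class TestConfusionAndEfficiency:
    def _decisions(self, assignments):
        return [ef.majority_vote(_two_class([c] * 3, video=v))
                for v, c in assignments.items()]

    def test_all_correct_is_diagonal(self):
        truth = {"a": 0, "b": 1, "c": 1}
        conf = ef.build_confusion(self._decisions(truth), truth, [0, 1])
        assert conf.tolist() == [[1, 0], [0, 2]]
        assert ef.efficiency(conf) == 1.0
        assert ef.efficiency_percent(conf) == 100

    def test_brute_force_recount_on_random_cohort(self):
        rng = np.random.default_rng(2)
        truth = {f"v{i}": int(rng.integers(0, 2)) for i in range(40)}
        decided = {v: int(rng.integers(0, 2)) for v in truth}
        conf = ef.build_confusion(self._decisions(decided), truth, [0, 1])
        for t in (0, 1):
            for d in (0, 1):
                expected = sum(1 for v in truth
                               if truth[v] == t and decided[v] == d)
                assert conf[t, d] == expected

    def test_missing_truth_names_video(self):
        with pytest.raises(ef.DecisionError, match="v_mystery"):
            ef.build_confusion(
                [ef.majority_vote(_two_class([1], video="v_mystery"))],
                {"other": 1}, [0, 1])

    def test_empty_matrix_is_error(self):
        with pytest.raises(ef.DecisionError):
            ef.efficiency(np.zeros((2, 2), dtype=int))


def test_score_profile_pairs_per_video():
    preds = ([_pred(0, (0.8, 0.1, 0.05, 0.05), video="a", roi=f"a{i}")
              for i in range(4)]
             + [_pred(3, (0.1, 0.1, 0.2, 0.6), video="b", roi=f"b{i}")
                for i in range(2)])
    decisions, _ = ef.decide_videos(preds, "max_trustiness")
    profile = ef.score_profile(decisions, {"a": 0, "b": 3})
    assert len(profile) == 2
    a = profile.set_index("video_id").loc["a"]
    assert a["assigned"] == 0
    assert a["score"] == pytest.approx(0.8)
    assert (profile["score"] <= 1.0).all()
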