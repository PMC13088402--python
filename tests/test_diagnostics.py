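import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hvsi.diagnostics import (
    ConfusionCounts,
    accuracy_metrics,
    association,
    classify,
    concordance,
    confusion,
    roc,
    round_percent,
    youden_cutoff,
)
from tests._oracles import auc_pair_count, ols_closed_form


def frame_from_scores(pos_scores, neg_scores):
    """Cohort frame where reference-positive rows get flow_volume < 400."""
    scores = list(pos_scores) + list(neg_scores)
    fv = [300.0] * len(pos_scores) + [800.0] * len(neg_scores)
    return pd.DataFrame(
        {"hvsi": scores, "flow_volume": fv, "resistance_index": 0.5, "group": "control"}
    )


class TestClassify:
    def test_below_cutoff_positive(self):
        assert classify(61, 121) == "positive"

    def test_above_cutoff_negative(self):
        assert classify(122, 121) == "negative"

    def test_boundary_is_positive(self):
        assert classify(121, 121) == "positive"


class TestConfusion:
    def test_verification20_counts(self, verification20):
        c = confusion(verification20, 121, "fv<400")
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 16)

    def test_all_negative_unflagged(self):
        f = frame_from_scores([], [500, 600, 700])
        c = confusion(f, 121, "fv<400")
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 3)

    def test_perfect_separation_no_errors(self):
        f = frame_from_scores([50, 60], [500, 600])
        c = confusion(f, 100, "fv<400")
        assert c.fp == c.fn == 0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            confusion(frame_from_scores([], []), 121, "fv<400")

    def test_unknown_rule_errors(self, verification20):
        with pytest.raises(ValueError, match="unknown reference rule"):
            confusion(verification20, 121, "fv>nonsense")


class TestAccuracyMetrics:
    def test_verification_statistics(self):
        m = accuracy_metrics(ConfusionCounts(tp=2, fp=1, fn=1, tn=16))
        assert m == {
            "sensitivity": 66.7,
            "specificity": 94.1,
            "ppv": 66.7,
            "npv": 94.1,
        }

    def test_all_perfect(self):
        m = accuracy_metrics(ConfusionCounts(tp=1, fp=0, fn=0, tn=1))
        assert all(v == 100.0 for v in m.values())

    def test_direct_ratios(self):
        m = accuracy_metrics(ConfusionCounts(tp=3, fp=1, fn=0, tn=16))
        assert m["sensitivity"] == 100.0
        assert m["specificity"] == 94.1

    def test_zero_denominator_reported_absent(self):
        m = accuracy_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
        assert "sensitivity" not in m and "ppv" not in m
        assert m["specificity"] == 100.0

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_complement_identities(self, tp, fp, fn, tn):
        c = ConfusionCounts(tp, fp, fn, tn)
        m = accuracy_metrics(c)
        if "sensitivity" in m:
            fnr = round_percent(100.0 * c.fn / (c.tp + c.fn))
            assert m["sensitivity"] + fnr == pytest.approx(100.0, abs=0.11)
        if "specificity" in m:
            fpr = round_percent(100.0 * c.fp / (c.tn + c.fp))
            assert m["specificity"] + fpr == pytest.approx(100.0, abs=0.11)


class TestROC:
    def test_perfectly_separated_auc_one(self):
        r = roc(frame_from_scores([10, 20], [500, 600]), "fv<400")
        assert r.auc == 1.0

    def test_all_tied_auc_half(self):
        r = roc(frame_from_scores([100, 100], [100, 100]), "fv<400")
        assert r.auc == 0.5

    def test_four_record_pair_counting(self):
        # positives score {1, 3}, negatives {2, 4}; lower = disease-leaning.
        r = roc(frame_from_scores([1, 3], [2, 4]), "fv<400")
        assert r.auc == auc_pair_count(np.array([-1.0, -3.0]), np.array([-2.0, -4.0]))
        assert r.auc == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single-class"):
            roc(frame_from_scores([1, 2], []), "fv<400")

    def test_curve_monotone_along_sweep(self, small_cohort):
        r = roc(small_cohort, "fv<400")
        assert np.all(np.diff(r.sensitivities) >= 0)
        assert np.all(np.diff(r.specificities) <= 0)

    def test_invariant_under_monotone_transform(self, small_cohort):
        base = roc(small_cohort, "fv<400")
        for transform in (lambda s: 2 * s + 5, lambda s: np.exp(s / 300.0)):
            f = small_cohort.copy()
            f["hvsi"] = transform(f["hvsi"].to_numpy(float))
            assert roc(f, "fv<400").auc == pytest.approx(base.auc, abs=1e-12)

    def test_delong_ci_brackets_auc(self, small_cohort):
        r = roc(small_cohort, "fv<400")
        assert r.ci_method == "delong"
        assert r.auc_ci[0] <= r.auc <= r.auc_ci[1]

    def test_small_sample_uses_bootstrap(self):
        r = roc(frame_from_scores([10, 20, 30], [100, 200, 300]), "fv<400")
        assert r.ci_method == "bootstrap"
        assert 0 <= r.auc_ci[0] <= r.auc_ci[1] <= 1

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(0, 999), min_size=1, max_size=6),
        st.lists(st.integers(0, 999), min_size=1, max_size=6),
    )
    def test_trapezoid_equals_rank_statistic(self, pos, neg):
        r = roc(frame_from_scores(pos, neg), "fv<400", ci="none")
        tpr = np.concatenate([[0.0], r.sensitivities])
        fpr = np.concatenate([[0.0], 1.0 - r.specificities])
        trapezoid = float(np.trapezoid(tpr, fpr))
        oracle = auc_pair_count(-np.asarray(pos, float), -np.asarray(neg, float))
        assert r.auc == pytest.approx(trapezoid, abs=1e-12)
        assert r.auc == pytest.approx(oracle, abs=1e-12)


class TestYouden:
    def test_perfect_separation_midpoint(self):
        r = roc(frame_from_scores([10, 20], [100, 200]), "fv<400")
        y = youden_cutoff(r)
        assert y["cutoff"] == 60.0  # midpoint of the separating gap (20, 100)
        assert y["sens"] == 1.0 and y["spec"] == 1.0

    def test_verification20_exhaustive_scan(self, verification20):
        # Brute-force oracle: scan every candidate threshold on the fixture.
        scores = verification20["hvsi"].to_numpy(float)
        ref = verification20["flow_volume"].to_numpy(float) < 400.0
        best_j, best_c = -np.inf, None
        uniq = np.sort(np.unique(scores))
        candidates = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1]]])
        for c in candidates:
            pos = scores <= c
            sens = (pos & ref).sum() / ref.sum()
            spec = (~pos & ~ref).sum() / (~ref).sum()
            if sens + spec - 1 >= best_j:
                best_j, best_c = sens + spec - 1, c
        r = roc(verification20, "fv<400")
        y = youden_cutoff(r)
        assert y["cutoff"] == best_c
        # The oracle places the maximal-J cutoff at 161 (midpoint of the
        # 122-200 score gap), catching all three low-flow rows at the cost
        # of one false positive.
        assert y["cutoff"] == 161.0
        assert best_j == pytest.approx(1.0 + 16 / 17 - 1.0)

    def test_tie_broken_toward_sensitivity(self):
        # Cutoffs 15 and 150 both give J = 0.5; prefer the more sensitive.
        f = frame_from_scores([10, 100], [20, 200])
        y = youden_cutoff(roc(f, "fv<400"))
        assert y["sens"] == 1.0


class TestConcordance:
    def test_verification20_published_value(self, verification20):
        c = concordance(verification20, 121, "fv<400")
        assert (c["agree"], c["total"], c["pct"]) == (18, 20, 90.0)

    def test_identical_rules_full_agreement(self):
        f = frame_from_scores([10, 20], [500, 600])
        assert concordance(f, 100, "fv<400")["pct"] == 100.0

    def test_always_opposite(self):
        f = frame_from_scores([500], [10])
        assert concordance(f, 100, "fv<400")["pct"] == 0.0


class TestAssociation:
    def test_exact_line(self):
        f = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [3.0, 5.0, 7.0, 9.0]})
        a = association(f, "x", "y")
        assert a["r2"] == pytest.approx(1.0)
        assert a["slope"] == pytest.approx(2.0)
        assert a["intercept"] == pytest.approx(1.0)

    def test_null_relationship(self, rng):
        f = pd.DataFrame(
            {"x": rng.normal(size=2000), "y": rng.normal(size=2000)}
        )
        assert association(f, "x", "y")["r2"] < 0.01

    def test_five_point_closed_form(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.1, 2.9, 6.2, 7.8, 11.5])
        a = association(pd.DataFrame({"x": x, "y": y}), "x", "y")
        slope, intercept = ols_closed_form(x, y)
        assert a["slope"] == pytest.approx(slope, abs=1e-12)
        assert a["intercept"] == pytest.approx(intercept, abs=1e-12)

    def test_zero_variance_errors(self):
        f = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="variance"):
            association(f, "x", "y")

    def test_signs_on_simulated_cohort(self, small_cohort):
        assert association(small_cohort, "flow_volume", "hvsi")["slope"] > 0
        assert association(small_cohort, "resistance_index", "hvsi")["slope"] < 0


def test_auc_exhaustive_all_labelings_small_n():
    """Trapezoid AUC == pair-count oracle for every labeling of <= 8 records."""
    rng = np.random.default_rng(4)
    score_sets = [
        np.arange(1, 9, dtype=float),  # distinct
        np.array([1, 1, 2, 2, 3, 3, 4, 4], dtype=float),  # heavy ties
        np.round(rng.uniform(0, 999, 8)),
    ]
    for scores in score_sets:
        for n in range(2, 9):
            s = scores[:n]
            for labels in itertools.product([0, 1], repeat=n):
                lab = np.array(labels, bool)
                if lab.all() or not lab.any():
                    continue
                f = pd.DataFrame(
                    {
                        "hvsi": s,
                        "flow_volume": np.where(lab, 300.0, 800.0),
                        "resistance_index": 0.5,
                        "group": "control",
                    }
                )
                r = roc(f, "fv<400", ci="none")
                assert r.auc == pytest.approx(
                    auc_pair_count(-s[lab], -s[~lab]), abs=1e-12
                )
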