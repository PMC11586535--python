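from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caninepcg.evaluate import (bootstrap_ci, cohort_summary, grading_metrics,
                                roc_curve, select_operating_point,
                                sensitivity_by_group, vertical_average)
from caninepcg.model import GradeDistribution, aggregate_patient
from caninepcg.tables import load_table_fixtures


def pair_counting_auc(scores, labels) -> Fraction:
    """Exact AUC oracle: fraction of positive-negative pairs ranked
    correctly, ties counting one half."""
    pos = [Fraction(s).limit_denominator(10**9)
           for s, l in zip(scores, labels) if l == 1]
    neg = [Fraction(s).limit_denominator(10**9)
           for s, l in zip(scores, labels) if l == 0]
    total = Fraction(0)
    for p in pos:
        for n in neg:
            if p > n:
                total += 1
            elif p == n:
                total += Fraction(1, 2)
    return total / (len(pos) * len(neg))


# --------------------------------------------------------------------------
# ROC


def test_toy_auc_by_hand():
    _, _, _, auc = roc_curve([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
    assert auc == pytest.approx(0.75)


def test_perfect_separation_and_errors():
    _, _, _, auc = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert auc == pytest.approx(1.0)
    with pytest.raises(ValueError):
        roc_curve([0.1, 0.2], [1, 1])


def test_independent_scores_near_half():
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 2, size=4000)
    scores = rng.random(4000)
    _, _, _, auc = roc_curve(scores, labels)
    assert abs(auc - 0.5) < 0.03


@settings(deadline=None, max_examples=150, derandomize=True)
@given(st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.5, 0.75, 1.0]),
                min_size=2, max_size=12),
       st.data())
def test_trapezoid_auc_matches_pair_counting_oracle(scores, data):
    n = len(scores)
    labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    if len(set(labels)) < 2:
        labels[0], labels[-1] = 0, 1
    _, _, _, auc = roc_curve(scores, labels)
    oracle = pair_counting_auc(scores, labels)
    assert abs(auc - float(oracle)) < 1e-12


def test_vertical_average_identity():
    fpr = np.array([0.0, 0.2, 0.6, 1.0])
    tpr = np.array([0.0, 0.5, 0.9, 1.0])
    summ = vertical_average([(fpr, tpr)])
    np.testing.assert_allclose(summ.tpr_mean, np.interp(summ.fpr_grid, fpr, tpr))
    assert summ.auc_mean == pytest.approx(np.trapezoid(tpr, fpr))
    assert summ.auc_ci[0] == pytest.approx(summ.auc_ci[1])


def test_vertical_average_mirrored_curves_give_diagonal():
    fpr = np.array([0.0, 0.5, 1.0])
    above = (fpr, np.array([0.0, 0.9, 1.0]))
    below = (fpr, 2 * fpr - above[1])      # vertical mirror about the diagonal
    summ = vertical_average([above, below])
    np.testing.assert_allclose(summ.tpr_mean, summ.fpr_grid, atol=1e-12)
    assert summ.auc_mean == pytest.approx(0.5, abs=1e-12)


def test_vertical_average_identical_curves_zero_width():
    fpr = np.array([0.0, 0.3, 1.0])
    tpr = np.array([0.0, 0.8, 1.0])
    summ = vertical_average([(fpr, tpr)] * 10)
    np.testing.assert_allclose(summ.tpr_low, summ.tpr_high)
    assert summ.auc_ci[0] == summ.auc_ci[1]


def test_vertical_average_order_and_duplication_invariant():
    rng = np.random.default_rng(3)
    curves = []
    for _ in range(4):
        fpr = np.sort(np.concatenate([[0, 1], rng.random(5)]))
        tpr = np.sort(np.concatenate([[0, 1], rng.random(5)]))
        curves.append((fpr, tpr))
    a = vertical_average(curves)
    b = vertical_average(curves[::-1])
    c = vertical_average(curves + curves)
    np.testing.assert_allclose(a.tpr_mean, b.tpr_mean)
    np.testing.assert_allclose(a.tpr_mean, c.tpr_mean)
    assert a.auc_mean == pytest.approx(c.auc_mean)
    with pytest.raises(ValueError):
        vertical_average([])


def test_operating_point_selection():
    scores = [0.1, 0.2, 0.3, 0.6, 0.7, 0.9]
    labels = [0, 0, 0, 1, 1, 1]
    op = select_operating_point(scores, labels, "sensitive", target=1.0)
    assert op.sensitivity == 1.0 and op.specificity == 1.0


# --------------------------------------------------------------------------
# bootstrap


def test_constant_statistic_zero_width():
    run = {f"p{i}": 5.0 for i in range(20)}
    res = bootstrap_ci([run], lambda vals: float(np.mean(vals)),
                       n_bootstrap=100, seed=0)
    assert res.ci == (5.0, 5.0) and res.mean == 5.0


def test_normal_mean_ci_width_matches_closed_form():
    rng = np.random.default_rng(1)
    n = 1000
    run = {f"p{i}": float(v) for i, v in enumerate(rng.standard_normal(n))}
    res = bootstrap_ci([run], lambda vals: float(np.mean(vals)),
                       n_bootstrap=500, seed=2)
    width = res.ci[1] - res.ci[0]
    expected = 2 * 1.96 / np.sqrt(n)
    assert abs(width - expected) / expected < 0.2


def test_bootstrap_rejects_empty():
    with pytest.raises(ValueError):
        bootstrap_ci([], lambda v: 0.0)
    with pytest.raises(ValueError):
        bootstrap_ci([{}], lambda v: 0.0)


# --------------------------------------------------------------------------
# grading metrics


def test_perfect_predictions():
    m = grading_metrics(["none", "soft", "loud"], ["none", "soft", "loud"])
    assert m["accuracy"] == 1.0 and m["within_one"] == 1.0
    np.testing.assert_allclose(np.diag(m["confusion"])[[0, 1, 3]], 1.0)


def test_off_by_one_everywhere():
    pred = ["soft", "moderate", "loud", "thrilling"]
    expert = ["none", "soft", "moderate", "loud"]
    m = grading_metrics(pred, expert)
    assert m["accuracy"] == 0.0 and m["within_one"] == 1.0


def test_hand_counted_toy_vectors():
    m = grading_metrics(["none", "soft", "loud"], ["none", "moderate", "loud"])
    assert m["accuracy"] == pytest.approx(2 / 3)
    assert m["within_one"] == 1.0


def test_confusion_columns_sum_to_one():
    rng = np.random.default_rng(4)
    pred = rng.integers(0, 5, 100)
    expert = rng.integers(0, 5, 100)
    m = grading_metrics(pred, expert)
    present = np.unique(expert)
    np.testing.assert_allclose(m["confusion"][:, present].sum(axis=0), 1.0,
                               atol=1e-9)
    with pytest.raises(ValueError):
        grading_metrics([0, 1], [0])


# --------------------------------------------------------------------------
# group sensitivity and cohort summaries


def _patient(flag, maximal=("left_apex",)):
    probs = np.array([0.1, 0.2, 0.2, 0.4, 0.1]) if flag else \
        np.array([0.9, 0.1, 0.0, 0.0, 0.0])
    dists = {s: GradeDistribution(probs) for s in maximal} if flag else \
        {"left_apex": GradeDistribution(probs)}
    return aggregate_patient(dists)


def test_group_sensitivity_arithmetic():
    preds = {f"p{i}": _patient(i < 3) for i in range(4)}
    groups = {f"p{i}": "MMVD" for i in range(4)}
    out = sensitivity_by_group(preds, groups, n_bootstrap=50)
    assert out["MMVD"]["sensitivity"] == pytest.approx(0.75)
    all_flagged = {f"q{i}": _patient(True) for i in range(5)}
    out2 = sensitivity_by_group(all_flagged, {f"q{i}": "PS" for i in range(5)},
                                n_bootstrap=50)
    assert out2["PS"]["sensitivity"] == 1.0
    assert out2["PS"]["ci"] == (1.0, 1.0)
    with pytest.raises(ValueError):
        sensitivity_by_group(preds, {"p0": "MMVD", "zz": "DCM"})


def test_ps_murmurs_loudest_at_left_base(cohort_records_only):
    ps = [r for r in cohort_records_only
          if r.disease == "PS" and r.point_of_maximal_intensity]
    assert ps
    sites = [r.point_of_maximal_intensity for r in ps]
    assert max(set(sites), key=sites.count) == "left_base"


def test_fixture_percentages_match_published_text():
    t2 = cohort_summary(load_table_fixtures("table2"))
    t3 = cohort_summary(load_table_fixtures("table3"))
    assert t2.percent_any_murmur("MMVD") == 98
    assert t2.percent_any_murmur("normal") == 30
    assert t2.percent_grade("normal", "soft") == 28
    assert t2.percent_point_of_max("MMVD", "left_apex") == 93
    assert t3.percent_loud_or_thrilling_at_apex("B2") == 73
    assert t3.percent_loud_or_thrilling_at_apex("B1") == 23


def test_summary_from_generated_records(cohort_records_only):
    s = cohort_summary(cohort_records_only)
    assert 90 <= s.percent_any_murmur("MMVD") <= 100
    assert abs(s.percent_loud_or_thrilling_at_apex("B2") - 73) <= 12
    with pytest.raises(ValueError):
        cohort_summary([])
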