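import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dbrmeta import Label
from dbrmeta.metrics import (
    DegenerateCurveError,
    RocCurve,
    auc,
    aulc,
    aulc_ratio,
    binary_counts,
    compute_report,
    compute_roc,
    cpr_opr,
    cpr_opr_ratios,
    cross_over_curves,
    f1_sens_spec,
    max_f1,
    threshold_at,
)
from tests.conftest import labels_from_string


def pair_count_auc(labels, scores):
    """Independent oracle: concordant-pair fraction with ties counting 1/2."""
    labels = np.asarray(labels)
    pos = np.asarray(scores)[labels == Label.DNA]
    neg = np.asarray(scores)[labels != Label.DNA]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def random_instance(rng, n_max=12):
    n = rng.integers(2, n_max + 1)
    labels = rng.choice(
        [Label.DNA, Label.OTHER, Label.NONE], size=n, p=[0.4, 0.3, 0.3]
    )
    if (labels == Label.DNA).all():
        labels[0] = Label.NONE
    if not (labels == Label.DNA).any():
        labels[0] = Label.DNA
    scores = rng.choice(np.round(rng.normal(size=4), 2), size=n)  # force ties
    return labels, scores


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def test_roc_perfect_separation():
    curve = compute_roc(labels_from_string("D."), np.array([0.9, 0.1]))
    assert list(curve.fpr) == [0, 0, 1]
    assert list(curve.tpr) == [0, 1, 1]
    assert auc(curve) == 1.0


def test_roc_full_tie_single_interior_point():
    curve = compute_roc(labels_from_string("D."), np.array([0.5, 0.5]))
    np.testing.assert_array_equal(curve.fpr, [0, 1])
    np.testing.assert_array_equal(curve.tpr, [0, 1])
    assert auc(curve) == pytest.approx(0.5)


def test_four_residue_auc_matches_pair_counting():
    labels = labels_from_string("D.DO")
    scores = np.array([0.8, 0.7, 0.6, 0.2])
    assert auc(compute_roc(labels, scores)) == pytest.approx(0.75)
    assert pair_count_auc(labels, scores) == pytest.approx(0.75)


def test_roc_requires_both_classes():
    with pytest.raises(DegenerateCurveError):
        compute_roc(labels_from_string("DD"), np.array([1.0, 0.5]))
    with pytest.raises(DegenerateCurveError):
        compute_roc(labels_from_string(".O"), np.array([1.0, 0.5]))


def test_auc_equals_pair_oracle_on_random_small_instances():
    rng = np.random.default_rng(42)
    for _ in range(300):
        labels, scores = random_instance(rng)
        assert auc(compute_roc(labels, scores)) == pytest.approx(
            pair_count_auc(labels, scores), abs=1e-12
        )


def test_random_scores_give_half_auc():
    rng = np.random.default_rng(0)
    labels = np.where(rng.random(50_000) < 0.3, Label.DNA, Label.NONE)
    scores = rng.random(50_000)
    assert auc(compute_roc(labels, scores)) == pytest.approx(0.5, abs=0.01)


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=30, deadline=None, derandomize=True, database=None)
def test_metrics_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    labels, scores = random_instance(rng, n_max=40)
    if not ((labels == Label.DNA).any() and (labels != Label.DNA).any()):
        return
    transformed = np.exp(3 * scores) + 1.0  # strictly increasing
    a1 = auc(compute_roc(labels, scores))
    a2 = auc(compute_roc(labels, transformed))
    assert a1 == pytest.approx(a2, abs=1e-12)


# ---------------------------------------------------------------------------
# AULC and its random-baseline ratio
# ---------------------------------------------------------------------------


def test_aulc_full_range_equals_auc():
    rng = np.random.default_rng(1)
    labels = np.where(rng.random(500) < 0.2, Label.DNA, Label.NONE)
    scores = rng.normal(size=500) + 0.5 * (labels == Label.DNA)
    curve = compute_roc(labels, scores)
    area, bound = aulc(curve, "fixed_fpr", 1.0)
    assert bound == 1.0
    assert area == pytest.approx(auc(curve), abs=1e-12)


def test_aulc_perfect_predictor_fixed_bound():
    labels = labels_from_string("DD..")
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    area, bound = aulc(compute_roc(labels, scores), "fixed_fpr", 0.1)
    assert area == pytest.approx(0.1)  # TPR = 1 over the whole region
    assert aulc_ratio(area, bound) == pytest.approx(20.0)


def test_aulc_random_predictor_ratio_near_one():
    rng = np.random.default_rng(3)
    labels = np.where(rng.random(200_000) < 0.015, Label.DNA, Label.NONE)
    ratios = []
    for _ in range(10):
        scores = rng.random(200_000)
        area, bound = aulc(compute_roc(labels, scores), "fixed_fpr", 0.1)
        ratios.append(aulc_ratio(area, bound))
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)


def test_aulc_ratio_twice_better_is_two():
    # ROC built to satisfy TPR = 2*FPR across the low-FPR region via ties
    n_groups = 10
    labels, scores = [], []
    for k in range(n_groups):
        s = 1.0 - 0.01 * (k + 1)
        labels += [Label.DNA, Label.DNA, Label.NONE]
        scores += [s, s, s]
    labels += [Label.DNA] * 80 + [Label.NONE] * 90
    scores += [0.0] * 170
    area, bound = aulc(
        compute_roc(np.array(labels), np.array(scores)), "fixed_fpr", 0.1
    )
    assert aulc_ratio(area, bound) == pytest.approx(2.0, abs=1e-9)


def test_aulc_count_matched_bound_matches_threshold_scan():
    rng = np.random.default_rng(5)
    labels = np.where(rng.random(4000) < 0.05, Label.DNA, Label.NONE)
    scores = rng.normal(size=4000) + 1.0 * (labels == Label.DNA)
    curve = compute_roc(labels, scores)
    _, bound = aulc(curve, "count_matched")
    # oracle: scan thresholds until predicted positives reach P
    p = (labels == Label.DNA).sum()
    order = np.sort(scores)[::-1]
    thr = order[p - 1]  # loosest threshold admitting exactly P predictions
    calls = scores >= thr
    fpr_at = ((labels != Label.DNA) & calls).sum() / (labels != Label.DNA).sum()
    assert bound == pytest.approx(fpr_at, abs=1e-9)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def test_threshold_at_zero_fpr_perfect_head():
    labels = labels_from_string("DD..")
    scores = np.array([0.9, 0.8, 0.7, 0.1])
    curve = compute_roc(labels, scores)
    thr, f, t = threshold_at(curve, fpr=1e-9)
    assert t == pytest.approx(1.0, abs=1e-6)
    calls = scores > thr
    assert 0.7 < thr <= 0.8
    assert list(calls.astype(int)) == [1, 1, 0, 0]


def test_threshold_interpolates_between_curve_points():
    curve = RocCurve(
        fpr=np.array([0.0, 0.4, 0.6, 1.0]),
        tpr=np.array([0.0, 0.6, 0.8, 1.0]),
        thresholds=np.array([np.inf, 0.8, 0.5, 0.1]),
        n_pos=10, n_neg=10,
    )
    _, f, t = threshold_at(curve, fpr=0.5)
    assert (f, t) == (0.5, pytest.approx(0.7))


def test_threshold_at_degenerate_curve_errors():
    curve = compute_roc(labels_from_string("D."), np.array([0.5, 0.5]))
    with pytest.raises(DegenerateCurveError, match="calibration"):
        threshold_at(curve, fpr=0.1)


def test_threshold_at_tpr_one_perfect_predictor():
    labels = labels_from_string("DD..")
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    _, f, t = threshold_at(compute_roc(labels, scores), tpr=1.0)
    assert f == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# binary counts, F1, CPR/OPR
# ---------------------------------------------------------------------------


def test_binary_counts_partition():
    counts = binary_counts(labels_from_string("DO."), np.array([1, 1, 0], bool))
    assert (counts.tp, counts.fp, counts.tn, counts.fn) == (1, 1, 1, 0)
    assert (counts.fp_other, counts.fp_none) == (1, 0)


def test_all_negative_calls():
    labels = labels_from_string("DDO..")
    counts = binary_counts(labels, np.zeros(5, bool))
    assert counts.fp == 0 and counts.fn == 2


def test_fpr_decomposes_into_cpr_opr():
    labels = labels_from_string("DOO..")
    calls = np.array([0, 1, 0, 0, 0], bool)
    counts = binary_counts(labels, calls)
    cpr, opr = cpr_opr(counts)
    assert counts.fpr == pytest.approx(0.25)
    weighted = (cpr * counts.n_other + opr * counts.n_none) / (
        counts.n_other + counts.n_none
    )
    assert weighted == pytest.approx(counts.fpr)


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=30, deadline=None, derandomize=True, database=None)
def test_fpr_decomposition_at_every_threshold(seed):
    rng = np.random.default_rng(seed)
    labels = rng.choice([Label.DNA, Label.OTHER, Label.NONE], size=60)
    scores = np.round(rng.normal(size=60), 1)
    for thr in np.unique(scores):
        counts = binary_counts(labels, scores > thr)
        if counts.n_other == 0 or counts.n_none == 0 or counts.tn + counts.fp == 0:
            continue
        cpr, opr = cpr_opr(counts)
        weighted = (cpr * counts.n_other + opr * counts.n_none) / (
            counts.n_other + counts.n_none
        )
        assert weighted == pytest.approx(counts.fpr, abs=1e-12)


def test_f1_sens_spec_values():
    assert f1_sens_spec(1.0, 0.0) == 1.0
    assert f1_sens_spec(0.5, 0.1) == pytest.approx(2 * 0.45 / 1.4)
    assert f1_sens_spec(0.0, 1.0) == 0.0


def test_max_f1_dominates_operating_points():
    rng = np.random.default_rng(9)
    labels = np.where(rng.random(2000) < 0.1, Label.DNA, Label.NONE)
    scores = rng.normal(size=2000) + 1.2 * (labels == Label.DNA)
    curve = compute_roc(labels, scores)
    m = max_f1(curve)
    for f in (0.1, 0.2):
        _, ach_f, ach_t = threshold_at(curve, fpr=f)
        assert m >= f1_sens_spec(ach_t, ach_f) - 1e-12
    assert max_f1(compute_roc(labels_from_string("D."), [1.0, 0.0])) == 1.0


def test_max_f1_small_curve_exhaustive():
    curve = RocCurve(
        fpr=np.array([0.0, 0.2, 1.0]),
        tpr=np.array([0.4, 0.9, 1.0]),
        thresholds=np.array([np.inf, 0.5, 0.0]),
        n_pos=10, n_neg=10,
    )
    expected = max(
        f1_sens_spec(t, f) for f, t in zip(curve.fpr, curve.tpr)
    )
    assert max_f1(curve) == pytest.approx(expected)


def test_cpr_opr_edge_cases():
    half = binary_counts(labels_from_string("OO"), np.array([1, 0], bool))
    cpr, opr = cpr_opr(half)
    assert cpr == pytest.approx(0.5)
    assert np.isnan(opr)  # no NONE residues: undefined, flagged not 0


def test_cpr_opr_ratios_arithmetic():
    assert cpr_opr_ratios(0.05, 0.1, 0.1) == (pytest.approx(2.0),
                                              pytest.approx(1.0))
    assert cpr_opr_ratios(0.0, 0.1, 0.1)[0] == np.inf


# ---------------------------------------------------------------------------
# cross-/over-prediction curves
# ---------------------------------------------------------------------------


def test_crossover_perfect_predictor_zero_area():
    labels = labels_from_string("DDOO..")
    scores = np.array([0.9, 0.8, 0.4, 0.3, 0.2, 0.1])
    c = cross_over_curves(labels, scores)
    assert c.aucpc == pytest.approx(0.0)
    assert c.auopc == pytest.approx(0.0)


def test_crossover_anti_perfect_cpr_is_one():
    # all OTHER residues outrank all DNA: CPR hits 1 before any TPR gain
    labels = labels_from_string("OODD..")
    scores = np.array([0.9, 0.8, 0.4, 0.3, 0.2, 0.1])
    c = cross_over_curves(labels, scores)
    assert c.aucpc == pytest.approx(1.0)


def test_crossover_random_near_half():
    rng = np.random.default_rng(11)
    labels = rng.choice(
        [Label.DNA, Label.OTHER, Label.NONE], size=100_000, p=[0.02, 0.1, 0.88]
    )
    c = cross_over_curves(labels, rng.random(100_000))
    assert c.aucpc == pytest.approx(0.5, abs=0.03)
    assert c.auopc == pytest.approx(0.5, abs=0.03)


def test_crossover_requires_all_classes():
    with pytest.raises(DegenerateCurveError, match="OTHER"):
        cross_over_curves(labels_from_string("D."), np.array([1.0, 0.0]))


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


def test_report_rates_in_range(medium_dataset):
    labels = medium_dataset.pooled_labels()
    scores = medium_dataset.pooled_scores("struct_a")
    rep = compute_report(labels, scores)
    flat = rep.as_dict()
    for key in ("auc", "aucpc", "auopc", "cpr", "opr", "max_f1",
                "sensitivity_at_fpr_0.1", "specificity_at_tpr_0.5"):
        assert 0.0 <= flat[key] <= 1.0, key
    assert flat["aulc_ratio"] >= 0
    assert rep.calibration_fpr == 0.1
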