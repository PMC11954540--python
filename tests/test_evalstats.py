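"""Evaluation statistics against brute-force and hand-traced oracles."""

import numpy as np
import pytest

from octad.evalstats import (LabeledScores, anomaly_profile, interp_profile,
                             loo_ppv_npv, optimal_cutoff, pr_curve_ap,
                             roc_curve_auc, severity_scores,
                             training_threshold)


def concordance_auc(scores, labels):
    """O(n^2) Mann-Whitney oracle: P(anom > norm) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def step_weighted_ap(scores, labels):
    """Literal step-weighted AP: sum over thresholds of (R_k - R_{k-1}) P_k."""
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    tp = fp = 0
    i = 0
    while i < len(sorted_labels):
        j = i
        while j < len(sorted_labels) and sorted_scores[j] == sorted_scores[i]:
            tp += sorted_labels[j]
            fp += 1 - sorted_labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


# ----------------------------------------------------------------------- ROC
def test_roc_auc_perfect_and_all_ties():
    perfect = LabeledScores(np.array([1., 2., 3., 4.]), np.array([0, 0, 1, 1]))
    assert roc_curve_auc(perfect).area == pytest.approx(1.0)
    ties = LabeledScores(np.full(6, 2.0), np.array([0, 1, 0, 1, 0, 1]))
    assert roc_curve_auc(ties).area == pytest.approx(0.5)


def test_roc_auc_matches_concordance_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        n = int(rng.integers(10, 50))
        scores = np.round(rng.standard_normal(n), 1)  # induce ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        got = roc_curve_auc(LabeledScores(scores, labels)).area
        assert got == pytest.approx(concordance_auc(scores, labels), abs=1e-9)


def test_roc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_curve_auc(LabeledScores(np.array([1., 2.]), np.array([1, 1])))


def test_roc_curve_endpoints():
    curve = roc_curve_auc(LabeledScores(np.array([3., 1., 2., 5.]), np.array([0, 0, 1, 1])))
    assert (curve.x[0], curve.y[0]) == (0.0, 0.0)
    assert (curve.x[-1], curve.y[-1]) == (1.0, 1.0)


# ------------------------------------------------------------------------ PR
def test_ap_perfect_and_single_positive_ranked_last():
    perfect = LabeledScores(np.array([1., 2., 3., 4.]), np.array([0, 0, 1, 1]))
    assert pr_curve_ap(perfect).area == pytest.approx(1.0)
    worst = LabeledScores(np.array([5., 4., 3., 2., 1.]), np.array([0, 0, 0, 0, 1]))
    assert pr_curve_ap(worst).area == pytest.approx(1 / 5)


def test_ap_matches_step_weighted_definition():
    rng = np.random.default_rng(4)
    for _ in range(10):
        n = int(rng.integers(8, 40))
        scores = np.round(rng.standard_normal(n), 1)
        labels = rng.integers(0, 2, n)
        if labels.sum() == 0:
            continue
        got = pr_curve_ap(LabeledScores(scores, labels)).area
        assert got == pytest.approx(step_weighted_ap(scores, labels), abs=1e-9)


def test_ap_requires_a_positive():
    with pytest.raises(ValueError):
        pr_curve_ap(LabeledScores(np.array([1., 2.]), np.array([0, 0])))


# ------------------------------------------------------------ optimal cutoff
def test_optimal_cutoff_perfect_separation_hits_the_corner():
    data = LabeledScores(np.array([1., 2., 3., 4.]), np.array([0, 0, 1, 1]))
    curve = roc_curve_auc(data)
    thr = optimal_cutoff(curve)
    idx = int(np.flatnonzero(curve.thresholds == thr)[0])
    assert curve.x[idx] == 0.0 and curve.y[idx] == 1.0


def test_optimal_cutoff_minimizes_distance_over_all_swept_points():
    rng = np.random.default_rng(6)
    scores = rng.standard_normal(40)
    labels = rng.integers(0, 2, 40)
    labels[0], labels[1] = 0, 1
    curve = roc_curve_auc(LabeledScores(scores, labels))
    thr = optimal_cutoff(curve)
    idx = int(np.flatnonzero(curve.thresholds == thr)[0])
    d2 = curve.x ** 2 + (1 - curve.y) ** 2
    assert d2[idx] == pytest.approx(d2.min())


def test_optimal_cutoff_tie_breaks_toward_higher_threshold():
    # two equidistant points (0,0) and (1,1): the higher threshold wins
    curve = roc_curve_auc(LabeledScores(np.array([2.0, 2.0]), np.array([0, 1])))
    assert optimal_cutoff(curve) == curve.thresholds.max()


# ----------------------------------------------------------------- LOO PPV/NPV
def three_volume_toy():
    scores = np.array([0.1, 0.4, 0.8, 0.9, 0.2, 0.3, 0.7, 0.6, 0.5, 0.35, 0.95, 0.15])
    labels = np.array([0, 0, 1, 1, 0, 0, 1, 1, 1, 0, 1, 0])
    groups = np.array(["A"] * 4 + ["B"] * 4 + ["C"] * 4)
    return LabeledScores(scores, labels, group_id=groups)


def test_loo_matches_hand_traced_three_volume_run():
    # expected values from a manual trace of: ROC on the other two volumes,
    # cutoff closest to (0,1) with ties to the higher threshold, binarize
    # held-out scores with score >= cutoff
    result = loo_ppv_npv(three_volume_toy())
    per = result.per_volume.set_index("volume_id")
    assert per.loc["A", ["threshold", "tp", "fp", "tn", "fn"]].tolist() == [0.5, 2, 0, 2, 0]
    assert per.loc["B", ["threshold", "tp", "fp", "tn", "fn"]].tolist() == [0.5, 2, 0, 2, 0]
    assert per.loc["C", ["threshold", "tp", "fp", "tn", "fn"]].tolist() == [0.6, 1, 0, 2, 1]
    assert per.loc["A", "ppv"] == 1.0 and per.loc["A", "npv"] == 1.0
    assert per.loc["C", "ppv"] == 1.0
    assert per.loc["C", "npv"] == pytest.approx(2 / 3)
    assert result.ppv_mean == pytest.approx(1.0)
    assert result.npv_mean == pytest.approx((1.0 + 1.0 + 2 / 3) / 3)


def test_loo_perfectly_separable_gives_unit_ppv_npv():
    scores, labels, groups = [], [], []
    for v in range(3):
        scores += [0.1 + 0.01 * v, 0.2, 0.8, 0.9 - 0.01 * v]
        labels += [0, 0, 1, 1]
        groups += [f"v{v}"] * 4
    res = loo_ppv_npv(LabeledScores(np.array(scores), np.array(labels), group_id=np.array(groups)))
    assert np.allclose(res.per_volume.ppv, 1.0)
    assert np.allclose(res.per_volume.npv, 1.0)


def test_loo_volume_without_normals_reports_missing_npv():
    # fold c trains on a+b (perfect separation, cutoff 0.8); both of c's
    # slices score above it, so TN + FN = 0 and NPV is undefined
    scores = np.array([0.1, 0.9, 0.2, 0.8, 0.9, 0.95])
    labels = np.array([0, 1, 0, 1, 1, 1])
    groups = np.array(["a", "a", "b", "b", "c", "c"])
    res = loo_ppv_npv(LabeledScores(scores, labels, group_id=groups))
    row = res.per_volume.set_index("volume_id").loc["c"]
    assert np.isnan(row.npv) and row.ppv == 1.0
    assert res.n_missing_npv == 1


def test_loo_single_global_fold_reduction():
    # two identical volumes: each fold trains on a copy of the full data, so
    # per-fold cutoffs and counts equal the ordinary global PPV/NPV
    scores = np.array([0.1, 0.6, 0.8, 0.4])
    labels = np.array([0, 1, 1, 0])
    data = LabeledScores(np.tile(scores, 2), np.tile(labels, 2),
                         group_id=np.array(["x"] * 4 + ["y"] * 4))
    res = loo_ppv_npv(data)
    global_thr = optimal_cutoff(roc_curve_auc(LabeledScores(scores, labels)))
    assert np.allclose(res.per_volume.threshold, global_thr)
    pred = scores >= global_thr
    ppv = (pred & (labels == 1)).sum() / pred.sum()
    assert np.allclose(res.per_volume.ppv, ppv)


def test_loo_requires_two_volumes_and_warns_on_single_class_fold():
    with pytest.raises(ValueError):
        loo_ppv_npv(LabeledScores(np.array([1., 2.]), np.array([0, 1]),
                                  group_id=np.array(["a", "a"])))
    # fold 'b' trains on volume 'a' only, which is single-class
    scores = np.array([0.5, 0.6, 0.1, 0.9])
    labels = np.array([1, 1, 0, 1])
    groups = np.array(["a", "a", "b", "b"])
    with pytest.warns(UserWarning):
        res = loo_ppv_npv(LabeledScores(scores, labels, group_id=groups))
    assert "b" in res.skipped_folds


# ------------------------------------------------------------------ profiles
def test_profile_hand_interpolation_and_identities():
    assert np.allclose(interp_profile([0.0, 1.0], 3), [0.0, 0.5, 1.0])
    assert np.allclose(interp_profile([2.0, 2.0, 2.0], 5), 2.0)
    seq = [0.3, 0.9, 0.1, 0.5]
    assert np.array_equal(interp_profile(seq, 4), np.asarray(seq))


def test_profile_exact_for_knot_aligned_piecewise_linear_input():
    # upsampling a piecewise-linear sequence to a grid containing its knots
    # reproduces the segment values exactly
    got = interp_profile([0.0, 2.0, 1.0], 5)
    assert np.array_equal(got, np.array([0.0, 1.0, 2.0, 1.5, 1.0]))


def test_profile_per_class_means():
    profiles = [[0.0, 1.0], [1.0, 3.0], [5.0, 5.0]]
    out = anomaly_profile(profiles, target_length=3, classes=["a", "a", "b"])
    assert np.allclose(out["a"], [0.5, 1.25, 2.0])
    assert np.allclose(out["b"], 5.0)


def test_profile_input_validation():
    with pytest.raises(ValueError):
        interp_profile([1.0], 3)
    with pytest.raises(ValueError):
        anomaly_profile([], 3)


# ------------------------------------------------------------------ severity
def test_training_threshold_values_and_weighting():
    assert training_threshold([np.full((4, 4), 0.7)]) == pytest.approx(0.7)
    assert training_threshold([np.full((4, 4), 0.2), np.full((4, 4), 0.4)]) == pytest.approx(0.3)
    a, b = np.full((2, 2), 0.2), np.full((4, 4), 0.4)
    flat = np.concatenate([a.ravel(), b.ravel()])
    assert training_threshold([a, b]) == pytest.approx(flat.mean())
    with pytest.raises(ValueError):
        training_threshold([])


def test_severity_thresholded_mean_and_empty_exceedance():
    m = np.array([[0.1, 0.2], [0.4, 0.6]])
    mask = np.array([[0, 0], [1, 1]], dtype=np.uint8)
    records, _ = severity_scores([m], [mask], threshold=0.3)
    assert records[0].map_score == pytest.approx(0.5)
    assert records[0].relative_lesion_area == pytest.approx(0.5)
    records, _ = severity_scores([np.full((2, 2), 0.1)], [mask], threshold=0.3)
    assert records[0].map_score == 0.0


def test_severity_rank_perfect_case_and_constant_series():
    maps = [np.full((2, 2), v) for v in (0.4, 0.6, 0.8)]
    masks = [np.zeros((2, 2), np.uint8) for _ in range(3)]
    masks[0][0, 0] = 1
    masks[1][0, :] = 1
    masks[2][:, :] = 1
    _, (pear, spear) = severity_scores(maps, masks, threshold=0.3)
    assert spear == pytest.approx(1.0)
    _, (p2, s2) = severity_scores(maps, [masks[1]] * 3, threshold=1.0)
    assert np.isnan(p2) and np.isnan(s2)


def test_severity_monotone_under_raising_above_threshold_values():
    m = np.array([[0.5, 0.2], [0.9, 0.1]])
    mask = np.ones((2, 2), np.uint8)
    base, _ = severity_scores([m], [mask], threshold=0.3)
    raised = m.copy()
    raised[1, 0] = 1.5
    higher, _ = severity_scores([raised], [mask], threshold=0.3)
    assert higher[0].map_score >= base[0].map_score


def test_severity_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        severity_scores([np.zeros((2, 2))], [np.zeros((3, 3), np.uint8)], 0.3)
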