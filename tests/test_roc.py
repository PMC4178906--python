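"""ROC stack: brute-force oracles, cross-library checks, invariants."""

import numpy as np
import pytest

from pmews import (
    auroc,
    auroc_ci,
    confusion_at_cutoff,
    cutoff_sweep,
    disposal_by_score,
    roc_curve,
    youden_optimal_cutoff,
)


def brute_force_auroc(scores, labels):
    """O(n^2) pair count with half credit for ties (independent oracle)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def _random_cohort(rng, n_max=50):
    n = int(rng.integers(4, n_max + 1))
    scores = rng.integers(0, 10, n)
    labels = np.zeros(n, dtype=int)
    labels[: int(rng.integers(1, n))] = 1
    rng.shuffle(labels)
    if labels.all() or not labels.any():
        labels[0] = 1 - labels[0]
    return scores, labels


def test_auroc_examples():
    assert auroc([0, 1, 2, 3], [0, 0, 1, 1]) == 1.0
    assert auroc([3, 2, 1, 0], [0, 0, 1, 1]) == 0.0
    # pairs: (2,1)+ (2,2)=tie (3,1)+ (3,2)+ -> (1+0.5+1+1)/4
    assert auroc([1, 2, 2, 3], [0, 0, 1, 1]) == pytest.approx(0.875)


def test_auroc_matches_brute_force_on_many_random_cohorts():
    rng = np.random.default_rng(2024)
    for _ in range(300):
        scores, labels = _random_cohort(rng)
        assert auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels), abs=1e-12
        )


def test_auroc_matches_sklearn():
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(5)
    for _ in range(50):
        scores, labels = _random_cohort(rng)
        assert auroc(scores, labels) == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12
        )


def test_auroc_invariant_under_monotone_transform():
    rng = np.random.default_rng(11)
    scores, labels = _random_cohort(rng)
    base = auroc(scores, labels)
    assert auroc(3 * scores + 7, labels) == pytest.approx(base, abs=1e-12)
    assert auroc(np.exp(scores / 4.0), labels) == pytest.approx(base, abs=1e-12)


def test_auroc_complement_symmetry():
    rng = np.random.default_rng(13)
    for _ in range(20):
        scores, labels = _random_cohort(rng)
        assert auroc(scores, labels) + auroc(scores, 1 - labels) == pytest.approx(
            1.0, abs=1e-12
        )


def test_auroc_equals_trapezoidal_area_under_roc():
    rng = np.random.default_rng(17)
    for _ in range(20):
        scores, labels = _random_cohort(rng)
        pts = roc_curve(scores, labels)
        fpr = np.array([1 - p.specificity for p in pts])
        tpr = np.array([p.sensitivity for p in pts])
        area = -np.trapezoid(tpr, fpr)  # fpr decreases with threshold
        assert auroc(scores, labels) == pytest.approx(area, abs=1e-12)


def test_roc_curve_endpoints_and_monotonicity():
    rng = np.random.default_rng(19)
    scores, labels = _random_cohort(rng)
    pts = roc_curve(scores, labels)
    assert (pts[0].sensitivity, pts[0].specificity) == (1.0, 0.0)
    assert (pts[-1].sensitivity, pts[-1].specificity) == (0.0, 1.0)
    sens = [p.sensitivity for p in pts]
    spec = [p.specificity for p in pts]
    assert all(a >= b for a, b in zip(sens, sens[1:]))
    assert all(a <= b for a, b in zip(spec, spec[1:]))


def test_roc_curve_perfect_separation_point():
    pts = {p.threshold: p for p in roc_curve([0, 1, 2, 3], [0, 0, 1, 1])}
    assert pts[2].sensitivity == 1.0 and pts[2].specificity == 1.0


def test_roc_curve_tied_scores_point():
    pts = {p.threshold: p for p in roc_curve([1, 1, 2, 2], [0, 1, 0, 1])}
    assert pts[2].sensitivity == 0.5 and pts[2].specificity == 0.5


def test_single_class_labels_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        auroc([1, 2, 3], [1, 1, 1])
    with pytest.raises(ValueError, match="degenerate"):
        roc_curve([1, 2, 3], [0, 0, 0])


def test_delong_and_bootstrap_cis_agree(labeled_cohort):
    from pmews import score_dataframe

    scored = score_dataframe(labeled_cohort)
    scores = scored["total_pmews"].to_numpy()
    y = scored["needs_ems"].to_numpy()
    lo_d, hi_d = auroc_ci(scores, y, method="delong")
    lo_b, hi_b = auroc_ci(scores, y, method="bootstrap", n_boot=10000, seed=3)
    assert lo_d <= auroc(scores, y) <= hi_d
    assert abs(lo_d - lo_b) < 0.01
    assert abs(hi_d - hi_b) < 0.01


def test_delong_ci_narrows_with_sample_size():
    rng = np.random.default_rng(23)
    widths = []
    for n in (50, 500, 5000):
        scores = np.concatenate([rng.integers(0, 6, n), rng.integers(3, 9, n)])
        labels = np.repeat([0, 1], n)
        lo, hi = auroc_ci(scores, labels)
        widths.append(hi - lo)
    assert widths[0] > widths[1] > widths[2]


def test_single_positive_gives_wide_interval_without_crash():
    scores = [5, 1, 2, 3, 2, 1]
    labels = [1, 0, 0, 0, 0, 0]
    lo, hi = auroc_ci(scores, labels)
    assert 0.0 <= lo <= hi <= 1.0


def test_bootstrap_below_100_replicates_warns(caplog):
    with caplog.at_level("WARNING", logger="pmews"):
        auroc_ci([1, 2, 3, 4], [0, 0, 1, 1], method="bootstrap", n_boot=50, seed=0)
    assert any("replicates" in r.message for r in caplog.records)


def test_confusion_at_cutoff_hand_count():
    cp = confusion_at_cutoff([5, 5, 3, 3], [1, 0, 1, 0], 4)
    assert (cp.tp, cp.fp, cp.fn, cp.tn) == (1, 1, 1, 1)
    assert cp.ppv == 0.5 and cp.npv == 0.5


def test_confusion_counts_sum_and_match_roc_curve():
    rng = np.random.default_rng(29)
    scores, labels = _random_cohort(rng)
    n_pos, n_neg = labels.sum(), (1 - labels).sum()
    pts = {p.threshold: p for p in roc_curve(scores, labels)}
    for cp in cutoff_sweep(scores, labels):
        assert cp.tp + cp.fn == n_pos
        assert cp.tn + cp.fp == n_neg
        assert cp.sensitivity == pytest.approx(pts[cp.cutoff].sensitivity)
        assert cp.specificity == pytest.approx(pts[cp.cutoff].specificity)


def test_cutoff_at_min_score_flags_everyone():
    cp = confusion_at_cutoff([1, 2, 3, 4], [0, 1, 0, 1], 1)
    assert cp.sensitivity == 1.0 and cp.specificity == 0.0


def test_cutoff_outside_range_is_valid_and_warns(caplog):
    with caplog.at_level("WARNING", logger="pmews"):
        cp = confusion_at_cutoff([1, 2, 3], [0, 1, 1], 99)
    assert cp.tp == 0 and cp.fp == 0
    assert any("outside" in r.message for r in caplog.records)


def test_disposal_by_score_counts_and_gaps():
    scores = [0, 0, 2, 2, 2, 5]
    labels = [0, 1, 1, 1, 0, 1]
    tab = disposal_by_score(scores, labels).table
    assert list(tab["score"]) == [0, 2, 5]  # empty levels omitted
    assert tab["n"].sum() == len(scores)
    assert tab["n_needs_ems"].sum() == sum(labels)
    row5 = tab[tab["score"] == 5].iloc[0]
    assert row5["proportion_needs_ems"] == 1.0


def test_youden_matches_exhaustive_search():
    rng = np.random.default_rng(31)
    for _ in range(50):
        scores, labels = _random_cohort(rng, n_max=200)
        pts = roc_curve(scores, labels)
        best = youden_optimal_cutoff(pts)
        js = {p.threshold: p.sensitivity + p.specificity - 1 for p in pts}
        j_max = max(js.values())
        assert js[best] == pytest.approx(j_max)
        # ties break toward the higher cutoff
        assert best == max(t for t, j in js.items() if j == pytest.approx(j_max))


def test_youden_perfect_separation_and_all_tied():
    pts = roc_curve([0, 1, 2, 3], [0, 0, 1, 1])
    assert youden_optimal_cutoff(pts) == 2
    tied = roc_curve([5, 5, 5, 5], [0, 1, 0, 1])
    assert youden_optimal_cutoff(tied) == max(p.threshold for p in tied)
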