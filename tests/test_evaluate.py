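"""ROC/AUC, balancing, vertical averaging, event metrics, statistics."""

import numpy as np
import pytest

from seizurekit.evaluate import (balance_patients, compare_runs,
                                 event_metrics, relative_gain, roc_auc,
                                 threshold_at_sensitivity, vertical_average)


def pairwise_auc(scores, labels):
    """Independent oracle: fraction of correctly ordered (seizure,
    non-seizure) pairs, ties half-weighted."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def test_auc_endpoints():
    scores = np.array([0.1, 0.2, 0.8, 0.9])
    labels = np.array([0, 0, 1, 1])
    assert roc_auc(scores, labels).auc == 1.0
    assert roc_auc(-scores, labels).auc == 0.0


def test_auc_matches_pairwise_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(10, 200))
        scores = np.round(rng.normal(size=n), 1)   # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[:2] = [0, 1]
        got = roc_auc(scores, labels).auc
        assert got == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)


def test_auc_single_class_raises():
    with pytest.raises(ValueError):
        roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))


def test_balance_patients_equalizes_counts(rng):
    # patients with 3 and 5 seizure epochs -> both end with 5
    labels = np.array([1] * 3 + [0] * 10 + [1] * 5 + [0] * 4)
    patients = np.array(["a"] * 13 + ["b"] * 9)
    scores = rng.standard_normal(labels.size)
    bs, bl, bp = balance_patients(scores, labels, patients, seed=0)
    for p in ("a", "b"):
        assert ((bp == p) & (bl == 1)).sum() == 5
        assert ((bp == p) & (bl == 0)).sum() == 10


def test_balance_single_patient_and_idempotence(rng):
    labels = np.array([1, 1, 0, 0, 0])
    patients = np.array(["a"] * 5)
    scores = rng.standard_normal(5)
    bs, bl, bp = balance_patients(scores, labels, patients, seed=0)
    assert np.sort(bs).tolist() == np.sort(scores).tolist()


def test_balancing_neutralizes_seizure_burden(rng):
    """Duplicating one patient's epochs barely moves the balanced AUC."""
    n_per = 40
    scores, labels, patients = [], [], []
    for i, shift in enumerate([1.5, 1.0, 2.0, 0.8]):
        lab = np.array([1] * 10 + [0] * (n_per - 10))
        sc = rng.standard_normal(n_per) + shift * lab
        scores.append(sc); labels.append(lab)
        patients.append(np.full(n_per, f"p{i}"))
    scores = np.concatenate(scores); labels = np.concatenate(labels)
    patients = np.concatenate(patients)
    dup = np.concatenate([scores, scores[patients == "p0"]])
    dup_l = np.concatenate([labels, labels[patients == "p0"]])
    dup_p = np.concatenate([patients, patients[patients == "p0"]])
    aucs, aucs_dup = [], []
    for s in range(20):
        b = balance_patients(scores, labels, patients, seed=s)
        aucs.append(roc_auc(b[0], b[1]).auc)
        bd = balance_patients(dup, dup_l, dup_p, seed=s)
        aucs_dup.append(roc_auc(bd[0], bd[1]).auc)
    assert abs(np.mean(aucs) - np.mean(aucs_dup)) < 0.01


def test_vertical_average_arithmetic():
    import copy
    a = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
    # identical curves average to themselves (on the grid)
    avg = vertical_average([a, a])
    assert np.allclose(avg.sensitivity, vertical_average([a]).sensitivity)
    # two flat curves with sensitivities 0.6 and 0.8 -> 0.7 at the grid point
    grid = np.array([0.9])
    c_lo, c_hi = copy.deepcopy(a), copy.deepcopy(a)
    c_lo.sensitivity = np.full_like(c_lo.sensitivity, 0.6)
    c_hi.sensitivity = np.full_like(c_hi.sensitivity, 0.8)
    avg2 = vertical_average([c_lo, c_hi], grid)
    assert avg2.sensitivity[0] == pytest.approx(0.7)


def test_vertical_average_auc_between_inputs(rng):
    curves = []
    for _ in range(5):
        n = 300
        sc = rng.standard_normal(n)
        lab = rng.integers(0, 2, size=n)
        sc[lab == 1] += rng.uniform(0.5, 2.0)
        curves.append(roc_auc(sc, lab))
    avg = vertical_average(curves)
    aucs = [c.auc for c in curves]
    assert min(aucs) - 0.02 <= avg.auc <= max(aucs) + 0.02


def test_relative_gain_worked_values():
    assert relative_gain(0.8, 0.9) == pytest.approx(50.0)
    assert relative_gain(0.7, 0.7) == 0.0
    assert relative_gain(0.5, 1.0) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        relative_gain(1.0, 1.0)


def brute_force_fd(decisions, seizure_epochs):
    """Enumerate positive segments; count those disjoint from seizures."""
    fd = 0
    in_seg, touches = False, False
    for i, d in enumerate(decisions):
        if d and not in_seg:
            in_seg, touches = True, False
        if d and i in seizure_epochs:
            touches = True
        if not d and in_seg:
            fd += not touches
            in_seg = False
    if in_seg:
        fd += not touches
    return fd


def test_event_metrics_worked_example():
    # 10 epochs of 10 s (stride 10), seizure annotated over epochs 4-6
    starts = np.arange(10) * 10.0
    ann = [(40.0, 70.0)]
    decisions = np.zeros(10, dtype=int)
    decisions[[1, 2, 5, 9]] = 1
    em = event_metrics(decisions, starts, 10.0, ann, record_duration_h=1.0)
    assert em.n_false_detections == 2      # {1,2} and {9}
    assert em.fd_per_hour == 2.0
    assert em.sdr == 1.0                   # epoch 5 overlaps the seizure


def test_event_metrics_edge_cases():
    starts = np.arange(6) * 10.0
    ann = [(10.0, 30.0)]
    em = event_metrics(np.zeros(6, dtype=int), starts, 10.0, ann, 1.0)
    assert em.n_false_detections == 0 and em.sdr == 0.0
    covering = np.array([0, 1, 1, 0, 0, 0])
    em2 = event_metrics(covering, starts, 10.0, ann, 1.0)
    assert em2.n_false_detections == 0 and em2.sdr == 1.0


def test_event_metrics_fd_matches_brute_force(rng):
    starts = np.arange(30) * 10.0
    for _ in range(1000):
        decisions = rng.integers(0, 2, size=30)
        seiz = set(rng.choice(30, size=rng.integers(0, 4),
                              replace=False).tolist())
        ann = [(s * 10.0, s * 10.0 + 10.0) for s in sorted(seiz)]
        em = event_metrics(decisions, starts, 10.0, ann, 1.0)
        assert em.n_false_detections == brute_force_fd(decisions, seiz)


def test_threshold_at_sensitivity(rng):
    scores = np.concatenate([rng.normal(0, 1, 60), rng.normal(2, 1, 40)])
    labels = np.array([0] * 60 + [1] * 40)
    thr = threshold_at_sensitivity(scores, labels, 0.80)
    pos = scores[labels == 1]
    assert (pos >= thr).mean() >= 0.80
    larger = np.unique(scores[scores > thr])
    if larger.size:
        assert (pos >= larger[0]).mean() < 0.80
    # separable case: target 1.0 -> threshold at or below seizure minimum
    sep_s = np.array([0.0, 0.1, 1.0, 1.1])
    sep_l = np.array([0, 0, 1, 1])
    assert threshold_at_sensitivity(sep_s, sep_l, 1.0) <= 1.0


def test_compare_runs_branches(rng):
    a = rng.normal(0, 1, 10)
    same_p = compare_runs(a, a.copy())
    assert same_p[0] == "t-test"
    assert same_p[1] > 0.9
    b = rng.normal(5, 1, 10)
    name, p = compare_runs(a, b)
    assert name == "t-test" and p < 1e-3
    skewed = np.exp(rng.normal(0, 1, 50)) ** 3
    name2, _ = compare_runs(skewed, rng.normal(0, 1, 50))
    assert name2 == "wilcoxon-ranksum"
    with pytest.raises(ValueError):
        compare_runs(a[:2], b)
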