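"""Training-set assembly, standardization, SVM, grid search, SV analysis."""

import numpy as np
import pytest
from scipy.optimize import minimize

from seizurekit.features import FeatureTensor
from seizurekit.model import (GRID_C_DEFAULT, GRID_SIGMA_DEFAULT,
                              TrainingSetSpec, assemble_training_set,
                              derive_seed, fit_standardizer, grid_search,
                              largest_remainder, sv_composition, train_svm)
from seizurekit.preprocess import EpochLabels


def _tensor(pid, cohort, n_epochs=40, n_ch=3, n_feat=4, seizure_frac=0.3,
            seed=0):
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_epochs, n_ch, n_feat))
    labels = np.zeros(n_epochs, dtype=np.int8)
    labels[:int(n_epochs * seizure_frac)] = 1
    values[labels == 1] += 2.0
    return FeatureTensor(values=values, labels=EpochLabels(labels=labels),
                         patient_id=pid, cohort=cohort,
                         channels=[f"c{i}" for i in range(n_ch)],
                         epoch_starts_s=np.arange(n_epochs) * 5.0,
                         epoch_length_s=10.0,
                         duration_s=n_epochs * 5.0 + 5.0)


def test_largest_remainder_sums_and_spreads():
    q = largest_remainder(10, 3)
    assert q.sum() == 10 and set(q) == {3, 4}
    assert np.array_equal(largest_remainder(9, 3), [3, 3, 3])


def test_assembly_quotas_and_shortfall():
    # patient a has 6 seizure FVs available (2 epochs x 3 channels)
    a = _tensor("a", "neo", n_epochs=20, seizure_frac=0.1, seed=1)
    b = _tensor("b", "neo", n_epochs=40, seizure_frac=0.5, seed=2)
    spec = TrainingSetSpec(target_seizure_fvs=20, target_nonseizure_fvs=20,
                           seed=5)
    ts = assemble_training_set([a, b], spec)
    n_a = int(((ts.patient_ids == "a") & (ts.y == 1)).sum())
    n_b = int(((ts.patient_ids == "b") & (ts.y == 1)).sum())
    assert n_a == 6            # all available, shortfall logged
    assert n_b == 10           # full quota
    assert "a" in ts.shortfalls and ts.shortfalls["a"]["seizure"] == 4


def test_assembly_respects_per_channel_cap():
    t = _tensor("a", "neo", n_epochs=200, n_ch=2, seizure_frac=0.5, seed=3)
    b = _tensor("b", "neo", n_epochs=200, n_ch=2, seizure_frac=0.5, seed=4)
    spec = TrainingSetSpec(target_seizure_fvs=400, target_nonseizure_fvs=40,
                           max_seizure_fvs_per_patient_per_channel=24, seed=6)
    ts = assemble_training_set([t, b], spec)
    # at most 24 per channel x 2 channels = 48 seizure FVs per patient
    for pid in ("a", "b"):
        assert ((ts.patient_ids == pid) & (ts.y == 1)).sum() <= 48


def test_assembly_deterministic_under_seed():
    tensors = [_tensor("a", "neo", seed=1), _tensor("b", "neo", seed=2)]
    spec = TrainingSetSpec(target_seizure_fvs=10, target_nonseizure_fvs=10,
                           seed=9)
    t1 = assemble_training_set(tensors, spec)
    t2 = assemble_training_set(tensors, spec)
    assert np.array_equal(t1.X, t2.X)
    t3 = assemble_training_set(
        tensors, TrainingSetSpec(target_seizure_fvs=10,
                                 target_nonseizure_fvs=10, seed=10))
    assert t3.X.shape == t1.X.shape
    assert not np.array_equal(t1.X, t3.X)


def test_standardizer_population_convention_and_guard():
    std = fit_standardizer(np.array([[1.0, 5.0], [3.0, 5.0]]))
    assert np.allclose(std.mean, [2.0, 5.0])
    assert np.allclose(std.sd, [1.0, 1.0])      # population sd; 0 guarded
    z = std.transform(np.array([[1.0, 5.0], [3.0, 5.0]]))
    assert np.allclose(z[:, 0], [-1.0, 1.0])
    assert np.allclose(z[:, 1], 0.0)
    # column equal to the training mean maps to zeros
    assert np.allclose(std.transform(np.array([[2.0, 5.0]])), 0.0)


def _blobs(n=40, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 2))
    y = np.zeros(n, dtype=int)
    y[n // 2:] = 1
    X[y == 1] += gap
    return X, y


def test_svm_separable_blobs():
    X, y = _blobs()
    clf = train_svm(X, y, C=10.0, sigma=2.0)
    assert (clf.svc.predict(X) == y).all()
    assert (clf.decision_values(X[y == 1]) > 0).all()
    # only margin points become SVs: far fewer SVs than training points
    assert clf.sv_labels.size < X.shape[0] // 2


def test_svm_single_class_raises():
    X = np.zeros((5, 2))
    with pytest.raises(ValueError):
        train_svm(X, np.ones(5), 10.0, 2.0)


def test_large_sigma_approaches_linear_separator():
    X, y = _blobs(gap=6.0)
    clf = train_svm(X, y, C=100.0, sigma=500.0)
    assert (clf.svc.predict(X) == y).all()
    # midpoint far along the separating direction stays correctly labelled
    probe = np.array([[10.0, 10.0], [-4.0, -4.0]])
    d = clf.decision_values(probe)
    assert d[0] > 0 > d[1]


def test_svm_matches_reference_qp_solution(rng):
    """Decision values vs an independent dual-QP solve on a toy set."""
    n = 30
    X = rng.standard_normal((n, 2))
    y = np.where(np.arange(n) < n // 2, -1.0, 1.0)
    X[y > 0] += 1.5
    C, sigma = 5.0, 1.5
    gamma = 1.0 / (2 * sigma**2)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-gamma * sq)
    Q = (y[:, None] * y[None, :]) * K

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - np.ones_like(a)

    res = minimize(neg_dual, np.zeros(n), jac=grad, method="SLSQP",
                   bounds=[(0, C)] * n,
                   constraints=[{"type": "eq", "fun": lambda a: a @ y,
                                 "jac": lambda a: y}],
                   options={"maxiter": 5000, "ftol": 1e-16})
    a = res.x
    margin = (a > 1e-6) & (a < C - 1e-6)
    b = np.mean(y[margin] - (a * y) @ K[:, margin])
    ref_decision = (a * y) @ K + b

    clf = train_svm(X, (y > 0).astype(int), C, sigma, tol=1e-9)
    got = clf.decision_values(X)
    assert np.allclose(got, ref_decision, atol=1e-6)


def test_grid_search_single_cell_and_tie_break():
    X, y = _blobs(gap=8.0, seed=2)
    pids = np.array(["p%d" % (i % 6) for i in range(len(y))])
    assert grid_search(X, y, pids, C_grid=[40.0], sigma_grid=[7.0]) == (40.0,
                                                                        7.0)
    # trivially separable data: every cell reaches AUC 1 -> smallest (C, s)
    C, s = grid_search(X, y, pids)
    assert (C, s) == (min(GRID_C_DEFAULT), min(GRID_SIGMA_DEFAULT))


def test_grid_search_matches_exhaustive_oracle(rng):
    """The selected cell equals the argmax of an independently computed
    fold-AUC surface with the same tie rule."""
    from seizurekit.evaluate import roc_auc
    from seizurekit.model import _grouped_folds
    from sklearn.svm import SVC
    n = 80
    X = rng.standard_normal((n, 3))
    y = rng.integers(0, 2, size=n)
    X[y == 1, 0] += 1.0
    pids = np.array(["p%d" % (i % 8) for i in range(n)])
    C_grid, s_grid = [1.0, 10.0], [0.5, 2.0, 8.0]
    got = grid_search(X, y, pids, C_grid, s_grid)

    best = (-np.inf, None)
    for C in sorted(C_grid):
        for s in sorted(s_grid):
            aucs = []
            for tr, te in _grouped_folds(pids, 5):
                if len(set(y[tr])) < 2 or len(set(y[te])) < 2:
                    continue
                m = SVC(C=C, kernel="rbf", gamma=1 / (2 * s**2)).fit(X[tr],
                                                                     y[tr])
                aucs.append(roc_auc(m.decision_function(X[te]), y[te]).auc)
            score = np.mean(aucs) if aucs else -np.inf
            if score > best[0] + 1e-12:
                best = (score, (C, s))
    assert got == best[1]


def test_sv_composition_fractions():
    X, y = _blobs(n=60, gap=2.0, seed=4)
    cohorts = np.array(["neo"] * 30 + ["adult"] * 30)
    pids = np.array(["p%d" % (i % 10) for i in range(60)])
    clf = train_svm(X, y, 10.0, 2.0, patient_ids=pids, cohorts=cohorts)
    comp = sv_composition(clf)
    assert sum(comp["by_cohort"].values()) == pytest.approx(1.0)
    assert sum(comp["by_cohort_class"].values()) == pytest.approx(1.0)
    for frac in comp["became_sv"].values():
        assert 0.0 <= frac <= 1.0


def test_sv_composition_single_cohort_and_overlap_ordering(rng):
    # single cohort -> 100 % of SVs from it
    X, y = _blobs(seed=5)
    clf = train_svm(X, y, 10.0, 2.0,
                    cohorts=np.array(["neo"] * len(y)))
    comp = sv_composition(clf)
    assert comp["by_cohort"] == {"neo": 1.0}

    # cohort A's classes overlap more -> A supplies more SVs
    nA = nB = 40
    XA = rng.standard_normal((nA, 2))
    yA = np.arange(nA) % 2
    XA[yA == 1] += 0.7          # heavy overlap
    XB = rng.standard_normal((nB, 2))
    yB = np.arange(nB) % 2
    XB[yB == 1] += 6.0          # clean separation
    X = np.vstack([XA, XB])
    y = np.concatenate([yA, yB])
    cohorts = np.array(["A"] * nA + ["B"] * nB)
    clf = train_svm(X, y, 10.0, 2.0, cohorts=cohorts)
    comp = sv_composition(clf)
    assert comp["by_cohort"]["A"] > comp["by_cohort"]["B"]


def test_sv_composition_requires_provenance():
    X, y = _blobs()
    clf = train_svm(X, y, 10.0, 2.0)
    with pytest.raises(ValueError):
        sv_composition(clf)


def test_derive_seed_stable_and_bounded():
    assert derive_seed(1, 2, 3) == derive_seed(1, 2, 3)
    assert derive_seed(1, 2, 3) != derive_seed(1, 3, 2)
    for s in range(20):
        assert 0 <= derive_seed(s, 7) < 2**31
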