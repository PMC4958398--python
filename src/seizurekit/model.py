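"""Training-set assembly, Gaussian-SVM training and evaluation protocols.

Training sets are assembled so that every patient contributes equally
(largest-remainder quotas), with seizure feature vectors capped at 24 per
patient per channel, mirroring routine-registration class balances.  The
classifier is a soft-margin SVM with Gaussian kernel
``k(u, v) = exp(-||u - v||^2 / (2 sigma^2))``; features are standardized to
zero mean / unit sd with training-set parameters only.  Protocols:
leave-one-patient-out cross-validation (no information from the test patient
enters any fitted component), single-classifier cross-cohort testing, and
Monte-Carlo repetition of the whole procedure over freshly sampled training
sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .features import FeatureTensor

__all__ = [
    "TrainingSetSpec",
    "TrainingSet",
    "Standardizer",
    "SeizureClassifier",
    "GRID_C_DEFAULT",
    "GRID_SIGMA_DEFAULT",
    "TABLE_PRESETS",
    "largest_remainder",
    "assemble_training_set",
    "fit_standardizer",
    "train_svm",
    "grid_search",
    "sv_composition",
    "derive_seed",
]

logger = logging.getLogger(__name__)

GRID_C_DEFAULT = (10.0, 20.0, 40.0, 50.0, 100.0)
GRID_SIGMA_DEFAULT = (4.0, 5.0, 6.0, 7.0, 8.0, 9.0)

#: published (C, sigma) optima per train/test scenario, usable as presets
TABLE_PRESETS = {
    ("adult", "adult"): (40.0, 7.0),
    ("neo", "adult"): (40.0, 5.0),
    ("combi", "adult"): (50.0, 6.0),
    ("adult", "neo"): (20.0, 8.0),
    ("neo", "neo"): (20.0, 8.0),
    ("combi", "neo"): (50.0, 6.0),
}


def derive_seed(master_seed: int, *indices: int) -> int:
    """Deterministic splitmix64-style child seed, kept below 2**31."""
    z = (master_seed & 0xFFFFFFFFFFFFFFFF) + 0x9E3779B97F4A7C15
    for idx in indices:
        z = (z + (idx + 1) * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
        z = z ^ (z >> 31)
    return int(z % (2**31))


@dataclass(frozen=True)
class TrainingSetSpec:
    """Target composition of one randomly sampled training set."""

    target_seizure_fvs: int = 4500
    target_nonseizure_fvs: int = 9000
    max_seizure_fvs_per_patient_per_channel: int = 24
    seed: int = 0


@dataclass
class TrainingSet:
    """Labelled feature-vector matrix with per-row provenance."""

    X: np.ndarray                     # n x 103
    y: np.ndarray                     # n, 1 = seizure
    patient_ids: np.ndarray           # n, str
    cohorts: np.ndarray               # n, str
    shortfalls: dict = field(default_factory=dict)


def largest_remainder(total: int, n_parts: int) -> np.ndarray:
    """Split ``total`` into ``n_parts`` near-equal integer quotas.

    The remainder goes to the first parts (deterministic allocation)."""
    base, rem = divmod(total, n_parts)
    quotas = np.full(n_parts, base, dtype=int)
    quotas[:rem] += 1
    return quotas


def _patient_rows(tensors: list[FeatureTensor]):
    """Group flattened (epoch x channel) rows by patient."""
    per_patient: dict[str, dict] = {}
    for t in tensors:
        e, c, f = t.values.shape
        flat = t.values.reshape(e * c, f)
        labels = np.repeat(t.labels.labels, c)
        channels = np.tile(np.arange(c), e)
        d = per_patient.setdefault(
            t.patient_id, {"X": [], "y": [], "ch": [], "cohort": t.cohort})
        d["X"].append(flat)
        d["y"].append(labels)
        d["ch"].append(channels)
    for d in per_patient.values():
        d["X"] = np.vstack(d["X"])
        d["y"] = np.concatenate(d["y"])
        d["ch"] = np.concatenate(d["ch"])
    return per_patient


def assemble_training_set(tensors: list[FeatureTensor],
                          spec: TrainingSetSpec) -> TrainingSet:
    """Randomly sample a training set with equal per-patient contributions.

    Per-patient quotas are largest-remainder shares of the targets; seizure
    draws are additionally capped at ``max_seizure_fvs_per_patient_per_channel``
    per channel.  Sampling is without replacement within a patient and fully
    reproducible from ``spec.seed``.  Infeasible quotas take all available
    rows and record the shortfall.
    """
    per_patient = _patient_rows(tensors)
    patients = sorted(per_patient)
    n_pat = len(patients)
    rng = np.random.default_rng(spec.seed)
    quotas_s = largest_remainder(spec.target_seizure_fvs, n_pat)
    quotas_ns = largest_remainder(spec.target_nonseizure_fvs, n_pat)

    xs, ys, pids, cohs = [], [], [], []
    shortfalls: dict[str, dict] = {}
    cap = spec.max_seizure_fvs_per_patient_per_channel
    for p, q_s, q_ns in zip(patients, quotas_s, quotas_ns):
        d = per_patient[p]
        seiz_idx = np.where(d["y"] == 1)[0]
        ns_idx = np.where(d["y"] == 0)[0]

        # seizure rows: random order, greedy take under the per-channel cap
        order = rng.permutation(seiz_idx)
        taken: list[int] = []
        ch_counts: dict[int, int] = {}
        for idx in order:
            if len(taken) >= q_s:
                break
            ch = int(d["ch"][idx])
            if ch_counts.get(ch, 0) >= cap:
                continue
            ch_counts[ch] = ch_counts.get(ch, 0) + 1
            taken.append(idx)
        n_ns_take = min(q_ns, ns_idx.size)
        ns_take = rng.choice(ns_idx, size=n_ns_take, replace=False)

        if len(taken) < q_s or n_ns_take < q_ns:
            shortfalls[p] = {"seizure": q_s - len(taken),
                             "nonseizure": q_ns - n_ns_take}
            logger.info("training-set shortfall for %s: %s", p, shortfalls[p])

        sel = np.concatenate([np.array(taken, dtype=int), ns_take])
        xs.append(d["X"][sel])
        ys.append(d["y"][sel])
        pids.append(np.full(sel.size, p, dtype=object))
        cohs.append(np.full(sel.size, d["cohort"], dtype=object))

    return TrainingSet(X=np.vstack(xs), y=np.concatenate(ys),
                       patient_ids=np.concatenate(pids),
                       cohorts=np.concatenate(cohs),
                       shortfalls=shortfalls)


@dataclass
class Standardizer:
    """Per-feature mean/sd (population sd), fitted on training data only."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def fit_standardizer(X: np.ndarray) -> Standardizer:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    guarded = np.where(sd > 0, sd, 1.0)
    if (sd == 0).any():
        logger.info("standardizer: %d constant features, sd guarded to 1",
                    int((sd == 0).sum()))
    return Standardizer(mean=mean, sd=guarded)


@dataclass
class SeizureClassifier:
    """Trained Gaussian-kernel SVM plus its training provenance.

    ``decision_values`` returns the signed distance from the decision
    surface (positive = seizure side); inputs must already be standardized
    with ``standardizer``.
    """

    svc: SVC
    C: float
    sigma: float
    standardizer: Standardizer
    sv_patient_ids: np.ndarray
    sv_cohorts: np.ndarray
    sv_labels: np.ndarray
    train_cohorts: np.ndarray
    train_labels: np.ndarray

    def decision_values(self, X_std: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(X_std)


def train_svm(X_std: np.ndarray, y: np.ndarray, C: float, sigma: float,
              patient_ids: np.ndarray | None = None,
              cohorts: np.ndarray | None = None,
              standardizer: Standardizer | None = None,
              tol: float = 1e-3) -> SeizureClassifier:
    """Fit the soft-margin Gaussian-kernel SVM on standardized data."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    gamma = 1.0 / (2.0 * sigma**2)
    svc = SVC(C=C, kernel="rbf", gamma=gamma, tol=tol)
    svc.fit(X_std, y)
    n = X_std.shape[0]
    if patient_ids is None:
        patient_ids = np.full(n, "", dtype=object)
    if cohorts is None:
        cohorts = np.full(n, "", dtype=object)
    sv = svc.support_
    return SeizureClassifier(
        svc=svc, C=C, sigma=sigma,
        standardizer=standardizer if standardizer is not None
        else Standardizer(np.zeros(X_std.shape[1]), np.ones(X_std.shape[1])),
        sv_patient_ids=np.asarray(patient_ids)[sv],
        sv_cohorts=np.asarray(cohorts)[sv],
        sv_labels=y[sv],
        train_cohorts=np.asarray(cohorts),
        train_labels=y,
    )


def _grouped_folds(patient_ids: np.ndarray, n_splits: int):
    """Patient-grouped folds: patients are split, not rows."""
    patients = np.unique(patient_ids)
    n_splits = min(n_splits, patients.size)
    folds = [[] for _ in range(n_splits)]
    for i, p in enumerate(patients):
        folds[i % n_splits].append(p)
    for held in folds:
        test_mask = np.isin(patient_ids, held)
        yield ~test_mask, test_mask


def grid_search(X_std: np.ndarray, y: np.ndarray, patient_ids: np.ndarray,
                C_grid=GRID_C_DEFAULT, sigma_grid=GRID_SIGMA_DEFAULT,
                n_splits: int = 5) -> tuple[float, float]:
    """Select (C, sigma) maximizing inner patient-grouped CV AUC.

    Ties are broken by smaller C, then smaller sigma (grids are scanned in
    ascending order and only strict improvements replace the incumbent).
    """
    from .evaluate import roc_auc
    if len(C_grid) == 0 or len(sigma_grid) == 0:
        raise ValueError("grids must be non-empty")
    folds = list(_grouped_folds(patient_ids, n_splits))
    best = (-np.inf, None, None)
    for C in sorted(C_grid):
        for sigma in sorted(sigma_grid):
            aucs = []
            for train_mask, test_mask in folds:
                ytr, yte = y[train_mask], y[test_mask]
                if np.unique(ytr).size < 2 or np.unique(yte).size < 2:
                    continue
                clf = SVC(C=C, kernel="rbf", gamma=1.0 / (2 * sigma**2))
                clf.fit(X_std[train_mask], ytr)
                scores = clf.decision_function(X_std[test_mask])
                aucs.append(roc_auc(scores, yte).auc)
            score = float(np.mean(aucs)) if aucs else -np.inf
            if score > best[0] + 1e-12:
                best = (score, C, sigma)
    if best[1] is None:
        raise ValueError("no valid grid cell (single-class folds everywhere)")
    return best[1], best[2]


def sv_composition(classifier: SeizureClassifier) -> dict:
    """Support-vector composition by cohort and by (cohort, class).

    Returns cohort fractions of the SVs (summing to 1), per (cohort, class)
    fractions, and for each training subset the fraction of its feature
    vectors that became support vectors.
    """
    if (classifier.sv_cohorts == "").any():
        raise ValueError("classifier has no cohort provenance")
    sv_coh = classifier.sv_cohorts
    n_sv = sv_coh.size
    out = {"by_cohort": {}, "by_cohort_class": {}, "became_sv": {}}
    for coh in np.unique(classifier.train_cohorts):
        out["by_cohort"][str(coh)] = float((sv_coh == coh).sum() / n_sv)
        for cls in (0, 1):
            key = (str(coh), int(cls))
            sv_n = int(((sv_coh == coh) & (classifier.sv_labels == cls)).sum())
            out["by_cohort_class"][key] = sv_n / n_sv
            train_n = int(((classifier.train_cohorts == coh)
                           & (classifier.train_labels == cls)).sum())
            out["became_sv"][key] = sv_n / train_n if train_n else 0.0
    return out
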