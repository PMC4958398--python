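"""End-to-end experimental protocols.

Wires the stages into the full evaluation matrix: three training
compositions (neo, adult, combi) x two test cohorts x {FBC, no FBC}, with
leave-one-patient-out cross-validation whenever the test cohort contributes
to training and single-classifier cross-cohort testing otherwise, all
repeated over Monte-Carlo resamplings of the training set.  Per-run
epoch-based (patient-balanced AUC) and event-based (FD/h at 80 % epoch
sensitivity, SDR) metrics are produced, plus vertically averaged ROC curves
and relative-gain summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import fbc as fbc_mod
from .evaluate import (ROCCurve, balance_patients, event_metrics,
                       relative_gain, roc_auc, threshold_at_sensitivity,
                       vertical_average)
from .features import FeatureTensor, extract_tensor
from .model import (TABLE_PRESETS, SeizureClassifier, TrainingSetSpec,
                    assemble_training_set, derive_seed, fit_standardizer,
                    grid_search, train_svm)
from .postprocess import KalmanParams, postprocess_scores
from .preprocess import make_epochs, preprocess_recording
from .synthetic import CohortConfig, generate_cohort

__all__ = [
    "PipelineConfig",
    "PatientScores",
    "FittedPipeline",
    "extract_cohort_tensors",
    "fit_pipeline",
    "score_tensor",
    "loo_crossval",
    "cross_cohort",
    "monte_carlo",
    "run_matrix",
    "CellResult",
    "MatrixReport",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to train and apply one classifier."""

    fbc: bool = True
    C: float | None = None
    sigma: float | None = None
    grid_search: bool = False
    training_spec: TrainingSetSpec = field(default_factory=TrainingSetSpec)
    kalman: KalmanParams = field(default_factory=KalmanParams)
    filter_ranks: str = "all"
    baseline_epochs: int = fbc_mod.DEFAULT_BASELINE_EPOCHS


@dataclass
class PatientScores:
    """Multi-channel epoch scores of one test recording."""

    patient_id: str
    scores: np.ndarray
    labels: np.ndarray
    epoch_starts_s: np.ndarray
    epoch_length_s: float
    duration_s: float
    annotations: list


@dataclass
class FittedPipeline:
    classifier: SeizureClassifier
    fbc_model: "fbc_mod.FBCModel | None"
    config: PipelineConfig


def extract_cohort_tensors(config: CohortConfig,
                           records_per_patient: int = 1
                           ) -> list[FeatureTensor]:
    """Generate, preprocess and featurize a whole synthetic cohort."""
    tensors = []
    for rec in generate_cohort(config, records_per_patient):
        pre = preprocess_recording(rec)
        grid = make_epochs(pre)
        tensors.append(extract_tensor(pre, grid))
    return tensors


def _by_patient(tensors: list[FeatureTensor]) -> dict[str, list[FeatureTensor]]:
    out: dict[str, list[FeatureTensor]] = {}
    for t in tensors:
        out.setdefault(t.patient_id, []).append(t)
    return out


class _ThresholdCache:
    """Memoizes annotation-derived thresholds per (patient, orientation).

    The thresholds depend only on the patient's own tensor and the global
    feature orientation, so they can be shared across LOO folds and
    Monte-Carlo runs without any information crossing patients.
    """

    def __init__(self) -> None:
        self._store: dict = {}

    def get(self, tensor: FeatureTensor, sign: np.ndarray) -> np.ndarray:
        key = (tensor.patient_id, tensor.record_index, sign.tobytes())
        if key not in self._store:
            self._store[key] = fbc_mod.training_thresholds(tensor, sign)
        return self._store[key]


def fit_pipeline(train_tensors: list[FeatureTensor], config: PipelineConfig,
                 seed: int,
                 threshold_cache: _ThresholdCache | None = None
                 ) -> FittedPipeline:
    """Fit FBC (optionally), the standardizer and the SVM on training
    patients only."""
    fbc_model = None
    used = train_tensors
    if config.fbc:
        sign = fbc_mod.fit_orientation(train_tensors)
        baselines = {t.patient_id: fbc_mod.compute_baseline(
            t, n_epochs=config.baseline_epochs) for t in train_tensors}
        if threshold_cache is not None:
            # pre-populate via the cache so folds share patient thresholds
            for t in train_tensors:
                threshold_cache.get(t, sign)
        fbc_model = _fit_fbc_cached(train_tensors, baselines, sign,
                                    threshold_cache)
        used = [fbc_mod.apply_fbc(t, baselines[t.patient_id], fbc_model,
                                  mode="train") for t in train_tensors]
    spec = TrainingSetSpec(
        target_seizure_fvs=config.training_spec.target_seizure_fvs,
        target_nonseizure_fvs=config.training_spec.target_nonseizure_fvs,
        max_seizure_fvs_per_patient_per_channel=(
            config.training_spec.max_seizure_fvs_per_patient_per_channel),
        seed=seed,
    )
    ts = assemble_training_set(used, spec)
    std = fit_standardizer(ts.X)
    X_std = std.transform(ts.X)
    if config.grid_search or config.C is None or config.sigma is None:
        C, sigma = grid_search(X_std, ts.y, ts.patient_ids)
    else:
        C, sigma = config.C, config.sigma
    clf = train_svm(X_std, ts.y, C, sigma, patient_ids=ts.patient_ids,
                    cohorts=ts.cohorts, standardizer=std)
    return FittedPipeline(classifier=clf, fbc_model=fbc_model, config=config)


def _fit_fbc_cached(tensors, baselines, sign, cache):
    """fit_fbc, but drawing each patient's thresholds through the cache."""
    if cache is None:
        return fbc_mod.fit_fbc(tensors, baselines, sign)
    ans_pts, tr_pts = [], []
    for t in tensors:
        base = baselines[t.patient_id]
        tr = cache.get(t, sign)
        ans_oriented = base.ans * sign[None, :]
        ok = np.isfinite(tr).all(axis=1)
        if ok.any():
            ans_pts.append(ans_oriented[ok])
            tr_pts.append(tr[ok])
    if not ans_pts:
        raise ValueError("no (aNS, Tr) points in the training cohort")
    return _ols_fbc(np.vstack(ans_pts), np.vstack(tr_pts), sign)


def _ols_fbc(A: np.ndarray, T: np.ndarray, sign: np.ndarray):
    n_feat = A.shape[1]
    slope = np.ones(n_feat)
    intercept = np.zeros(n_feat)
    r2 = np.zeros(n_feat)
    for f in range(n_feat):
        a, t_ = A[:, f], T[:, f]
        if np.unique(a).size < 2:
            slope[f], intercept[f] = 0.0, float(t_.mean())
            continue
        coef = np.polyfit(a, t_, 1)
        slope[f], intercept[f] = float(coef[0]), float(coef[1])
        pred = slope[f] * a + intercept[f]
        ss_tot = float(np.sum((t_ - t_.mean()) ** 2))
        r2[f] = 1.0 - float(np.sum((t_ - pred) ** 2)) / ss_tot \
            if ss_tot > 0 else 1.0
    return fbc_mod.FBCModel(slope=slope, intercept=intercept, sign=sign,
                            r_squared=r2,
                            n_points=np.full(n_feat, A.shape[0]))


def score_tensor(tensor: FeatureTensor, pipeline: FittedPipeline
                 ) -> PatientScores:
    """Apply the fitted pipeline to one (held-out) recording tensor."""
    values = tensor.values
    if pipeline.fbc_model is not None:
        baseline = fbc_mod.compute_baseline(
            tensor, n_epochs=pipeline.config.baseline_epochs)
        corrected = fbc_mod.apply_fbc(tensor, baseline, pipeline.fbc_model,
                                      mode="test")
        values = corrected.values
    e, c, f = values.shape
    X_std = pipeline.classifier.standardizer.transform(values.reshape(-1, f))
    raw = pipeline.classifier.decision_values(X_std).reshape(e, c)
    series = postprocess_scores(raw, pipeline.config.kalman,
                                pipeline.config.filter_ranks)
    return PatientScores(
        patient_id=tensor.patient_id,
        scores=series.multichannel,
        labels=tensor.labels.labels.copy(),
        epoch_starts_s=tensor.epoch_starts_s.copy(),
        epoch_length_s=tensor.epoch_length_s,
        duration_s=tensor.duration_s,
        annotations=list(tensor.annotations),
    )


def loo_crossval(train_tensors: list[FeatureTensor],
                 config: PipelineConfig, seed: int,
                 extra_train: list[FeatureTensor] | None = None,
                 threshold_cache: _ThresholdCache | None = None,
                 return_pipelines: bool = False):
    """Leave-one-patient-out: one classifier per held-out patient.

    ``extra_train`` tensors (e.g. the other cohort in combined training)
    participate in every fold's training but are never tested.  The held-out
    patient's data enter no fitted component.  With ``return_pipelines`` the
    per-fold fitted pipelines are returned alongside the scores, keyed by the
    held-out patient.
    """
    groups = _by_patient(train_tensors)
    patients = sorted(groups)
    if len(patients) < 2:
        raise ValueError("LOO requires at least 2 patients")
    extra = list(extra_train) if extra_train else []
    out: list[PatientScores] = []
    pipelines: dict[str, FittedPipeline] = {}
    for i, held in enumerate(patients):
        fold_train = [t for p in patients if p != held for t in groups[p]]
        pipeline = fit_pipeline(fold_train + extra, config,
                                derive_seed(seed, i),
                                threshold_cache=threshold_cache)
        pipelines[held] = pipeline
        for t in groups[held]:
            out.append(score_tensor(t, pipeline))
    if return_pipelines:
        return out, pipelines
    return out


def cross_cohort(train_tensors: list[FeatureTensor],
                 test_tensors: list[FeatureTensor],
                 config: PipelineConfig, seed: int,
                 threshold_cache: _ThresholdCache | None = None
                 ) -> list[PatientScores]:
    """Single classifier trained on one dataset, tested on the other."""
    pipeline = fit_pipeline(train_tensors, config, seed,
                            threshold_cache=threshold_cache)
    return [score_tensor(t, pipeline) for t in test_tensors]


@dataclass
class RunResult:
    auc: float
    curve: ROCCurve
    fd_per_hour: float
    sdr: float
    operating_threshold: float


def evaluate_scores(scored: list[PatientScores], seed: int,
                    sensitivity_target: float = 0.80) -> RunResult:
    """Patient-balanced AUC plus event metrics at the 80 %-sensitivity
    operating point, from the per-recording score series of one run."""
    scores = np.concatenate([s.scores for s in scored])
    labels = np.concatenate([s.labels for s in scored])
    patients = np.concatenate(
        [np.full(s.scores.size, s.patient_id, dtype=object) for s in scored])
    b_scores, b_labels, _ = balance_patients(scores, labels, patients, seed)
    curve = roc_auc(b_scores, b_labels)
    thr = threshold_at_sensitivity(scores, labels, sensitivity_target)
    n_fd = 0
    total_h = 0.0
    n_seiz = n_det = 0
    for s in scored:
        em = event_metrics(s.scores >= thr, s.epoch_starts_s,
                           s.epoch_length_s, s.annotations,
                           s.duration_s / 3600.0, thr)
        n_fd += em.n_false_detections
        n_seiz += em.n_seizures
        n_det += em.n_detected
        total_h += s.duration_s / 3600.0
    return RunResult(
        auc=curve.auc, curve=curve,
        fd_per_hour=n_fd / total_h if total_h > 0 else 0.0,
        sdr=n_det / n_seiz if n_seiz else 0.0,
        operating_threshold=thr,
    )


def monte_carlo(run_fn, n_runs: int = 10, master_seed: int = 0) -> list:
    """Repeat a seeded experiment; run r receives derive_seed(master, r)."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    return [run_fn(derive_seed(master_seed, r)) for r in range(n_runs)]


# ------------------------------------------------------------ full matrix

@dataclass
class CellResult:
    """One (training composition, test cohort, FBC) cell of the matrix."""

    train: str
    test: str
    fbc: bool
    C: float
    sigma: float
    auc_runs: list[float]
    fd_per_hour_runs: list[float]
    sdr_runs: list[float]
    mean_auc: float
    sd_auc: float
    average_curve: ROCCurve

    def summary(self) -> dict:
        return {
            "train": self.train, "test": self.test, "fbc": self.fbc,
            "C": self.C, "sigma": self.sigma,
            "mean_auc": self.mean_auc, "sd_auc": self.sd_auc,
            "mean_fd_per_hour": float(np.mean(self.fd_per_hour_runs)),
            "mean_sdr": float(np.mean(self.sdr_runs)),
        }


@dataclass
class MatrixReport:
    cells: list[CellResult]
    relative_gains: dict
    master_seed: int

    def cell(self, train: str, test: str, fbc: bool) -> CellResult:
        for c in self.cells:
            if (c.train, c.test, c.fbc) == (train, test, fbc):
                return c
        raise KeyError((train, test, fbc))

    def to_table(self):
        import pandas as pd
        return pd.DataFrame([c.summary() for c in self.cells])


def run_matrix(cohort_tensors: dict[str, list[FeatureTensor]],
               base_config: PipelineConfig | None = None,
               n_monte_carlo: int = 10, master_seed: int = 0,
               compositions=("neo", "adult", "combi"),
               use_presets: bool = True) -> MatrixReport:
    """Run the 3 training compositions x 2 test cohorts x {FBC, no FBC}
    matrix (12 cells) with Monte-Carlo repetition.

    ``cohort_tensors`` maps cohort name ("neo", "adult") to its feature
    tensors.  When the test cohort is part of the training composition, LOO
    is used (the other cohort, if present, joins every fold's training);
    otherwise a single cross-cohort classifier is trained per run.
    """
    if base_config is None:
        base_config = PipelineConfig()
    names = sorted(cohort_tensors)
    cache = _ThresholdCache()
    cells: list[CellResult] = []
    for comp_i, comp in enumerate(compositions):
        train_names = names if comp == "combi" else [comp]
        for test_i, test in enumerate(names):
            for fbc_on in (False, True):
                C, sigma = base_config.C, base_config.sigma
                if use_presets and (C is None or sigma is None):
                    C, sigma = TABLE_PRESETS.get((comp, test), (50.0, 6.0))
                cfg = PipelineConfig(
                    fbc=fbc_on, C=C, sigma=sigma,
                    grid_search=base_config.grid_search,
                    training_spec=base_config.training_spec,
                    kalman=base_config.kalman,
                    filter_ranks=base_config.filter_ranks,
                    baseline_epochs=base_config.baseline_epochs,
                )
                cell_seed = derive_seed(master_seed, comp_i, test_i,
                                        int(fbc_on))

                def one_run(seed, _cfg=cfg, _test=test,
                            _train_names=train_names):
                    test_t = cohort_tensors[_test]
                    if _test in _train_names:
                        extra = [t for n in _train_names if n != _test
                                 for t in cohort_tensors[n]]
                        scored = loo_crossval(test_t, _cfg, seed,
                                              extra_train=extra,
                                              threshold_cache=cache)
                    else:
                        train_t = [t for n in _train_names
                                   for t in cohort_tensors[n]]
                        scored = cross_cohort(train_t, test_t, _cfg, seed,
                                              threshold_cache=cache)
                    return evaluate_scores(scored, derive_seed(seed, 999))

                runs = monte_carlo(one_run, n_monte_carlo, cell_seed)
                aucs = [r.auc for r in runs]
                cells.append(CellResult(
                    train=comp, test=test, fbc=fbc_on, C=C, sigma=sigma,
                    auc_runs=aucs,
                    fd_per_hour_runs=[r.fd_per_hour for r in runs],
                    sdr_runs=[r.sdr for r in runs],
                    mean_auc=float(np.mean(aucs)),
                    sd_auc=float(np.std(aucs)),
                    average_curve=vertical_average([r.curve for r in runs]),
                ))
    report = MatrixReport(cells=cells, relative_gains={}, master_seed=master_seed)
    for comp in compositions:
        for test in names:
            no = report.cell(comp, test, False).mean_auc
            yes = report.cell(comp, test, True).mean_auc
            if no < 1.0:
                report.relative_gains[f"{comp}->{test}"] = relative_gain(no, yes)
    return report
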