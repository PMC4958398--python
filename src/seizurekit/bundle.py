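"""Versioned serialization of a fitted pipeline.

A bundle is a single ``.npz`` archive holding the SVM dual solution, the
standardizer, the optional FBC model and a JSON metadata blob, so an
evaluation can be reproduced without retraining.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .experiment import FittedPipeline, PipelineConfig
from .fbc import FBCModel
from .model import SeizureClassifier, Standardizer, TrainingSetSpec
from .postprocess import KalmanParams

BUNDLE_VERSION = "1"

__all__ = ["save_bundle", "load_bundle", "BUNDLE_VERSION"]


def save_bundle(pipeline: FittedPipeline, path: str | Path) -> Path:
    path = Path(path)
    clf = pipeline.classifier
    svc = clf.svc
    meta = {
        "version": BUNDLE_VERSION,
        "C": clf.C,
        "sigma": clf.sigma,
        "fbc": pipeline.fbc_model is not None,
        "config": {
            "filter_ranks": pipeline.config.filter_ranks,
            "baseline_epochs": pipeline.config.baseline_epochs,
            "kalman_q": pipeline.config.kalman.process_variance,
            "kalman_r": pipeline.config.kalman.measurement_variance,
        },
    }
    arrays = {
        "support_vectors": svc.support_vectors_,
        "dual_coef": svc.dual_coef_,
        "intercept": svc.intercept_,
        "classes": svc.classes_,
        "n_support": svc.n_support_,
        "std_mean": clf.standardizer.mean,
        "std_sd": clf.standardizer.sd,
        "sv_patient_ids": clf.sv_patient_ids.astype(str),
        "sv_cohorts": clf.sv_cohorts.astype(str),
        "sv_labels": clf.sv_labels,
        "train_cohorts": clf.train_cohorts.astype(str),
        "train_labels": clf.train_labels,
        "meta_json": np.array(json.dumps(meta)),
    }
    if pipeline.fbc_model is not None:
        m = pipeline.fbc_model
        arrays.update(fbc_slope=m.slope, fbc_intercept=m.intercept,
                      fbc_sign=m.sign, fbc_r2=m.r_squared,
                      fbc_n_points=m.n_points)
    np.savez(path, **arrays)
    return path


class _FrozenSVM:
    """Decision-function-only SVM rebuilt from a stored dual solution:
    f(x) = sum_i dual_coef_i * exp(-gamma ||sv_i - x||^2) + b."""

    def __init__(self, support_vectors: np.ndarray, dual_coef: np.ndarray,
                 intercept: float, gamma: float) -> None:
        self.support_vectors_ = support_vectors
        self.dual_coef_ = dual_coef
        self.intercept_ = float(intercept)
        self.gamma = gamma
        self.support_ = np.arange(support_vectors.shape[0])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        sq = (np.sum(X**2, axis=1)[:, None]
              + np.sum(self.support_vectors_**2, axis=1)[None, :]
              - 2.0 * X @ self.support_vectors_.T)
        K = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return K @ self.dual_coef_.ravel() + self.intercept_


def load_bundle(path: str | Path) -> FittedPipeline:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta_json"]))
        gamma = 1.0 / (2.0 * meta["sigma"] ** 2)
        svc = _FrozenSVM(data["support_vectors"], data["dual_coef"],
                         float(data["intercept"][0]), gamma)
        std = Standardizer(mean=data["std_mean"], sd=data["std_sd"])
        clf = SeizureClassifier(
            svc=svc, C=float(meta["C"]), sigma=float(meta["sigma"]),
            standardizer=std,
            sv_patient_ids=data["sv_patient_ids"],
            sv_cohorts=data["sv_cohorts"],
            sv_labels=data["sv_labels"],
            train_cohorts=data["train_cohorts"],
            train_labels=data["train_labels"],
        )
        fbc_model = None
        if meta["fbc"]:
            fbc_model = FBCModel(
                slope=data["fbc_slope"], intercept=data["fbc_intercept"],
                sign=data["fbc_sign"], r_squared=data["fbc_r2"],
                n_points=data["fbc_n_points"])
        cfg = PipelineConfig(
            fbc=meta["fbc"], C=meta["C"], sigma=meta["sigma"],
            training_spec=TrainingSetSpec(),
            kalman=KalmanParams(
                process_variance=meta["config"]["kalman_q"],
                measurement_variance=meta["config"]["kalman_r"]),
            filter_ranks=meta["config"]["filter_ranks"],
            baseline_epochs=meta["config"]["baseline_epochs"],
        )
    return FittedPipeline(classifier=clf, fbc_model=fbc_model, config=cfg)
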