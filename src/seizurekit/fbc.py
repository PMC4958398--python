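"""Feature baseline correction (FBC).

Per-patient, per-channel normalization that subtracts an estimated optimal
single-feature detection threshold (Tr) from each feature value.  In the
training phase, for channels that contain seizure epochs, Tr is computed
from the annotations as the threshold maximizing Youden's J.  For nearly
every feature a linear relation holds between Tr and the average non-seizure
feature value (aNS) computed over a few baseline epochs from the start of
the recording; this relation is fitted by ordinary least squares on the
training patients and used at test time to estimate Tr from aNS alone.  The
aim is that, after correction, the optimal detection threshold is the same
(approximately zero) for every patient and channel.

Features whose values *decrease* during seizure are handled by a global
per-feature orientation sign fitted on the training data; all corrected
tensors live in oriented space (sign * value - Tr, higher = more
seizure-like).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .features import FeatureTensor, feature_manifest

__all__ = [
    "BaselineProfile",
    "FBCModel",
    "optimal_threshold",
    "compute_baseline",
    "fit_orientation",
    "fit_fbc",
    "apply_fbc",
]

logger = logging.getLogger(__name__)

DEFAULT_BASELINE_WINDOW_S = 180.0
DEFAULT_BASELINE_EPOCHS = 10


def optimal_threshold(values: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    The classifier is ``predict seizure iff value >= threshold`` on already
    oriented values.  Candidates are the midpoints between adjacent sorted
    unique values; ties on J are broken by the midpoint of the lowest and
    highest tied candidates.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == 1]
    neg = values[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("optimal_threshold requires both classes")
    uniq = np.unique(values)
    if uniq.size == 1:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    # sensitivity and specificity at each candidate, vectorized
    sens = (pos[None, :] >= candidates[:, None]).mean(axis=1)
    spec = (neg[None, :] < candidates[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best = j.max()
    tied = candidates[np.isclose(j, best, rtol=0, atol=1e-12)]
    return float((tied.min() + tied.max()) / 2.0)


@dataclass
class BaselineProfile:
    """Average non-seizure feature values (aNS) per channel for one patient.

    ``ans`` is channels x features; ``n_baseline_epochs`` is how many
    non-seizure epochs the mean was taken over.
    """

    patient_id: str
    ans: np.ndarray
    n_baseline_epochs: int


def compute_baseline(tensor: FeatureTensor,
                     window_s: float = DEFAULT_BASELINE_WINDOW_S,
                     n_epochs: int = DEFAULT_BASELINE_EPOCHS) -> BaselineProfile:
    """aNS = mean over the first ``n_epochs`` non-seizure epochs whose start
    lies inside the window (default: first 3 minutes)."""
    in_window = tensor.epoch_starts_s < window_s
    non_seizure = tensor.labels.labels == 0
    eligible = np.where(in_window & non_seizure)[0]
    if eligible.size == 0:
        raise ValueError(
            f"no non-seizure epochs in the first {window_s:.0f} s of "
            f"{tensor.patient_id}")
    if eligible.size < n_epochs:
        logger.info("baseline for %s: only %d of %d requested epochs",
                    tensor.patient_id, eligible.size, n_epochs)
    use = eligible[:n_epochs]
    ans = tensor.values[use].mean(axis=0)  # channels x features
    return BaselineProfile(patient_id=tensor.patient_id, ans=ans,
                           n_baseline_epochs=int(use.size))


def fit_orientation(tensors: list[FeatureTensor]) -> np.ndarray:
    """Global per-feature sign s in {+1, -1} so s*feature is higher in seizure.

    Fitted once on the pooled training data (mean seizure minus mean
    non-seizure value per feature); features with no class difference keep
    sign +1.
    """
    seiz_sum = None
    ns_sum = None
    n_s = n_ns = 0
    for t in tensors:
        lab = t.labels.labels.astype(bool)
        if lab.any():
            s = t.values[lab].reshape(-1, t.values.shape[2]).sum(axis=0)
            seiz_sum = s if seiz_sum is None else seiz_sum + s
            n_s += int(lab.sum()) * t.n_channels
        if (~lab).any():
            ns = t.values[~lab].reshape(-1, t.values.shape[2]).sum(axis=0)
            ns_sum = ns if ns_sum is None else ns_sum + ns
            n_ns += int((~lab).sum()) * t.n_channels
    if seiz_sum is None or ns_sum is None:
        raise ValueError("orientation requires both classes in training data")
    diff = seiz_sum / n_s - ns_sum / n_ns
    sign = np.where(diff >= 0, 1.0, -1.0)
    return sign


@dataclass
class FBCModel:
    """Per-feature linear Tr ~ aNS relation plus orientation signs.

    ``slope``/``intercept``/``r_squared`` are length-103 arrays fitted on the
    oriented training data; ``sign`` maps raw features to oriented space.
    """

    slope: np.ndarray
    intercept: np.ndarray
    sign: np.ndarray
    r_squared: np.ndarray
    n_points: np.ndarray

    def estimate_threshold(self, ans_oriented: np.ndarray) -> np.ndarray:
        """Tr estimate (oriented space) from oriented aNS values."""
        return self.slope * ans_oriented + self.intercept

    def to_frame(self) -> pd.DataFrame:
        m = feature_manifest()
        return pd.DataFrame({
            "feature": m.names,
            "slope": self.slope,
            "intercept": self.intercept,
            "sign": self.sign,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FBCModel":
        return cls(slope=df["slope"].to_numpy(),
                   intercept=df["intercept"].to_numpy(),
                   sign=df["sign"].to_numpy(),
                   r_squared=df["r_squared"].to_numpy(),
                   n_points=df["n_points"].to_numpy())


def training_thresholds(tensor: FeatureTensor,
                        sign: np.ndarray) -> np.ndarray:
    """Annotation-derived Tr per (channel, feature) in oriented space.

    Only channels containing seizure epochs yield thresholds; other channels
    are NaN (the caller falls back to the regression estimate there).
    """
    n_ch = tensor.n_channels
    n_feat = tensor.values.shape[2]
    labels = tensor.labels.labels
    tr = np.full((n_ch, n_feat), np.nan)
    if not (labels == 1).any() or not (labels == 0).any():
        return tr
    for c in range(n_ch):
        oriented = tensor.values[:, c, :] * sign[None, :]
        for f in range(n_feat):
            tr[c, f] = optimal_threshold(oriented[:, f], labels)
    return tr


def fit_fbc(tensors: list[FeatureTensor],
            baselines: dict[str, BaselineProfile],
            sign: np.ndarray | None = None) -> FBCModel:
    """Fit the per-feature OLS of Tr on aNS over all training
    (patient, channel) points where a Tr is computable.

    Channels are pooled.  Features with fewer than 2 distinct points fall
    back to slope 1, intercept 0 (pure aNS subtraction), logged.
    """
    if sign is None:
        sign = fit_orientation(tensors)
    n_feat = tensors[0].values.shape[2]
    ans_pts: list[np.ndarray] = []
    tr_pts: list[np.ndarray] = []
    for t in tensors:
        base = baselines[t.patient_id]
        tr = training_thresholds(t, sign)           # channels x features
        ans_oriented = base.ans * sign[None, :]
        ok = np.isfinite(tr).all(axis=1)            # channels with seizures
        if ok.any():
            ans_pts.append(ans_oriented[ok])
            tr_pts.append(tr[ok])
    if not ans_pts:
        raise ValueError("no (aNS, Tr) points: no training channel contains "
                         "seizure epochs")
    A = np.vstack(ans_pts)   # points x features
    T = np.vstack(tr_pts)
    slope = np.ones(n_feat)
    intercept = np.zeros(n_feat)
    r2 = np.zeros(n_feat)
    n_pts = np.full(n_feat, A.shape[0])
    for f in range(n_feat):
        a, t_ = A[:, f], T[:, f]
        if np.unique(a).size < 2:
            if a.size >= 2:
                slope[f] = 0.0
                intercept[f] = float(t_.mean())
            else:
                logger.info("feature %d: insufficient points, aNS fallback", f)
            continue
        coef = np.polyfit(a, t_, 1)
        slope[f], intercept[f] = float(coef[0]), float(coef[1])
        pred = slope[f] * a + intercept[f]
        ss_res = float(np.sum((t_ - pred) ** 2))
        ss_tot = float(np.sum((t_ - t_.mean()) ** 2))
        r2[f] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FBCModel(slope=slope, intercept=intercept, sign=sign,
                    r_squared=r2, n_points=n_pts)


def apply_fbc(tensor: FeatureTensor, baseline: BaselineProfile,
              model: FBCModel, mode: str = "test") -> FeatureTensor:
    """Subtract the detection threshold: corrected = sign*feature - Tr.

    mode="test": Tr is always the regression estimate slope*aNS + intercept.
    mode="train": the annotation-derived Tr is used on channels where it is
    computable; other channels use the estimate.
    """
    if mode not in ("train", "test"):
        raise ValueError("mode must be 'train' or 'test'")
    if baseline.ans.shape != tensor.values.shape[1:]:
        raise ValueError("baseline does not match tensor channels/features")
    ans_oriented = baseline.ans * model.sign[None, :]
    tr = model.estimate_threshold(ans_oriented)      # channels x features
    if mode == "train":
        tr_exact = training_thresholds(tensor, model.sign)
        tr = np.where(np.isfinite(tr_exact), tr_exact, tr)
    oriented = tensor.values * model.sign[None, None, :]
    corrected = oriented - tr[None, :, :]
    return _dc_replace(tensor, values=corrected)
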