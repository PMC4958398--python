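"""Performance evaluation.

Epoch-based metrics: ROC/AUC on multi-channel scores, with per-patient class
balancing (every patient is resampled with replacement up to the maximum
per-patient seizure / non-seizure epoch counts, so patients with more or
longer seizures do not dominate the AUC), and vertical averaging of ROC
curves over Monte-Carlo runs (sensitivities averaged at fixed specificities).

Event-based metrics: false detections per hour (FD/h — contiguous positive
epoch segments with no overlap with any annotated seizure) and seizure
detection rate (SDR — fraction of annotated seizures with at least one
positive epoch).

The relative gain of a method change is expressed as a percentage of the
maximally achievable gain: 100 * (auc_after - auc_before) / (1 - auc_before).

Statistical comparison of Monte-Carlo metric distributions: Shapiro-Wilk
normality gate at alpha = 0.05, then a two-sample t test if both groups pass,
otherwise a Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ROCCurve",
    "EventMetrics",
    "balance_patients",
    "roc_auc",
    "vertical_average",
    "relative_gain",
    "event_metrics",
    "threshold_at_sensitivity",
    "compare_runs",
]

DEFAULT_SPECIFICITY_GRID = np.round(np.arange(0.0, 1.0001, 0.01), 2)


@dataclass
class ROCCurve:
    """Sensitivity vs specificity at all distinct thresholds."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0 + 1e-12):
            raise ValueError("auc must be in [0, 1]")


@dataclass
class EventMetrics:
    fd_per_hour: float
    sdr: float
    operating_threshold: float
    n_false_detections: int = 0
    n_seizures: int = 0
    n_detected: int = 0


def balance_patients(scores: np.ndarray, labels: np.ndarray,
                     patients: np.ndarray, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equalize per-patient class counts by resampling with replacement.

    Nmax-S / Nmax-NS are the largest per-patient seizure / non-seizure epoch
    counts; every patient is brought up to exactly those counts by randomly
    taking multiple copies of its own epochs.  Patients missing a class
    contribute only the class they have.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    patients = np.asarray(patients)
    if scores.size == 0:
        raise ValueError("empty input")
    rng = np.random.default_rng(seed)
    uniq = np.unique(patients)
    n_s = {p: int(((patients == p) & (labels == 1)).sum()) for p in uniq}
    n_ns = {p: int(((patients == p) & (labels == 0)).sum()) for p in uniq}
    nmax_s = max(n_s.values())
    nmax_ns = max(n_ns.values())
    out_s, out_l, out_p = [], [], []
    for p in uniq:
        for cls, target in ((1, nmax_s), (0, nmax_ns)):
            idx = np.where((patients == p) & (labels == cls))[0]
            if idx.size == 0 or target == 0:
                continue
            if idx.size == target:
                take = idx
            else:
                # keep every original epoch, top up with random copies
                extra = rng.choice(idx, size=target - idx.size, replace=True) \
                    if target > idx.size else None
                take = idx if extra is None else np.concatenate([idx, extra])
            out_s.append(scores[take])
            out_l.append(np.full(take.size, cls, dtype=labels.dtype))
            out_p.append(np.full(take.size, p, dtype=patients.dtype))
    return (np.concatenate(out_s), np.concatenate(out_l),
            np.concatenate(out_p))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC over all distinct thresholds; trapezoidal AUC.

    Equals the normalized Mann-Whitney U statistic (ties half-weighted).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("roc_auc requires both classes")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    specificity = 1.0 - fpr
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, sensitivity=tpr,
                    specificity=specificity, auc=auc)


def vertical_average(curves: list[ROCCurve],
                     specificity_grid: np.ndarray | None = None) -> ROCCurve:
    """Average sensitivities at fixed specificity values across curves."""
    if not curves:
        raise ValueError("need at least one curve")
    grid = DEFAULT_SPECIFICITY_GRID if specificity_grid is None \
        else np.asarray(specificity_grid, dtype=float)
    sens_stack = []
    for c in curves:
        order = np.argsort(c.specificity)
        spec_sorted = c.specificity[order]
        sens_sorted = c.sensitivity[order]
        sens_stack.append(np.interp(grid, spec_sorted, sens_sorted))
    mean_sens = np.mean(sens_stack, axis=0)
    order = np.argsort(grid)
    auc = float(np.trapezoid(mean_sens[order], 1.0 - grid[order]))
    auc = abs(auc)
    return ROCCurve(thresholds=np.full(grid.size, np.nan),
                    sensitivity=mean_sens, specificity=grid,
                    auc=min(auc, 1.0))


def relative_gain(auc_before: float, auc_after: float) -> float:
    """Percentage of the maximally achievable AUC gain:
    100 * (after - before) / (1 - before)."""
    if auc_before >= 1.0:
        raise ValueError("relative gain undefined for a perfect baseline")
    return 100.0 * (auc_after - auc_before) / (1.0 - auc_before)


def _positive_segments(decisions: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs [i, j) of positive decisions."""
    d = np.asarray(decisions).astype(int)
    padded = np.concatenate([[0], d, [0]])
    diff = np.diff(padded)
    starts = np.where(diff == 1)[0]
    ends = np.where(diff == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def event_metrics(decisions: np.ndarray, epoch_starts_s: np.ndarray,
                  epoch_length_s: float,
                  annotations: list[tuple[float, float]],
                  record_duration_h: float,
                  operating_threshold: float = np.nan) -> EventMetrics:
    """FD/h and SDR from per-epoch binary decisions.

    A false detection is a contiguous run of positive epochs none of which
    overlaps any annotated seizure; a seizure is detected when at least one
    positive epoch overlaps it.  Epoch intervals are half-open
    ``[start, start + length)``.
    """
    decisions = np.asarray(decisions).astype(int)
    epoch_starts_s = np.asarray(epoch_starts_s, dtype=float)
    if decisions.size != epoch_starts_s.size:
        raise ValueError("decisions not aligned with the epoch grid")

    def overlaps(e: int, interval: tuple[float, float]) -> bool:
        s = epoch_starts_s[e]
        return min(s + epoch_length_s, interval[1]) > max(s, interval[0])

    n_fd = 0
    for i, j in _positive_segments(decisions):
        touches = any(overlaps(e, ann) for e in range(i, j)
                      for ann in annotations)
        if not touches:
            n_fd += 1
    n_detected = 0
    positives = np.where(decisions == 1)[0]
    for ann in annotations:
        if any(overlaps(e, ann) for e in positives):
            n_detected += 1
    n_seiz = len(annotations)
    return EventMetrics(
        fd_per_hour=n_fd / record_duration_h if record_duration_h > 0 else 0.0,
        sdr=n_detected / n_seiz if n_seiz else 0.0,
        operating_threshold=operating_threshold,
        n_false_detections=n_fd,
        n_seizures=n_seiz,
        n_detected=n_detected,
    )


def threshold_at_sensitivity(scores: np.ndarray, labels: np.ndarray,
                             target: float = 0.80) -> float:
    """Largest threshold achieving epoch sensitivity >= target."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = np.sort(scores[labels == 1])
    if pos.size == 0 or (labels == 0).sum() == 0:
        raise ValueError("threshold_at_sensitivity requires both classes")
    # sensitivity at threshold t is mean(pos >= t); scan candidate thresholds
    candidates = np.unique(scores)[::-1]
    for t in candidates:
        if (pos >= t).mean() >= target:
            return float(t)
    return float(scores.min())


def compare_runs(samples_a: np.ndarray, samples_b: np.ndarray,
                 alpha: float = 0.05) -> tuple[str, float]:
    """Normality-gated two-group comparison.

    Shapiro-Wilk on each group; if both are compatible with normality the
    two-sample t test is used, otherwise the Wilcoxon rank-sum test.
    Returns (test name, p-value).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 samples per group")

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:  # Shapiro undefined for constant input
            return True
        return stats.shapiro(x).pvalue > alpha

    if _normal(a) and _normal(b):
        res = stats.ttest_ind(a, b)
        return "t-test", float(res.pvalue)
    res = stats.ranksums(a, b)
    return "wilcoxon-ranksum", float(res.pvalue)
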