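"""Classifier output post-processing.

The SVM produces one signed decision value per channel per epoch.  For each
epoch the channel outputs are sorted in ascending order; the value at rank k
over time forms the k-th sorted output time series.  Each rank series is
smoothed with a causal scalar Kalman filter (random-walk state plus white
measurement noise) to remove random fluctuations, and the multi-channel
score of an epoch is the maximum over the filtered rank series — equivalent
to requiring detection in at least one channel.  A detection threshold then
yields the binary per-epoch decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KalmanParams",
    "ScoreSeries",
    "sort_outputs",
    "kalman_filter",
    "multichannel_score",
    "decide",
    "postprocess_scores",
]


@dataclass(frozen=True)
class KalmanParams:
    """Random-walk-plus-noise state model: x_k = x_{k-1} + w (var q),
    z_k = x_k + v (var r)."""

    process_variance: float = 0.01
    measurement_variance: float = 1.0
    initial_state: float | None = None   # None -> first observation
    initial_variance: float = 1e6        # diffuse

    def __post_init__(self) -> None:
        if self.process_variance < 0:
            raise ValueError("process_variance must be >= 0")
        if self.measurement_variance <= 0:
            raise ValueError("measurement_variance must be > 0")


def sort_outputs(raw: np.ndarray) -> np.ndarray:
    """Sort each epoch's channel outputs ascending (stable)."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    return np.sort(raw, axis=1, kind="stable")


def kalman_filter(series: np.ndarray, params: KalmanParams) -> np.ndarray:
    """Causal scalar Kalman filter for the random-walk model."""
    z = np.asarray(series, dtype=float).ravel()
    q = params.process_variance
    r = params.measurement_variance
    x = z[0] if params.initial_state is None else params.initial_state
    p = params.initial_variance
    out = np.empty_like(z)
    for k, zk in enumerate(z):
        # predict
        p = p + q
        # update; posterior variance as gain*r == p*r/(p+r), which stays
        # accurate for diffuse priors where (1-gain) cancels catastrophically
        gain = p / (p + r)
        x = x + gain * (zk - x)
        p = gain * r
        out[k] = x
    return out


def multichannel_score(filtered: np.ndarray) -> np.ndarray:
    """Per-epoch maximum over the (filtered) rank series."""
    filtered = np.atleast_2d(np.asarray(filtered, dtype=float))
    return filtered.max(axis=1)


def decide(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Binary decisions: 1 iff score >= threshold."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(np.int8)


@dataclass
class ScoreSeries:
    """All stages of the post-processor for one recording."""

    raw: np.ndarray          # epochs x channels
    sorted: np.ndarray       # epochs x channels, ascending per epoch
    filtered: np.ndarray     # epochs x channels (per-rank Kalman)
    multichannel: np.ndarray  # epochs


def postprocess_scores(raw: np.ndarray,
                       params: KalmanParams | None = None,
                       filter_ranks: str = "all") -> ScoreSeries:
    """Full chain: sort, Kalman-filter rank series, take per-epoch max.

    ``filter_ranks``: "all" filters every rank time series (default);
    "max" filters only the top rank; "none" skips filtering (identity).
    """
    if params is None:
        params = KalmanParams()
    if filter_ranks not in ("all", "max", "none"):
        raise ValueError("filter_ranks must be 'all', 'max' or 'none'")
    srt = sort_outputs(raw)
    filtered = srt.copy()
    if filter_ranks == "all":
        for k in range(srt.shape[1]):
            filtered[:, k] = kalman_filter(srt[:, k], params)
    elif filter_ranks == "max":
        filtered[:, -1] = kalman_filter(srt[:, -1], params)
    return ScoreSeries(raw=np.atleast_2d(raw), sorted=srt, filtered=filtered,
                       multichannel=multichannel_score(filtered))
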