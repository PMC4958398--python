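"""Quantitative EEG feature battery: 103 features per 10-s epoch per channel.

The battery mixes time-domain descriptors (curve length, RMS, Hjorth
parameters, zero-crossing rates, extrema counts, peak-peak voltage),
spectral descriptors (total 0-12 Hz power, peak frequency, spectral edge
frequencies, overlapping 2-Hz subband powers raw and normalized, a 15-band
linear filter bank with cepstral and frequency-filtered transforms),
wavelet energies (Db4 detail scales D4 ~0.78-1.56 Hz and D3 ~1.56-3.13 Hz,
bracketing the 1-2 Hz delta rhythm at 25 Hz sampling), autoregressive
modelling errors for orders 1-9 (Burg), and information-theoretic measures
(Shannon, spectral and SVD entropy, Fisher information, Teager energy,
skewness, kurtosis).

The ordered manifest is fixed and versioned; `extract_features` returns the
manifest-ordered vector and never produces NaN/Inf (degenerate epochs fall
back to defined values, typically 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy.fft import dct
from scipy.stats import kurtosis as _kurtosis, skew as _skew

from .preprocess import EpochGrid, EpochLabels, label_epochs
from .synthetic import EEGRecording

__all__ = [
    "MANIFEST_VERSION",
    "FeatureManifest",
    "FeatureTensor",
    "feature_manifest",
    "extract_features",
    "extract_tensor",
    "burg_errors",
]

MANIFEST_VERSION = "1.0"

#: overlapping 2-Hz subbands 0-2, 1-3, ... 10-12 Hz
SUBBANDS_2HZ = [(float(lo), float(lo + 2)) for lo in range(0, 11)]
#: linear filter bank 0-2, 1-3, ... 14-16 Hz
FILTERBANK_BANDS = [(float(lo), float(lo + 2)) for lo in range(0, 15)]
N_FILTERBANK = len(FILTERBANK_BANDS)

_SVD_EMBED_DIM = 20
_SVD_EMBED_DELAY = 1
_LOG_EPS = 1e-12


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered, versioned list of (name, group, parameters) entries."""

    entries: tuple[tuple[str, str, dict], ...]
    version: str = MANIFEST_VERSION

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def group(self, group: str) -> list[int]:
        return [i for i, e in enumerate(self.entries) if e[1] == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(n, g, repr(p)) for n, g, p in self.entries],
            columns=["feature", "group", "parameters"],
        )


def _build_manifest() -> FeatureManifest:
    e: list[tuple[str, str, dict]] = []
    e.append(("total_power_0_12hz", "spectral_power", {"band": (0.0, 12.0)}))
    e.append(("peak_frequency_hz", "spectral_shape", {}))
    for pct in (80, 90, 95):
        e.append((f"sef_{pct}", "spectral_shape", {"percent": pct}))
    for lo, hi in SUBBANDS_2HZ:
        e.append((f"subband_power_{lo:g}_{hi:g}hz", "spectral_power",
                  {"band": (lo, hi)}))
    for lo, hi in SUBBANDS_2HZ:
        e.append((f"norm_subband_power_{lo:g}_{hi:g}hz", "spectral_norm",
                  {"band": (lo, hi)}))
    e.append(("wavelet_energy_d4", "wavelet", {"wavelet": "db4", "level": 4,
                                               "band_hz": (0.78, 1.56)}))
    e.append(("wavelet_energy_d3", "wavelet", {"wavelet": "db4", "level": 3,
                                               "band_hz": (1.56, 3.13)}))
    e.append(("curve_length", "amplitude", {}))
    e.append(("n_maxima", "shape_counts", {}))
    e.append(("n_minima", "shape_counts", {}))
    e.append(("rms_amplitude", "amplitude", {}))
    e.append(("hjorth_activity", "hjorth_power", {}))
    e.append(("hjorth_mobility", "hjorth_ratio", {}))
    e.append(("hjorth_complexity", "hjorth_ratio", {}))
    for sig in ("x", "dx", "ddx"):
        e.append((f"zcr_{sig}", "zero_crossings", {"signal": sig}))
    for sig in ("dx", "ddx"):
        e.append((f"var_{sig}", "diff_variance", {"signal": sig}))
    for order in range(1, 10):
        e.append((f"ar_error_order{order}", "ar_error", {"order": order}))
    e.append(("skewness", "distribution", {}))
    e.append(("kurtosis", "distribution", {}))
    e.append(("nonlinear_energy", "nonlinear", {}))
    e.append(("shannon_entropy", "entropy", {}))
    e.append(("spectral_entropy", "entropy", {}))
    e.append(("svd_entropy", "entropy", {"embed_dim": _SVD_EMBED_DIM,
                                         "delay": _SVD_EMBED_DELAY}))
    e.append(("fisher_information", "entropy", {"embed_dim": _SVD_EMBED_DIM,
                                                "delay": _SVD_EMBED_DELAY}))
    for lo, hi in FILTERBANK_BANDS:
        e.append((f"fb_energy_{lo:g}_{hi:g}hz", "filterbank_power",
                  {"band": (lo, hi)}))
    for k in range(N_FILTERBANK):
        e.append((f"cepstral_c{k}", "cepstral", {"index": k}))
    for k in range(N_FILTERBANK):
        e.append((f"freq_filtered_e{k}", "freq_filtered", {"index": k}))
    e.append(("peak_peak_voltage", "amplitude", {}))
    manifest = FeatureManifest(entries=tuple(e))
    assert len(manifest) == 103
    return manifest


_MANIFEST = _build_manifest()


def feature_manifest() -> FeatureManifest:
    """The fixed 103-entry feature manifest (shared instance)."""
    return _MANIFEST


# ----------------------------------------------------------------- helpers

def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float,
                hi: float) -> float:
    """Integrated PSD over [lo, hi], clipped to the available frequency axis."""
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def burg_errors(x: np.ndarray, max_order: int = 9) -> np.ndarray:
    """Residual variance of Burg AR fits for every order 1..max_order.

    One lattice recursion yields the whole error sequence; the final-order
    coefficients agree with textbook Burg solutions.  Non-increasing in the
    order by construction.
    """
    x = np.asarray(x, dtype=float)
    ef = x.copy()
    eb = x.copy()
    err = float(np.mean(x**2))
    out = np.empty(max_order)
    for m in range(max_order):
        fk = ef[m + 1:]
        bk = eb[m:-1]
        den = np.dot(fk, fk) + np.dot(bk, bk)
        k = -2.0 * np.dot(fk, bk) / den if den > 0 else 0.0
        new_f = fk + k * bk
        new_b = bk + k * fk
        ef[m + 1:] = new_f
        eb[m + 1:] = new_b
        err *= (1.0 - k * k)
        out[m] = err
    return out


def _sorted_singular_probs(x: np.ndarray) -> np.ndarray | None:
    m, tau = _SVD_EMBED_DIM, _SVD_EMBED_DELAY
    n_rows = x.size - (m - 1) * tau
    if n_rows < m:
        return None
    emb = np.lib.stride_tricks.sliding_window_view(x, m)[::tau]
    s = np.linalg.svd(emb, compute_uv=False)
    total = s.sum()
    if total <= 0:
        return None
    return s / total


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-np.sum(p * np.log(p)))


def extract_features(epoch: np.ndarray, sample_rate_hz: float = 25.0,
                     manifest: FeatureManifest | None = None) -> np.ndarray:
    """Compute the manifest-ordered 103-feature vector of one epoch.

    ``epoch`` is a 1-D microvolt series; at default settings a 10-s epoch at
    25 Hz, i.e. 250 samples.  Constant or all-zero epochs produce defined
    fallbacks (entropies, skewness, kurtosis, peak frequency -> 0), never
    NaN or Inf.
    """
    if manifest is None:
        manifest = _MANIFEST
    x = np.asarray(epoch, dtype=float).ravel()
    if x.ndim != 1 or x.size < 2:
        raise ValueError("epoch must be a 1-D series of >= 2 samples")
    fs = sample_rate_hz
    n = x.size
    out = np.empty(len(manifest))
    i = 0

    # ---- spectrum (Welch, 2-s Hamming windows, 50 % overlap)
    nperseg = min(int(round(2 * fs)), n)
    freqs, psd = sps.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                           noverlap=nperseg // 2, detrend=False)
    total_psd = float(np.trapezoid(psd, freqs))
    # a constant (zero-variance) epoch has no meaningful spectral shape:
    # shape descriptors fall back to 0 even though its DC power is real
    degenerate_spectrum = total_psd <= _LOG_EPS or np.var(x) == 0.0

    out[i] = _band_power(freqs, psd, 0.0, 12.0); i += 1  # total power 0-12

    if degenerate_spectrum:
        out[i] = 0.0; i += 1                               # peak frequency
        for _pct in (80, 90, 95):
            out[i] = 0.0; i += 1                           # SEFs
    else:
        out[i] = float(freqs[np.argmax(psd)]); i += 1
        cumulative = np.cumsum(psd)
        cumulative /= cumulative[-1]
        for pct in (80, 90, 95):
            idx = int(np.searchsorted(cumulative, pct / 100.0))
            out[i] = float(freqs[min(idx, freqs.size - 1)]); i += 1

    sub_powers = np.array([_band_power(freqs, psd, lo, hi)
                           for lo, hi in SUBBANDS_2HZ])
    out[i:i + 11] = sub_powers; i += 11
    if degenerate_spectrum:
        out[i:i + 11] = 0.0
    else:
        out[i:i + 11] = sub_powers / total_psd
    i += 11

    # ---- wavelet energies (Db4 detail levels 4 and 3)
    coeffs = pywt.wavedec(x, "db4", level=4)
    # coeffs = [A4, D4, D3, D2, D1]
    out[i] = float(np.sum(coeffs[1] ** 2)); i += 1  # D4 ~0.78-1.56 Hz
    out[i] = float(np.sum(coeffs[2] ** 2)); i += 1  # D3 ~1.56-3.13 Hz

    # ---- time-domain
    dx = np.diff(x)
    ddx = np.diff(dx)
    out[i] = float(np.sum(np.abs(dx))); i += 1      # curve length
    out[i] = float(np.sum((dx[:-1] > 0) & (dx[1:] < 0))); i += 1  # maxima
    out[i] = float(np.sum((dx[:-1] < 0) & (dx[1:] > 0))); i += 1  # minima
    out[i] = float(np.sqrt(np.mean(x**2))); i += 1  # RMS

    var_x = float(np.var(x))
    var_dx = float(np.var(dx))
    var_ddx = float(np.var(ddx))
    out[i] = var_x; i += 1                          # Hjorth activity
    mobility = np.sqrt(var_dx / var_x) if var_x > 0 else 0.0
    mobility_dx = np.sqrt(var_ddx / var_dx) if var_dx > 0 else 0.0
    out[i] = mobility; i += 1
    out[i] = (mobility_dx / mobility) if mobility > 0 else 0.0; i += 1

    for sig in (x, dx, ddx):
        centred = sig - np.mean(sig)
        out[i] = float(np.sum(np.signbit(centred[:-1]) !=
                              np.signbit(centred[1:]))); i += 1
    out[i] = var_dx; i += 1
    out[i] = var_ddx; i += 1

    # ---- AR modelling errors, orders 1-9
    if var_x > 0:
        out[i:i + 9] = burg_errors(x - np.mean(x), 9)
    else:
        out[i:i + 9] = 0.0
    i += 9

    out[i] = float(_skew(x)) if var_x > 0 else 0.0; i += 1
    out[i] = float(_kurtosis(x, fisher=False)) if var_x > 0 else 0.0; i += 1
    out[i] = float(np.mean(x[1:-1] ** 2 - x[:-2] * x[2:])); i += 1  # Teager

    # ---- entropies
    sq = x**2
    total_sq = sq.sum()
    out[i] = _entropy(sq / total_sq) if total_sq > 0 else 0.0; i += 1
    out[i] = _entropy(psd / psd.sum()) if not degenerate_spectrum else 0.0
    i += 1
    probs = _sorted_singular_probs(x)
    if probs is None:
        out[i] = 0.0; i += 1
        out[i] = 0.0; i += 1
    else:
        out[i] = _entropy(probs); i += 1
        with np.errstate(divide="ignore", invalid="ignore"):
            fisher = np.sum(np.diff(probs) ** 2 / probs[:-1])
        out[i] = float(fisher) if np.isfinite(fisher) else 0.0; i += 1

    # ---- linear filter bank + cepstral + frequency-filtered energies
    fb = np.array([_band_power(freqs, psd, lo, hi)
                   for lo, hi in FILTERBANK_BANDS])
    out[i:i + N_FILTERBANK] = fb; i += N_FILTERBANK
    log_fb = np.log(fb + _LOG_EPS)
    out[i:i + N_FILTERBANK] = dct(log_fb, type=2, norm="ortho")
    i += N_FILTERBANK
    # frequency filtering: first-order difference of neighbouring log
    # energies, zero-padded at the band edges
    padded = np.concatenate(([0.0], log_fb, [0.0]))
    out[i:i + N_FILTERBANK] = padded[2:] - padded[:-2]; i += N_FILTERBANK

    out[i] = float(np.max(x) - np.min(x)); i += 1   # peak-peak

    assert i == len(manifest)
    if not np.all(np.isfinite(out)):
        bad = [manifest.names[j] for j in np.where(~np.isfinite(out))[0]]
        raise AssertionError(f"non-finite features: {bad}")
    return out


@dataclass
class FeatureTensor:
    """Per-epoch x per-channel x 103-feature values for one recording."""

    values: np.ndarray                  # (n_epochs, n_channels, 103)
    labels: EpochLabels
    patient_id: str
    cohort: str
    channels: list[str]
    epoch_starts_s: np.ndarray
    epoch_length_s: float
    duration_s: float
    annotations: list[tuple[float, float]] = field(default_factory=list)
    record_index: int = 0

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def to_frame(self, manifest: FeatureManifest | None = None) -> pd.DataFrame:
        """Long table: one row per (epoch, channel), 103 named columns."""
        if manifest is None:
            manifest = _MANIFEST
        e, c, f = self.values.shape
        flat = self.values.reshape(e * c, f)
        df = pd.DataFrame(flat, columns=manifest.names)
        df.insert(0, "patient_id", self.patient_id)
        df.insert(1, "cohort", self.cohort)
        df.insert(2, "record_index", self.record_index)
        df.insert(3, "channel", np.tile(self.channels, e))
        df.insert(4, "epoch_start_s", np.repeat(self.epoch_starts_s, c))
        df.insert(5, "label", np.repeat(self.labels.labels, c))
        return df


def extract_tensor(recording: EEGRecording, grid: EpochGrid,
                   overlap_fraction_rule: float = 0.5,
                   manifest: FeatureManifest | None = None) -> FeatureTensor:
    """Extract the feature tensor of one (preprocessed) recording."""
    if manifest is None:
        manifest = _MANIFEST
    labels = label_epochs(grid, recording.annotations, overlap_fraction_rule)
    values = np.empty((grid.n_epochs, recording.n_channels, len(manifest)))
    for e, sl in enumerate(grid.slices(recording.sample_rate_hz)):
        for c in range(recording.n_channels):
            values[e, c] = extract_features(recording.signal[c, sl],
                                            recording.sample_rate_hz,
                                            manifest)
    return FeatureTensor(
        values=values,
        labels=labels,
        patient_id=recording.patient_id,
        cohort=recording.cohort,
        channels=list(recording.channels),
        epoch_starts_s=grid.epoch_starts_s,
        epoch_length_s=grid.epoch_length_s,
        duration_s=recording.duration_s,
        annotations=list(recording.annotations),
    )
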