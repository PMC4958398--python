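"""Synthetic annotated EEG cohorts.

Generates multi-channel recordings that emulate the statistical structure the
detection pipeline assumes: a 1/f-shaped stochastic background with a
per-patient multiplicative amplitude factor (the inter-patient baseline shift
that feature baseline correction must remove), plus annotated seizures
rendered as amplitude-ramped rhythmic discharges.  Two cohort presets are
provided: a neonatal-like cohort (9 channels, slow 1-3 Hz discharges with a
second harmonic, mimicking the more complex neonatal seizure morphology) and
an adult-like cohort (19 channels, faster and simpler discharges).

Generation is a pure function of ``(config, patient_index, record_index)``;
the first three minutes of every recording are kept seizure-free so a clean
baseline window always exists.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal.windows import tukey

__all__ = [
    "CohortConfig",
    "EEGRecording",
    "neonatal_config",
    "adult_config",
    "generate_recording",
    "generate_cohort",
]

#: 10-20 subsets used for the two montages.
NEONATAL_CHANNELS = ["Fp1", "Fp2", "C3", "C4", "T3", "T4", "O1", "O2", "Cz"]
ADULT_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
]

#: Seizure onsets never occur before this time, so baseline epochs are clean.
BASELINE_GUARD_S = 180.0


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    Amplitudes are in microvolts.  ``baseline_offset_sd`` is the standard
    deviation (log scale) of the lognormal per-patient amplitude factor;
    0 means every patient shares the same background scale.
    """

    cohort_name: str
    n_patients: int
    n_channels: int
    sample_rate_hz: float = 250.0
    duration_s: float = 1200.0
    seizure_rate: float = 2.0
    seizure_duration_s: tuple[float, float] = (30.0, 120.0)
    seizure_freq_hz: tuple[float, float] = (1.0, 3.0)
    baseline_offset_sd: float = 0.5
    background_spectral_slope: float = 1.0
    spectral_slope_sd: float = 0.3
    background_rms_uv: float = 20.0
    seizure_amplitude_factor: float = 2.0
    harmonic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.duration_s < BASELINE_GUARD_S:
            raise ValueError(
                f"duration_s must be >= {BASELINE_GUARD_S} s so that a "
                "baseline window exists"
            )
        if self.seizure_rate < 1:
            raise ValueError("seizure_rate must be >= 1 (every recording "
                             "must contain at least one seizure)")
        lo, hi = self.seizure_duration_s
        if not (0 < lo <= hi):
            raise ValueError("invalid seizure_duration_s range")
        lo, hi = self.seizure_freq_hz
        if not (0 < lo <= hi):
            raise ValueError("invalid seizure_freq_hz range")

    def to_dict(self) -> dict:
        return asdict(self)


def neonatal_config(**overrides) -> CohortConfig:
    """Neonatal-like cohort: 9 channels, slow complex discharges."""
    kw = dict(
        cohort_name="neo",
        n_patients=10,
        n_channels=9,
        seizure_freq_hz=(1.0, 3.0),
        seizure_duration_s=(30.0, 120.0),
        harmonic=True,
    )
    kw.update(overrides)
    return CohortConfig(**kw)


def adult_config(**overrides) -> CohortConfig:
    """Adult-like cohort: 19 channels, faster simple discharges."""
    kw = dict(
        cohort_name="adult",
        n_patients=10,
        n_channels=19,
        seizure_freq_hz=(3.0, 7.0),
        seizure_duration_s=(20.0, 90.0),
        harmonic=False,
    )
    kw.update(overrides)
    return CohortConfig(**kw)


@dataclass
class EEGRecording:
    """Multi-channel EEG with global seizure interval annotations.

    ``signal`` is channels x samples in microvolts; ``annotations`` is a list
    of half-open ``[start_s, end_s)`` seizure intervals, non-overlapping and
    sorted.  ``seizure_channels`` records which channel indices carried each
    discharge (generator bookkeeping; annotations themselves are global).
    """

    patient_id: str
    cohort: str
    channels: list[str]
    signal: np.ndarray
    sample_rate_hz: float
    annotations: list[tuple[float, float]] = field(default_factory=list)
    seizure_channels: list[list[int]] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.sample_rate_hz

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        dur = self.duration_s
        prev_end = -np.inf
        for start, end in self.annotations:
            if not (0 <= start < end <= dur):
                raise ValueError(f"annotation [{start}, {end}) outside record")
            if start < prev_end:
                raise ValueError("annotations overlap")
            prev_end = end


def _channel_labels(n_channels: int) -> list[str]:
    if n_channels == len(NEONATAL_CHANNELS):
        return list(NEONATAL_CHANNELS)
    if n_channels == len(ADULT_CHANNELS):
        return list(ADULT_CHANNELS)
    return [f"EEG{i + 1}" for i in range(n_channels)]


def _cohort_key(name: str) -> int:
    # stable across processes, unlike Python's randomized str hash
    return zlib.crc32(name.encode("utf-8"))


def _patient_rng(config: CohortConfig, patient_index: int,
                 tag: int = 0) -> np.random.Generator:
    # keyed on (seed, cohort, patient) only: per-patient draws are shared by
    # all of the patient's recordings
    key = [config.seed, _cohort_key(config.cohort_name), 0, patient_index, tag]
    return np.random.default_rng(np.random.SeedSequence(key))


def _record_rng(config: CohortConfig, patient_index: int,
                record_index: int) -> np.random.Generator:
    key = [config.seed, _cohort_key(config.cohort_name), 1,
           patient_index, record_index]
    return np.random.default_rng(np.random.SeedSequence(key))


def patient_amplitude_factor(config: CohortConfig, patient_index: int) -> float:
    """Lognormal per-patient multiplicative amplitude factor (drawn once)."""
    if config.baseline_offset_sd == 0:
        return 1.0
    rng = _patient_rng(config, patient_index)
    return float(rng.lognormal(mean=0.0, sigma=config.baseline_offset_sd))


def patient_spectral_slope(config: CohortConfig, patient_index: int) -> float:
    """Per-patient 1/f exponent: base slope plus a Gaussian offset (drawn
    once per patient), floored at 0.2.  Emulates inter-patient differences
    in background spectral shape (maturation, vigilance)."""
    if config.spectral_slope_sd == 0:
        return config.background_spectral_slope
    rng = _patient_rng(config, patient_index, tag=1)
    offset = rng.normal(0.0, config.spectral_slope_sd)
    return max(0.2, config.background_spectral_slope + offset)


def one_over_f_noise(rng: np.random.Generator, n_samples: int,
                     sample_rate_hz: float, slope: float) -> np.ndarray:
    """Gaussian noise with a 1/f**slope power spectrum, unit RMS."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate_hz)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    # amplitude shaping = f^(-slope/2) so that power goes as f^(-slope)
    shaping[nonzero] = freqs[nonzero] ** (-slope / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n_samples)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _place_seizures(rng: np.random.Generator, config: CohortConfig,
                    n_seizures: int) -> list[tuple[float, float]]:
    """Draw non-overlapping seizure intervals with onsets after the guard."""
    gap_s = 10.0
    available = config.duration_s - BASELINE_GUARD_S
    if config.seizure_duration_s[0] > available:
        raise ValueError(
            f"recording too short: a {config.seizure_duration_s[0]:.0f} s "
            f"seizure does not fit in the {available:.0f} s after the "
            "baseline window"
        )
    durations = rng.uniform(*config.seizure_duration_s, size=n_seizures)
    # the rate is an expectation; drop draws that do not fit, but keep >= 1
    while n_seizures > 1 and (durations.sum()
                              + gap_s * (n_seizures - 1)) > available:
        n_seizures -= 1
        durations = durations[:n_seizures]
    if durations.sum() > available:
        durations = np.array([rng.uniform(config.seizure_duration_s[0],
                                          min(config.seizure_duration_s[1],
                                              available))])
        n_seizures = 1
    total_needed = durations.sum() + gap_s * (n_seizures - 1)
    slack = available - total_needed
    # distribute the slack over n_seizures + 1 gaps (Dirichlet-style)
    cuts = np.sort(rng.uniform(0, slack, size=n_seizures))
    intervals = []
    cursor = BASELINE_GUARD_S
    prev_cut = 0.0
    for dur, cut in zip(durations, cuts):
        cursor += cut - prev_cut
        intervals.append((float(cursor), float(cursor + dur)))
        cursor += dur + gap_s
        prev_cut = cut
    return intervals


def _seizure_waveform(rng: np.random.Generator, config: CohortConfig,
                      duration_s: float, amplitude: float) -> np.ndarray:
    fs = config.sample_rate_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    freq = rng.uniform(*config.seizure_freq_hz)
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * freq * t + phase)
    if config.harmonic:
        wave = wave + 0.5 * np.sin(2 * np.pi * 2 * freq * t + 2 * phase)
    # amplitude ramp: taper 25 % on each side
    envelope = tukey(n, alpha=0.5)
    return amplitude * envelope * wave


def generate_recording(config: CohortConfig, patient_index: int,
                       record_index: int = 0) -> EEGRecording:
    """Generate one annotated recording, deterministically.

    The background is 1/f-shaped Gaussian noise scaled by the patient's
    amplitude factor; each seizure is an amplitude-ramped sinusoid (plus a
    second harmonic when ``config.harmonic``) added to either a random subset
    of channels (focal) or all channels (generalized) and annotated exactly.
    """
    rng = _record_rng(config, patient_index, record_index)
    fs = config.sample_rate_hz
    n_samples = int(round(config.duration_s * fs))
    n_ch = config.n_channels
    amp_factor = patient_amplitude_factor(config, patient_index)
    base_rms = config.background_rms_uv * amp_factor

    slope = patient_spectral_slope(config, patient_index)
    signal = np.empty((n_ch, n_samples))
    for c in range(n_ch):
        signal[c] = base_rms * one_over_f_noise(rng, n_samples, fs, slope)

    n_seizures = max(1, int(rng.poisson(config.seizure_rate)))
    intervals = _place_seizures(rng, config, n_seizures)
    seizure_channels: list[list[int]] = []
    for start, end in intervals:
        generalized = rng.random() < 0.5
        if generalized:
            chans = list(range(n_ch))
        else:
            k = max(2, n_ch // 2)
            chans = sorted(rng.choice(n_ch, size=k, replace=False).tolist())
        seizure_channels.append(chans)
        amplitude = config.seizure_amplitude_factor * base_rms
        wave = _seizure_waveform(rng, config, end - start, amplitude)
        i0 = int(round(start * fs))
        i1 = i0 + wave.size
        for c in chans:
            signal[c, i0:i1] += wave

    rec = EEGRecording(
        patient_id=f"{config.cohort_name}-P{patient_index:03d}",
        cohort=config.cohort_name,
        channels=_channel_labels(n_ch),
        signal=signal,
        sample_rate_hz=fs,
        annotations=intervals,
        seizure_channels=seizure_channels,
    )
    rec.validate()
    return rec


def generate_cohort(config: CohortConfig,
                    records_per_patient: int = 1) -> list[EEGRecording]:
    """Generate ``n_patients`` patients with ``records_per_patient`` each."""
    out = []
    for p in range(config.n_patients):
        for r in range(records_per_patient):
            out.append(generate_recording(config, p, r))
    return out
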