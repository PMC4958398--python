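"""EDF interchange and sidecar annotation files.

Recordings are written as plain EDF (16-bit samples, one data record per
second) with a per-recording CSV sidecar holding the seizure annotations
(columns: patient_id, start_s, end_s), so real clinical EDFs with interval
annotations can be substituted for the synthetic cohorts.  Reading goes
through mne.
"""

from __future__ import annotations

import csv
import datetime as _dt
from pathlib import Path

import numpy as np

from .synthetic import EEGRecording

__all__ = ["write_edf", "read_edf", "write_annotations", "read_annotations",
           "write_recording", "read_recording"]


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: EEGRecording, path: str | Path) -> Path:
    """Write the recording as EDF (physical unit uV, 1-s data records)."""
    path = Path(path)
    fs = recording.sample_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sample rate")
    fs = int(round(fs))
    n_ch = recording.n_channels
    sig = recording.signal
    n_records = sig.shape[1] // fs
    sig = sig[:, :n_records * fs]

    phys_min = np.floor(sig.min(axis=1))
    phys_max = np.ceil(sig.max(axis=1))
    same = phys_max <= phys_min
    phys_max[same] = phys_min[same] + 1.0
    dig_min, dig_max = -32768.0, 32767.0
    scale = (dig_max - dig_min) / (phys_max - phys_min)

    startdate = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b""
    header += _pad("0", 8)
    header += _pad(f"X X X {recording.patient_id}", 80)
    header += _pad(f"Startdate 01-JAN-2000 X X X cohort={recording.cohort}", 80)
    header += _pad(startdate.strftime("%d.%m.%y"), 8)
    header += _pad(startdate.strftime("%H.%M.%S"), 8)
    header += _pad(str(256 * (1 + n_ch)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)            # record duration, seconds
    header += _pad(str(n_ch), 4)

    def field(values, width):
        return b"".join(_pad(str(v), width) for v in values)

    header += field(recording.channels, 16)
    header += field(["EEG"] * n_ch, 80)             # transducer
    header += field(["uV"] * n_ch, 8)
    header += field([f"{v:g}" for v in phys_min], 8)
    header += field([f"{v:g}" for v in phys_max], 8)
    header += field([f"{dig_min:g}" for _ in range(n_ch)], 8)
    header += field([f"{dig_max:g}" for _ in range(n_ch)], 8)
    header += field([""] * n_ch, 80)                # prefiltering
    header += field([str(fs)] * n_ch, 8)
    header += field([""] * n_ch, 32)                # reserved

    digital = np.empty((n_ch, n_records * fs), dtype="<i2")
    for c in range(n_ch):
        d = (sig[c] - phys_min[c]) * scale[c] + dig_min
        digital[c] = np.clip(np.round(d), dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())
    return path


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file back into an EEGRecording (annotations empty)."""
    import mne
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # mne returns volts
    patient_id = raw.info["subject_info"].get("last_name", "") \
        if raw.info.get("subject_info") else ""
    if not patient_id:
        patient_id = Path(path).stem
    return EEGRecording(
        patient_id=patient_id,
        cohort="",
        channels=list(raw.ch_names),
        signal=signal,
        sample_rate_hz=float(raw.info["sfreq"]),
        annotations=[],
    )


def write_annotations(recording: EEGRecording, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "start_s", "end_s"])
        for start, end in recording.annotations:
            writer.writerow([recording.patient_id, f"{start:.3f}", f"{end:.3f}"])
    return path


def read_annotations(path: str | Path) -> list[tuple[float, float]]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append((float(row["start_s"]), float(row["end_s"])))
    return out


def write_recording(recording: EEGRecording, directory: str | Path,
                    stem: str | None = None) -> tuple[Path, Path]:
    """Write <stem>.edf plus <stem>.annotations.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or recording.patient_id
    edf_path = write_edf(recording, directory / f"{stem}.edf")
    ann_path = write_annotations(recording,
                                 directory / f"{stem}.annotations.csv")
    return edf_path, ann_path


def read_recording(edf_path: str | Path, cohort: str = "") -> EEGRecording:
    """Read an EDF and, if present, its sidecar annotation CSV."""
    edf_path = Path(edf_path)
    rec = read_edf(edf_path)
    rec.cohort = cohort
    sidecar = edf_path.parent / f"{edf_path.stem}.annotations.csv"
    if sidecar.exists():
        rec.annotations = read_annotations(sidecar)
    return rec
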