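"""Recording containers, on-disk bundle format, and integer-ratio decimation.

A recording bundle is a directory with three plain-text members:

* ``signals.csv`` — columns ``sample_index, bi_ohm, emg_au`` at the raw rate;
* ``meta.yaml`` — key/value sidecar (subject id, series id, sampling rate, units);
* ``annotations.csv`` — columns ``time_s, label`` with expert reference times.

Text keeps fixtures diff-able and the format device-independent; sample values
are written with ``repr`` round-trip precision so write→read is lossless.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from pathlib import Path

import numpy as np
import yaml

VALID_SERIES = ("I", "II", "III", "IV", "synthetic")


class BundleFormatError(ValueError):
    """Structured parse error for a recording bundle; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


@dataclasses.dataclass
class AnnotationSet:
    """Expert reference times (seconds, strictly increasing) with text labels."""

    reference_times: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.reference_times = np.asarray(self.reference_times, dtype=float)
        if self.reference_times.ndim != 1:
            raise BundleFormatError("reference_times", "must be a 1-D time vector")
        if len(self.labels) != self.reference_times.size:
            raise BundleFormatError("labels", "label count does not match time count")
        if self.reference_times.size and np.any(np.diff(self.reference_times) <= 0):
            raise BundleFormatError("reference_times", "times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.reference_times.size)


@dataclasses.dataclass
class Recording:
    """Raw two-channel recording: BI in ohm and EMG in arbitrary units at ``fs_raw``."""

    subject_id: int
    series_id: str
    fs_raw: float
    bi_raw: np.ndarray
    emg_raw: np.ndarray
    annotations: AnnotationSet

    def __post_init__(self) -> None:
        if int(self.subject_id) <= 0:
            raise BundleFormatError("subject_id", "must be a positive integer")
        self.subject_id = int(self.subject_id)
        if self.series_id not in VALID_SERIES:
            raise BundleFormatError("series_id", f"must be one of {VALID_SERIES}")
        if not self.fs_raw > 0:
            raise BundleFormatError("fs_raw", "sampling rate must be positive")
        self.bi_raw = np.asarray(self.bi_raw, dtype=float)
        self.emg_raw = np.asarray(self.emg_raw, dtype=float)
        if self.bi_raw.shape != self.emg_raw.shape or self.bi_raw.ndim != 1:
            raise BundleFormatError("bi_raw/emg_raw", "channels must be 1-D and equal length")
        if not (np.all(np.isfinite(self.bi_raw)) and np.all(np.isfinite(self.emg_raw))):
            raise BundleFormatError("bi_raw/emg_raw", "samples must be finite")
        if len(self.annotations) and self.annotations.reference_times[-1] > self.duration:
            raise BundleFormatError(
                "annotations", f"annotation out of range (duration {self.duration:g} s)"
            )
        if len(self.annotations) and self.annotations.reference_times[0] < 0:
            raise BundleFormatError("annotations", "annotation out of range (negative time)")

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.bi_raw.size / self.fs_raw


@dataclasses.dataclass
class CleanSignals:
    """Preprocessed channels: BI @100 Hz, EMG/tEMG/eEMG @1000 Hz."""

    bi: np.ndarray
    emg: np.ndarray
    temg: np.ndarray
    eemg: np.ndarray
    fs_bi: float = 100.0
    fs_emg: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("bi", "emg", "temg", "eemg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name}: non-finite samples after preprocessing")
            setattr(self, name, arr)
        # EMG-rate traces must agree in length; BI decimation ratio within 1 sample
        if not (self.emg.size == self.temg.size == self.eemg.size):
            raise ValueError("emg/temg/eemg lengths inconsistent")
        ratio = self.fs_emg / self.fs_bi
        if abs(self.emg.size / ratio - self.bi.size) > 1:
            raise ValueError("bi length inconsistent with decimation ratio")


def decimate(signal: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Keep every k-th sample, k = fs_in / fs_out (caller must band-limit first).

    The first retained sample is index 0, so output length is ``ceil(n / k)``.
    """
    signal = np.asarray(signal)
    k = fs_in / fs_out
    if abs(k - round(k)) > 1e-9 or k < 1:
        raise ValueError(f"fs_in/fs_out must be a positive integer ratio, got {k:g}")
    return signal[:: int(round(k))]


def _write_float_csv(path: Path, header: str, columns: list[np.ndarray]) -> None:
    buf = _stdio.StringIO()
    buf.write(header + "\n")
    n = len(columns[0]) if columns else 0
    for i in range(n):
        buf.write(",".join(repr(float(c[i])) if c.dtype.kind == "f" else str(int(c[i]))
                           for c in columns) + "\n")
    path.write_text(buf.getvalue())


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as a plain-text bundle directory; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    idx = np.arange(rec.bi_raw.size, dtype=np.int64)
    _write_float_csv(path / "signals.csv", "sample_index,bi_ohm,emg_au",
                     [idx, rec.bi_raw, rec.emg_raw])
    meta = {
        "subject_id": rec.subject_id,
        "series_id": rec.series_id,
        "fs_raw_hz": float(rec.fs_raw),
        "bi_unit": "ohm",
        "emg_unit": "au",
    }
    (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    ann = rec.annotations
    lines = ["time_s,label"]
    lines += [f"{repr(float(t))},{lab}" for t, lab in zip(ann.reference_times, ann.labels)]
    (path / "annotations.csv").write_text("\n".join(lines) + "\n")
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a bundle written by :func:`write_recording`."""
    path = Path(path)
    sig_file = path / "signals.csv"
    meta_file = path / "meta.yaml"
    ann_file = path / "annotations.csv"
    for f, field in ((sig_file, "signals.csv"), (meta_file, "meta.yaml"),
                     (ann_file, "annotations.csv")):
        if not f.exists():
            raise BundleFormatError(field, "missing bundle member")
    meta = yaml.safe_load(meta_file.read_text())
    for key in ("subject_id", "series_id", "fs_raw_hz"):
        if key not in meta:
            raise BundleFormatError(key, "missing metadata key")
    if meta.get("bi_unit", "ohm") != "ohm":
        raise BundleFormatError("bi_unit", f"unit mismatch: expected ohm, got {meta['bi_unit']}")

    header, *rows = sig_file.read_text().splitlines()
    cols = header.split(",")
    if cols != ["sample_index", "bi_ohm", "emg_au"]:
        raise BundleFormatError("signals.csv", f"unexpected columns {cols}")
    data = np.array([[float(v) for v in r.split(",")] for r in rows], dtype=float)
    if data.size == 0:
        data = np.empty((0, 3))
    sample_idx = data[:, 0]
    if sample_idx.size and np.any(np.diff(sample_idx) <= 0):
        raise BundleFormatError("sample_index", "non-monotone sample indices")

    ahead, *arows = ann_file.read_text().splitlines()
    if ahead.split(",") != ["time_s", "label"]:
        raise BundleFormatError("annotations.csv", f"unexpected columns {ahead}")
    times, labels = [], []
    for r in arows:
        if not r.strip():
            continue
        t, lab = r.split(",", 1)
        times.append(float(t))
        labels.append(lab)

    return Recording(
        subject_id=meta["subject_id"],
        series_id=meta["series_id"],
        fs_raw=meta["fs_raw_hz"],
        bi_raw=data[:, 1],
        emg_raw=data[:, 2],
        annotations=AnnotationSet(np.asarray(times), labels),
    )
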