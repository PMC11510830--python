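"""The 12-dimensional feature vector extracted before each candidate onset.

For a candidate at time ``t`` (sample index ``m`` on each channel's own rate)
a data vector of the last ``M_j`` samples up to and including ``m`` is sliced
per feature ``j`` from the BI (100 Hz), clean EMG (1000 Hz) or tEMG (1000 Hz)
channel. Features:

====  =======  ==========================================================
 j    channel  definition
====  =======  ==========================================================
 1    tEMG     standard deviation of the window
 2    tEMG     fraction of window samples strictly above the value at m
 3    tEMG     max of per-sub-window standard deviations
 4    BI       standard deviation of the window
 5    BI       fraction of window samples strictly above the value at m
 6    BI       max of per-sub-window standard deviations
 7    BI       index (1-based) of the sub-window with maximal std
 8    BI       index of the sub-window with minimal std
 9    EMG      average absolute amplitude change (AAC)
 10   EMG      std(second half) − std(first half), two sub-windows
 11   EMG      index of the sub-window with maximal std
 12   EMG      index of the sub-window with minimal std
====  =======  ==========================================================

All standard deviations use the population divisor. Exceedance counts (2, 5)
exclude the reference sample itself and divide by the full window length.
argmax/argmin ties break to the smallest sub-window index.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import CleanSignals

FEATURE_NAMES = [f"x{j}" for j in range(1, 13)]

#: features whose value is a 1-based sub-window index
INDEX_FEATURES = (7, 8, 11, 12)

#: features defined through sub-window standard deviations
TEMPORAL_FEATURES = (3, 6, 7, 8, 11, 12)


class InsufficientHistoryError(ValueError):
    """Raised when a candidate lies too early for the requested window."""


@dataclasses.dataclass
class FeatureConfig:
    """Per-feature window geometry.

    ``delta[j]`` is the sub-window length in samples on the feature's own
    channel rate (0.1 s by default: 10 samples @100 Hz for BI, 100 samples
    @1000 Hz for EMG/tEMG); ``w[j]`` the number of sub-windows for the
    temporal-structure features (so M_j = w[j]*delta[j]); ``m[j]`` the plain
    window length for the scalar features; ``n_max[j]`` caps the sub-window
    count searched by the window-length optimiser.
    """

    delta: dict[int, int] = dataclasses.field(default_factory=dict)
    w: dict[int, int] = dataclasses.field(default_factory=dict)
    m: dict[int, int] = dataclasses.field(default_factory=dict)
    n_max: dict[int, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for j in range(1, 13):
            default_delta = 10 if j in (4, 5, 6, 7, 8) else 100
            self.delta.setdefault(j, default_delta)
            self.n_max.setdefault(j, 10)
        for j in TEMPORAL_FEATURES:
            self.w.setdefault(j, 5)
        self.w[10] = 2  # onset-steepness feature is fixed at two sub-windows
        for j in (1, 2, 4, 5, 9):
            self.m.setdefault(j, 5 * self.delta[j])
        for j in TEMPORAL_FEATURES + (10,):
            self.m[j] = self.w[j] * self.delta[j]
        for j in range(1, 13):
            if self.m[j] <= 0 or self.delta[j] <= 0:
                raise ValueError("window lengths must be positive")
        for j in TEMPORAL_FEATURES:
            if self.w[j] < 2:
                raise ValueError("temporal features need at least 2 sub-windows")

    def window_samples(self, j: int) -> int:
        return self.m[j]


def slice_window(signal: np.ndarray, m_i: int, m_j: int) -> np.ndarray:
    """The last ``m_j`` samples up to and including index ``m_i``."""
    if m_i - m_j + 1 < 0:
        raise InsufficientHistoryError(
            f"window of {m_j} samples does not fit before index {m_i}")
    return np.asarray(signal, dtype=float)[m_i - m_j + 1: m_i + 1]


def window_stats(z: np.ndarray, w: int, delta: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-sub-window mean and population standard deviation."""
    z = np.asarray(z, dtype=float)
    if w < 2:
        raise ValueError("need at least 2 sub-windows")
    if z.size != w * delta:
        raise ValueError(f"window length {z.size} != {w}*{delta}")
    blocks = z.reshape(w, delta)
    return blocks.mean(axis=1), blocks.std(axis=1)


def _exceedance(z: np.ndarray, m_total: int) -> float:
    """Fraction of samples strictly above the last (reference) sample."""
    return float(np.sum(z[:-1] > z[-1])) / m_total


def extract_features(bi: np.ndarray, emg: np.ndarray, temg: np.ndarray,
                     toi_s: float, cfg: FeatureConfig | None = None,
                     fs_bi: float = 100.0, fs_emg: float = 1000.0) -> np.ndarray:
    """Feature vector x1..x12 for one candidate onset time (seconds).

    Raises :class:`InsufficientHistoryError` when the candidate lies too
    early for the largest requested window on any channel.
    """
    cfg = cfg or FeatureConfig()
    m_bi = int(round(toi_s * fs_bi))
    m_emg = int(round(toi_s * fs_emg))
    if m_bi >= len(bi) or m_emg >= min(len(emg), len(temg)):
        raise InsufficientHistoryError("candidate beyond end of signals")

    x = np.empty(12)
    # tEMG features
    x[0] = slice_window(temg, m_emg, cfg.m[1]).std()
    x[1] = _exceedance(slice_window(temg, m_emg, cfg.m[2]), cfg.m[2])
    _, sig3 = window_stats(slice_window(temg, m_emg, cfg.m[3]), cfg.w[3], cfg.delta[3])
    x[2] = sig3.max()
    # BI features
    x[3] = slice_window(bi, m_bi, cfg.m[4]).std()
    x[4] = _exceedance(slice_window(bi, m_bi, cfg.m[5]), cfg.m[5])
    _, sig6 = window_stats(slice_window(bi, m_bi, cfg.m[6]), cfg.w[6], cfg.delta[6])
    x[5] = sig6.max()
    _, sig7 = window_stats(slice_window(bi, m_bi, cfg.m[7]), cfg.w[7], cfg.delta[7])
    x[6] = int(np.argmax(sig7)) + 1
    _, sig8 = window_stats(slice_window(bi, m_bi, cfg.m[8]), cfg.w[8], cfg.delta[8])
    x[7] = int(np.argmin(sig8)) + 1
    # EMG features
    z9 = slice_window(emg, m_emg, cfg.m[9])
    x[8] = float(np.sum(np.abs(np.diff(z9)))) / cfg.m[9]
    _, sig10 = window_stats(slice_window(emg, m_emg, cfg.m[10]), 2, cfg.delta[10])
    x[9] = sig10[1] - sig10[0]
    _, sig11 = window_stats(slice_window(emg, m_emg, cfg.m[11]), cfg.w[11], cfg.delta[11])
    x[10] = int(np.argmax(sig11)) + 1
    _, sig12 = window_stats(slice_window(emg, m_emg, cfg.m[12]), cfg.w[12], cfg.delta[12])
    x[11] = int(np.argmin(sig12)) + 1
    return x


def feature_value(clean: CleanSignals, toi_s: float, j: int, n: int,
                  delta: int) -> float:
    """Value of feature ``j`` for one candidate with ``n`` sub-windows of
    length ``delta`` (window length M = n*delta); used by the window-length
    optimiser to scan window geometries feature by feature."""
    if j in (1, 2, 3):
        sig, m_i = clean.temg, int(round(toi_s * clean.fs_emg))
    elif j in (4, 5, 6, 7, 8):
        sig, m_i = clean.bi, int(round(toi_s * clean.fs_bi))
    else:
        sig, m_i = clean.emg, int(round(toi_s * clean.fs_emg))
    if m_i >= len(sig):
        raise InsufficientHistoryError("candidate beyond end of signals")
    m_total = n * delta
    z = slice_window(sig, m_i, m_total)
    if j in (1, 4):
        return float(z.std())
    if j in (2, 5):
        return _exceedance(z, m_total)
    if j == 9:
        return float(np.sum(np.abs(np.diff(z)))) / m_total
    if j == 10:
        _, sig_n = window_stats(z, 2, m_total // 2)
        return float(sig_n[1] - sig_n[0])
    _, sig_n = window_stats(z, n, delta)
    if j in (3, 6):
        return float(sig_n.max())
    if j in (7, 11):
        return float(np.argmax(sig_n) + 1)
    if j in (8, 12):
        return float(np.argmin(sig_n) + 1)
    raise ValueError(f"unknown feature index {j}")


def build_dataset(clean: CleanSignals, toi_s: np.ndarray, labels: np.ndarray,
                  subject: int, cfg: FeatureConfig | None = None):
    """Feature rows for a set of candidates of one subject.

    Returns ``(X, y, s, kept_times, n_dropped)``; candidates without enough
    history for the largest window are dropped.
    """
    cfg = cfg or FeatureConfig()
    rows, y_out, t_out = [], [], []
    n_dropped = 0
    for t, lab in zip(np.asarray(toi_s, float), np.asarray(labels, int)):
        try:
            rows.append(extract_features(clean.bi, clean.emg, clean.temg, t, cfg,
                                         fs_bi=clean.fs_bi, fs_emg=clean.fs_emg))
        except InsufficientHistoryError:
            n_dropped += 1
            continue
        y_out.append(lab)
        t_out.append(t)
    x_arr = np.asarray(rows) if rows else np.empty((0, 12))
    return (x_arr, np.asarray(y_out, int),
            np.full(len(y_out), subject, dtype=int), np.asarray(t_out), n_dropped)
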