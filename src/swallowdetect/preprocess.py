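"""Causal cleaning of the BI and EMG channels.

All stages are strictly causal IIR filters (the detectors must run online), so
no zero-phase ``filtfilt`` anywhere. Internal filter states are initialised
with a first-sample hold: a constant input produces the constant steady-state
output from sample 0, which avoids spurious onsets from start-up transients.

Stages (sampling rates in parentheses):

* BI: 3rd-order Butterworth low-pass, 15 Hz cut-off (max group delay 0.029 s),
  then decimation 4000 → 100 Hz.
* EMG: despike (Hampel) → 3rd-order Butterworth high-pass 30 Hz → notches at
  the 50/150/250 Hz mains harmonics → pluggable whitening stage (identity by
  default) → 3rd-order high-pass 30 Hz → 2nd-order low-pass 300 Hz (all @4000 Hz).
* tEMG: 3rd-order Butterworth low-pass 10 Hz on the *raw* EMG, 4000 → 1000 Hz.
* eEMG: clean EMG decimated to 1000 Hz, rectified, smoothed by a 3rd-order
  low-pass at 10 Hz.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import signal as sps

from .io import CleanSignals, Recording, decimate

FS_RAW = 4000.0
FS_BI = 100.0
FS_EMG = 1000.0


@dataclasses.dataclass
class PreprocessConfig:
    """Tunable filter parameters of the cleaning chain."""

    bi_lowpass_hz: float = 15.0
    bi_lowpass_order: int = 3
    emg_highpass_hz: float = 30.0
    emg_highpass_order: int = 3
    emg_lowpass_hz: float = 300.0
    emg_lowpass_order: int = 2
    notch_freqs_hz: tuple[float, ...] = (50.0, 150.0, 250.0)
    notch_q: float = 30.0
    trend_lowpass_hz: float = 10.0
    trend_lowpass_order: int = 3
    envelope_lowpass_hz: float = 10.0
    envelope_lowpass_order: int = 3
    despike_window: int = 11
    despike_n_mad: float = 5.0
    # whitening stage: rational transfer function (b, a); identity by default
    whitening_b: tuple[float, ...] = (1.0,)
    whitening_a: tuple[float, ...] = (1.0,)


def causal_filter(b: np.ndarray, a: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Apply an IIR filter causally with first-sample-hold state initialisation."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    zi = sps.lfilter_zi(b, a) * x[0]
    y, _ = sps.lfilter(b, a, x, zi=zi)
    return y


def despike(x: np.ndarray, window: int = 11, n_mad: float = 5.0) -> np.ndarray:
    """Hampel-style spike removal: replace samples deviating more than
    ``n_mad`` scaled MADs from the local median by that median.

    The window trails the current sample (no lookahead) so the stage is as
    causal as the filters around it.
    """
    x = np.asarray(x, dtype=float)
    if x.size < window:
        return x.copy()
    padded = np.pad(x, (window - 1, 0), mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, window)
    med = np.median(win, axis=-1)
    mad = np.median(np.abs(win - med[:, None]), axis=-1)
    # 1.4826 scales MAD to the std of Gaussian noise
    bad = np.abs(x - med) > n_mad * 1.4826 * np.maximum(mad, 1e-12)
    out = x.copy()
    out[bad] = med[bad]
    return out


def clean_bi(bi_raw: np.ndarray, cfg: PreprocessConfig | None = None,
             fs_in: float = FS_RAW) -> np.ndarray:
    """Low-pass the raw BI channel and decimate it to 100 Hz."""
    cfg = cfg or PreprocessConfig()
    b, a = sps.butter(cfg.bi_lowpass_order, cfg.bi_lowpass_hz, btype="low", fs=fs_in)
    if len(bi_raw) < 3 * max(len(b), len(a)):
        warnings.warn("BI input shorter than filter warm-up; output produced anyway")
    return decimate(causal_filter(b, a, bi_raw), fs_in, FS_BI)


def bi_filter_group_delay(cfg: PreprocessConfig | None = None, fs: float = FS_RAW,
                          f_max: float = 100.0, n_points: int = 2048
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Group delay (seconds) of the BI low-pass over [0, f_max] Hz."""
    cfg = cfg or PreprocessConfig()
    b, a = sps.butter(cfg.bi_lowpass_order, cfg.bi_lowpass_hz, btype="low", fs=fs)
    freqs = np.linspace(1e-3, f_max, n_points)
    w, gd = sps.group_delay((b, a), w=freqs, fs=fs)
    return w, gd / fs


def clean_emg(emg_raw: np.ndarray, cfg: PreprocessConfig | None = None,
              fs_in: float = FS_RAW) -> np.ndarray:
    """Clean the raw EMG channel (output stays at the raw rate).

    Chain: despike → high-pass 30 Hz → mains notches → whitening (default
    identity) → high-pass 30 Hz → low-pass 300 Hz.
    """
    cfg = cfg or PreprocessConfig()
    x = despike(emg_raw, cfg.despike_window, cfg.despike_n_mad)
    b_hp, a_hp = sps.butter(cfg.emg_highpass_order, cfg.emg_highpass_hz, btype="high", fs=fs_in)
    x = causal_filter(b_hp, a_hp, x)
    for f0 in cfg.notch_freqs_hz:
        b_n, a_n = sps.iirnotch(f0, cfg.notch_q, fs=fs_in)
        x = causal_filter(b_n, a_n, x)
    if tuple(cfg.whitening_b) != (1.0,) or tuple(cfg.whitening_a) != (1.0,):
        x = causal_filter(np.asarray(cfg.whitening_b, float),
                          np.asarray(cfg.whitening_a, float), x)
    x = causal_filter(b_hp, a_hp, x)
    b_lp, a_lp = sps.butter(cfg.emg_lowpass_order, cfg.emg_lowpass_hz, btype="low", fs=fs_in)
    return causal_filter(b_lp, a_lp, x)


def trend_emg(emg_raw: np.ndarray, cfg: PreprocessConfig | None = None,
              fs_in: float = FS_RAW) -> np.ndarray:
    """Low-frequency trend of the *raw* EMG (tEMG): 10 Hz low-pass, → 1000 Hz."""
    cfg = cfg or PreprocessConfig()
    b, a = sps.butter(cfg.trend_lowpass_order, cfg.trend_lowpass_hz, btype="low", fs=fs_in)
    return decimate(causal_filter(b, a, emg_raw), fs_in, FS_EMG)


def envelope_emg(emg_clean: np.ndarray, cfg: PreprocessConfig | None = None,
                 fs_in: float = FS_RAW) -> np.ndarray:
    """EMG envelope (eEMG): decimate clean EMG to 1000 Hz, rectify, smooth at 10 Hz."""
    cfg = cfg or PreprocessConfig()
    x = np.abs(decimate(np.asarray(emg_clean, float), fs_in, FS_EMG))
    b, a = sps.butter(cfg.envelope_lowpass_order, cfg.envelope_lowpass_hz, btype="low", fs=FS_EMG)
    return causal_filter(b, a, x)


def preprocess_recording(rec: Recording, cfg: PreprocessConfig | None = None) -> CleanSignals:
    """Run the full cleaning chain on a Recording."""
    cfg = cfg or PreprocessConfig()
    emg_clean_raw_rate = clean_emg(rec.emg_raw, cfg, fs_in=rec.fs_raw)
    return CleanSignals(
        bi=clean_bi(rec.bi_raw, cfg, fs_in=rec.fs_raw),
        emg=decimate(emg_clean_raw_rate, rec.fs_raw, FS_EMG),
        temg=trend_emg(rec.emg_raw, cfg, fs_in=rec.fs_raw),
        eemg=envelope_emg(emg_clean_raw_rate, cfg, fs_in=rec.fs_raw),
    )
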