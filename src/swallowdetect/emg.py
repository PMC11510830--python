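"""EMG-only detection of swallow onsets and its parameter grid search.

The detector thresholds the EMG envelope (eEMG, 1000 Hz) against
``theta0 * sigma0``, where ``sigma0`` is an adaptive estimate of the EMG
standard deviation at rest: the running minimum of a sliding-window standard
deviation (window ``n_sigma`` samples, shift 1). An onset fires at sample
``n`` when the ``w`` envelope samples up to and including ``n`` all exceed the
threshold. After an onset the detector is disabled for at least
``refractory_s`` seconds *and* until the envelope has fallen below the
threshold once (the intervention the onset would trigger is running anyway).

Two interchangeable implementations exist: a sample-by-sample streaming
detector (:class:`StreamingEmgDetector`, the online reference) and a
vectorised batch detector used by the grid search; a property test holds them
to identical outputs.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .matching import AssignParams, assign_labels
from .preprocess import FS_EMG


@dataclasses.dataclass
class EmgOnsetParams:
    """Threshold factor, window length and rest-noise estimation parameters."""

    theta0: float = 3.0
    w: int = 100
    n_sigma: int = 250
    refractory_s: float = 1.0
    sigma0_floor: float = 1e-12

    def __post_init__(self) -> None:
        if not self.theta0 > 0:
            raise ValueError("theta0 must be positive")
        if self.w < 1 or self.n_sigma < 2:
            raise ValueError("w must be >= 1 and n_sigma >= 2")

    @property
    def n_start(self) -> int:
        """Warm-up samples excluded from detection."""
        return max(self.w, self.n_sigma)


@dataclasses.dataclass
class OnsetList:
    """Detected EMG onsets: sample indices at 1000 Hz and times in seconds."""

    indices: np.ndarray
    times_s: np.ndarray
    n_skip: int = 0  # samples during which detection was disabled

    def __len__(self) -> int:
        return int(self.indices.size)


def estimate_rest_sigma(emg: np.ndarray, n_sigma: int = 250,
                        sigma0_floor: float = 1e-12) -> np.ndarray:
    """Per-sample rest-noise estimate: causal running minimum of the
    sliding-window standard deviation.

    Samples before the first full window hold the first window's value
    (the estimate before convergence; detection is excluded there anyway).
    The trace is non-increasing and floored at ``sigma0_floor`` so a silent
    channel never produces a zero threshold.
    """
    emg = np.asarray(emg, dtype=float)
    if emg.size < n_sigma:
        raise ValueError("insufficient samples: need at least n_sigma")
    roll = pd.Series(emg).rolling(n_sigma).std(ddof=0).to_numpy()
    roll[: n_sigma - 1] = roll[n_sigma - 1]
    return np.maximum(np.minimum.accumulate(roll), sigma0_floor)


class StreamingEmgDetector:
    """Sample-by-sample EMG onset detector (the online reference semantics)."""

    def __init__(self, params: EmgOnsetParams):
        self.p = params
        self.refractory = int(round(params.refractory_s * FS_EMG))
        self.n = -1
        self.count = 0
        self.armed = True
        self.below_seen = False
        self.n_on = None
        self.n_skip = 0

    def step(self, eemg_sample: float, sigma0_sample: float) -> bool:
        """Feed one envelope sample and its sigma0 value; True on onset."""
        self.n += 1
        above = eemg_sample > self.p.theta0 * sigma0_sample
        self.count = self.count + 1 if above else 0
        if not self.armed:
            if not above:
                self.below_seen = True
            if self.below_seen and self.n - self.n_on >= self.refractory:
                self.armed = True
            else:
                self.n_skip += 1
                return False
        if self.count >= self.p.w and self.n >= self.p.n_start:
            self.armed = False
            self.below_seen = False
            self.n_on = self.n
            return True
        return False


def _runs_above(above: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end (inclusive) indices of maximal runs of True."""
    d = np.diff(above.astype(np.int8), prepend=0, append=0)
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1) - 1


def detect_emg_onsets(eemg: np.ndarray, sigma0: np.ndarray,
                      params: EmgOnsetParams) -> OnsetList:
    """Vectorised batch detection; identical output to the streaming detector."""
    eemg = np.asarray(eemg, dtype=float)
    sigma0 = np.asarray(sigma0, dtype=float)
    if eemg.shape != sigma0.shape:
        raise ValueError("eemg and sigma0 must have equal length")
    m = eemg.size
    above = eemg > params.theta0 * sigma0
    starts, ends = _runs_above(above)
    refractory = int(round(params.refractory_s * FS_EMG))

    onsets: list[int] = []
    n_skip = 0
    n_on = -np.inf
    for s, e in zip(starts, ends):
        # earliest sample in this run satisfying window, warm-up and re-arm rules;
        # the below-threshold re-arm condition holds because runs are separated
        # by at least one below sample
        cand = max(s + params.w - 1, params.n_start)
        if not math.isinf(n_on):
            cand = max(cand, int(n_on) + refractory)
        if cand <= e:
            onsets.append(int(cand))
            n_on = cand
            # disabled samples: from the one after the onset up to (excluding)
            # the re-arm sample, clipped to the end of the recording
            rearm = max(int(n_on) + refractory, e + 1)
            n_skip += min(rearm, m) - int(n_on) - 1
    idx = np.asarray(onsets, dtype=np.int64)
    return OnsetList(indices=idx, times_s=idx / FS_EMG, n_skip=int(n_skip))


DEFAULT_THETA0_GRID = np.arange(1.0, 7.01, 0.5)        # 13 values
DEFAULT_W_GRID = np.arange(50, 301, 25, dtype=int)     # 11 values


@dataclasses.dataclass
class EmgGridResult:
    """Outcome of the delay-constrained grid search."""

    theta0: float
    w: int
    f_matrix: np.ndarray
    mu_matrix: np.ndarray
    delay_constraint_met: bool


def optimize_emg_params(recordings: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                        theta0_grid: np.ndarray | None = None,
                        w_grid: np.ndarray | None = None,
                        theta_mu_d: float = 0.05,
                        theta_la: float = 0.5) -> EmgGridResult:
    """Grid search over (theta0, w) maximising pooled F1 subject to a bound on
    the pooled mean detection delay.

    ``recordings`` is a list of (eemg, sigma0, reference_times) triples.
    F1 per cell is computed from confusion counts pooled over all recordings.
    Cells whose mean delay does not fall below ``theta_mu_d`` are infeasible;
    if no cell is feasible the cell with the smallest mean delay is returned
    with ``delay_constraint_met=False``.
    """
    theta0_grid = DEFAULT_THETA0_GRID if theta0_grid is None else np.asarray(theta0_grid, float)
    w_grid = DEFAULT_W_GRID if w_grid is None else np.asarray(w_grid, int)
    if theta0_grid.size == 0 or w_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")
    ap = AssignParams(theta_la=theta_la)

    f_mat = np.zeros((theta0_grid.size, w_grid.size))
    mu_mat = np.full((theta0_grid.size, w_grid.size), np.nan)
    for k, theta0 in enumerate(theta0_grid):
        for l, w in enumerate(w_grid):
            params = EmgOnsetParams(theta0=float(theta0), w=int(w))
            tp = fp = fn = 0
            delays: list[np.ndarray] = []
            for eemg, sigma0, refs in recordings:
                onsets = detect_emg_onsets(eemg, sigma0, params)
                match = assign_labels(onsets.times_s, refs, ap)
                tp += match.it
                fp += match.if_
                fn += match.fn
                delays.append(match.delays)
            if tp + fp + fn > 0:
                f_mat[k, l] = 2 * tp / (2 * tp + fp + fn)
            # else: degenerate cell, F stays 0
            d = np.concatenate(delays) if delays else np.empty(0)
            if d.size:
                mu_mat[k, l] = float(np.mean(d))

    feasible = mu_mat < theta_mu_d  # NaN compares False → infeasible
    if feasible.any():
        f_masked = np.where(feasible, f_mat, -np.inf)
        k, l = np.unravel_index(int(np.argmax(f_masked)), f_mat.shape)
        met = True
    else:
        mu_abs = np.where(np.isnan(mu_mat), np.inf, mu_mat)
        k, l = np.unravel_index(int(np.argmin(mu_abs)), mu_mat.shape)
        met = False
    return EmgGridResult(theta0=float(theta0_grid[k]), w=int(w_grid[l]),
                         f_matrix=f_mat, mu_matrix=mu_mat, delay_constraint_met=met)
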