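"""Evaluation scores: delay statistics, preselection scores, confusion scores.

Conventions fixed here so reported numbers are reproducible:

* the delay standard deviation uses the population divisor (1/N, not 1/(N−1));
* undefined ratios (0/0) propagate as NaN, never silently 0 — except the
  sensitivity/precision/F1 triple, which is 0 when TP = 0 with FP + FN > 0;
* the IQR uses linear interpolation between order statistics (numpy default).
"""

from __future__ import annotations

import math

import numpy as np


def delay_stats(delays: np.ndarray) -> tuple[float, float]:
    """Mean and population standard deviation of the detection delays."""
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise ValueError("no detections: delay vector is empty")
    return float(np.mean(delays)), float(np.std(delays))


def preselection_scores(it: int, if_: int, r: int) -> tuple[float, float]:
    """True-to-false candidate ratio Υ = It/If and sensitivity S_PS = It/R.

    ``If = 0`` with ``It > 0`` makes Υ infinite; the +inf sentinel is returned
    so callers can flag it explicitly.
    """
    if r <= 0:
        raise ValueError("reference count R must be positive")
    if it == 0:
        ratio = 0.0
    elif if_ == 0:
        ratio = math.inf
    else:
        ratio = it / if_
    return ratio, it / r


def classification_scores(tp: int, fn: int, fp: int, tn: int
                          ) -> tuple[float, float, float, float]:
    """Sensitivity, precision, specificity, F1 from a confusion table.

    Returns NaN for a genuinely undefined score (0/0 with no events of the
    relevant kind), with the exception that S = P = F = 0 when TP = 0 but
    FP + FN > 0 (there were events and the detector got none).
    """
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("confusion counts must be non-negative")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    s = ratio(tp, tp + fn)
    p = ratio(tp, tp + fp)
    c = ratio(tn, tn + fp)
    f = ratio(2 * tp, 2 * tp + fp + fn)
    if tp == 0 and fp + fn > 0:
        s, p, f = 0.0, 0.0, 0.0
    return s, p, c, f


def summarize_scores(values: np.ndarray) -> tuple[float, float]:
    """Median and interquartile range (Q3 − Q1) of per-subject scores."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no scores to summarize")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q3 - q1)
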