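"""Distribution-overlap feature relevance and window-length optimisation.

The relevance of a feature is measured by the overlap
``η(A, B) = ∫ min(f_A, f_B) dx`` of the class-conditional densities of its
values over true (swallow) and false (non-swallow) samples: η → 1 for
indistinguishable classes, η → 0 for disjoint supports. Continuous features
use Gaussian kernel density estimates with Silverman bandwidth, integrated on
a fine grid spanning the pooled range plus three bandwidths; integer-valued
features (the sub-window-index features) use the discrete probability-mass
overlap ``Σ min(p_A, p_B)`` instead.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

MIN_SAMPLES_PER_CLASS = 10


def _discrete_overlap(a: np.ndarray, b: np.ndarray) -> float:
    values = np.union1d(a, b)
    pa = np.array([np.mean(a == v) for v in values])
    pb = np.array([np.mean(b == v) for v in values])
    return float(np.minimum(pa, pb).sum())


def estimate_overlap(a: np.ndarray, b: np.ndarray, discrete: bool = False,
                     grid_points: int = 2048) -> float:
    """Overlap coefficient η ∈ [0, 1] of two one-dimensional samples.

    Degenerate (zero-variance) samples fall back to the discrete
    point-mass overlap, as do explicitly integer-valued features.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < MIN_SAMPLES_PER_CLASS or b.size < MIN_SAMPLES_PER_CLASS:
        raise ValueError(f"need at least {MIN_SAMPLES_PER_CLASS} samples per class")
    if discrete or np.std(a) == 0 or np.std(b) == 0:
        return _discrete_overlap(a, b)

    kde_a = stats.gaussian_kde(a, bw_method="silverman")
    kde_b = stats.gaussian_kde(b, bw_method="silverman")
    bw = max(np.sqrt(kde_a.covariance[0, 0]), np.sqrt(kde_b.covariance[0, 0]))
    lo = min(a.min(), b.min()) - 3 * bw
    hi = max(a.max(), b.max()) + 3 * bw
    grid = np.linspace(lo, hi, grid_points)
    eta = float(np.trapezoid(np.minimum(kde_a(grid), kde_b(grid)), grid))
    return min(eta, 1.0)


def optimize_window_length(dataset_builder, n_max: int,
                           discrete: bool = False) -> tuple[int, dict[int, float]]:
    """Pick the sub-window count with the smallest class overlap.

    ``dataset_builder(n)`` must return ``(a, b)``, the feature values of the
    true and false classes when the feature is computed with ``n``
    sub-windows (window length ``n * delta``). Counts ``n = 2..n_max`` are
    scanned; any ``n`` with fewer than 10 samples in either class is excluded
    (logged). Ties break to the smallest ``n``. Returns ``(n_opt, etas)``.
    """
    if n_max < 2:
        raise ValueError("n_max must be at least 2")
    etas: dict[int, float] = {}
    for n in range(2, n_max + 1):
        a, b = dataset_builder(n)
        try:
            etas[n] = estimate_overlap(a, b, discrete=discrete)
        except ValueError as exc:
            log.info("window count %d excluded: %s", n, exc)
    if not etas:
        raise ValueError("no window count had enough samples in both classes")
    n_opt = min(etas, key=lambda n: (etas[n], n))
    return n_opt, etas
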