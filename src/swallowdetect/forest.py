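"""Class-weighted random forest, hyperparameter sampling, nested LOSO selection.

The classifier is a scikit-learn ``Pipeline(StandardScaler, RandomForest)``
with 100 Gini trees, sqrt feature subsampling and bootstrap bagging. Class
weights follow the printed convention of the method this package implements:

    ω0 = weight0 · If / (2 I),    ω1 = weight1 · It / (2 I)

i.e. each class is weighted *proportionally* to its own frequency times a
tunable multiplier (``weighting="printed"``). The more common
inverse-frequency "balanced" weighting is available as
``weighting="inverse_frequency"`` (ωk = weightk · I / (2 · count_k)).

Model selection runs a nested leave-one-subject-out (LOSO) cross-validation:
the outer loop holds out one subject for unbiased testing; the inner loop
scores every hyperparameter vector on each remaining subject, giving an
F1 matrix O and a complexity matrix C (total leaf count of the forest). The
selection rule is a one-standard-error rule with a correlation-modified
standard error and a lowest-complexity tie-break.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

WEIGHT1_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

#: uniform random-search ranges for the four regularisation parameters
RANDOM_RANGES = {
    "ccp_alpha": (0.0, 0.00125),
    "min_impurity_decrease": (0.0, 0.001),
    "min_weight_fraction_leaf": (0.0, 0.0025),
    "max_samples": (0.65, 0.85),
}


@dataclasses.dataclass
class RfConfig:
    """Forest hyperparameters; fixed values follow the reference setup."""

    n_trees: int = 100
    seed: int = 1
    weight0: float = 1.0
    weight1: float = 1.0
    ccp_alpha: float = 0.0
    min_impurity_decrease: float = 0.0
    min_weight_fraction_leaf: float = 0.0
    max_samples: float | None = None
    weighting: str = "printed"  # or "inverse_frequency"


def class_weights(i_total: int, it: int, if_: int, weight0: float = 1.0,
                  weight1: float = 1.0, weighting: str = "printed"
                  ) -> tuple[float, float]:
    """Per-class sample weights ω0, ω1 from the class counts."""
    if i_total <= 0 or it + if_ != i_total:
        raise ValueError("need I = It + If > 0")
    if weighting == "printed":
        return weight0 * if_ / (2 * i_total), weight1 * it / (2 * i_total)
    if weighting == "inverse_frequency":
        w0 = weight0 * i_total / (2 * if_) if if_ else 0.0
        w1 = weight1 * i_total / (2 * it) if it else 0.0
        return w0, w1
    raise ValueError(f"unknown weighting {weighting!r}")


def sample_hyperparams(weight1_grid=WEIGHT1_GRID, n_random: int = 200,
                       seed: int = 1) -> list[dict]:
    """Mixed search space: Cartesian product of the weight1 grid with
    ``n_random`` uniform draws of the four regularisation parameters."""
    rng = np.random.default_rng(seed)
    draws = [
        {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in RANDOM_RANGES.items()}
        for _ in range(n_random)
    ]
    return [
        {"weight1": float(w1), **d}
        for w1, d in itertools.product(weight1_grid, draws)
    ]


def _make_pipeline(cfg: RfConfig, w0: float, w1: float) -> Pipeline:
    rf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=cfg.seed,
        class_weight={0: w0, 1: w1},
        ccp_alpha=cfg.ccp_alpha,
        min_impurity_decrease=cfg.min_impurity_decrease,
        min_weight_fraction_leaf=cfg.min_weight_fraction_leaf,
        max_samples=cfg.max_samples,
        # splitting limits disabled (defaults): min_samples_split=2,
        # min_samples_leaf=1, max_depth=None, max_leaf_nodes=None
    )
    return Pipeline([("scaler", StandardScaler()), ("forest", rf)])


def train_rf(x: np.ndarray, y: np.ndarray, cfg: RfConfig | None = None
             ) -> tuple[Pipeline, int]:
    """Fit the scaler+forest pipeline; returns (model, total leaf count)."""
    cfg = cfg or RfConfig()
    y = np.asarray(y, int)
    it = int((y == 1).sum())
    if_ = int((y == 0).sum())
    if it == 0 or if_ == 0:
        raise ValueError("training data must contain both classes")
    w0, w1 = class_weights(len(y), it, if_, cfg.weight0, cfg.weight1, cfg.weighting)
    model = _make_pipeline(cfg, w0, w1)
    model.fit(x, y)
    complexity = int(sum(t.get_n_leaves() for t in model["forest"].estimators_))
    return model, complexity


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    return 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0


def _cfg_from_lambda(lam: dict, base: RfConfig) -> RfConfig:
    return dataclasses.replace(base, weight1=lam["weight1"],
                               ccp_alpha=lam["ccp_alpha"],
                               min_impurity_decrease=lam["min_impurity_decrease"],
                               min_weight_fraction_leaf=lam["min_weight_fraction_leaf"],
                               max_samples=lam["max_samples"])


def select_hyperparams(o_mat: np.ndarray, c_mat: np.ndarray) -> int:
    """One-standard-error selection with complexity tie-break.

    1. row means μ_l of the F1 matrix; 2. l_max = argmax μ_l;
    3. σ_se = population std of the best row / sqrt(folds), modified per row
       by sqrt(1 − ρ_l) with ρ_l the Pearson correlation to the best row
       (ρ_l = 0 for zero-variance rows);
    4. among rows with μ_l ∈ [μ_lmax − σ_l_mod, μ_lmax], return the one with
       the lowest mean complexity.
    """
    o_mat = np.asarray(o_mat, dtype=float)
    c_mat = np.asarray(c_mat, dtype=float)
    mu = o_mat.mean(axis=1)
    l_max = int(np.argmax(mu))
    best = o_mat[l_max]
    sigma_se = float(np.std(best)) / np.sqrt(o_mat.shape[1])

    candidates = []
    for l in range(o_mat.shape[0]):
        if np.std(best) == 0 or np.std(o_mat[l]) == 0:
            rho = 0.0
        else:
            rho = float(np.corrcoef(best, o_mat[l])[0, 1])
        sigma_mod = sigma_se * np.sqrt(max(0.0, 1.0 - rho))
        if mu[l_max] - sigma_mod <= mu[l] <= mu[l_max]:
            candidates.append(l)
    if not candidates:  # l_max itself always qualifies unless ρ undefined
        candidates = [l_max]
    c_means = c_mat.mean(axis=1)
    return int(min(candidates, key=lambda l: (c_means[l], l)))


@dataclasses.dataclass
class NestedLosoResult:
    """Per held-out subject: unbiased F1, chosen hyperparameters, confusion."""

    subjects: list[int]
    f1: np.ndarray
    chosen_lambda: list[dict]
    confusions: list[tuple[int, int, int, int]]
    predictions: dict[int, np.ndarray]


def nested_loso(x: np.ndarray, y: np.ndarray, s: np.ndarray,
                lambda_list: list[dict], base_cfg: RfConfig | None = None
                ) -> NestedLosoResult:
    """Nested leave-one-subject-out selection and test.

    Subjects without at least one sample of each class are skipped as inner
    validation folds (their data still trains) and as outer test subjects.
    """
    base_cfg = base_cfg or RfConfig()
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    s = np.asarray(s, int)
    subjects = np.unique(s)
    usable = [int(sub) for sub in subjects
              if ((y[s == sub] == 1).any() and (y[s == sub] == 0).any())]
    if len(usable) < 3:
        raise ValueError("nested LOSO needs at least 3 subjects with both classes")

    out_subjects, out_f1, out_lambda, out_conf = [], [], [], {}
    predictions: dict[int, np.ndarray] = {}
    for s_test in usable:
        inner_subjects = [sub for sub in usable if sub != s_test]
        o_mat = np.zeros((len(lambda_list), len(inner_subjects)))
        c_mat = np.zeros_like(o_mat)
        for col, s_val in enumerate(inner_subjects):
            train_mask = (s != s_test) & (s != s_val)
            val_mask = s == s_val
            for row, lam in enumerate(lambda_list):
                model, leaves = train_rf(x[train_mask], y[train_mask],
                                         _cfg_from_lambda(lam, base_cfg))
                o_mat[row, col] = _f1(y[val_mask], model.predict(x[val_mask]))
                c_mat[row, col] = leaves
        l_opt = select_hyperparams(o_mat, c_mat)
        model, _ = train_rf(x[s != s_test], y[s != s_test],
                            _cfg_from_lambda(lambda_list[l_opt], base_cfg))
        y_pred = model.predict(x[s == s_test])
        y_true = y[s == s_test]
        out_subjects.append(s_test)
        out_f1.append(_f1(y_true, y_pred))
        out_lambda.append(lambda_list[l_opt])
        out_conf[s_test] = (
            int(np.sum((y_pred == 1) & (y_true == 1))),
            int(np.sum((y_pred == 1) & (y_true == 0))),
            int(np.sum((y_pred == 0) & (y_true == 1))),
            int(np.sum((y_pred == 0) & (y_true == 0))),
        )
        predictions[s_test] = y_pred

    return NestedLosoResult(
        subjects=out_subjects,
        f1=np.asarray(out_f1),
        chosen_lambda=out_lambda,
        confusions=[out_conf[sub] for sub in out_subjects],
        predictions=predictions,
    )
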