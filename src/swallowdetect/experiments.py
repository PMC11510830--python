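"""End-to-end experiments: EMG-only vs BI/EMG detection with LOSO evaluation.

Both experiment drivers take a list of :class:`~swallowdetect.io.Recording`
(one or more per subject) plus an :class:`ExperimentConfig` and produce a
plain-dict report (JSON-serialisable, deterministic under a fixed seed):
per-subject scores, median[IQR] summaries and pooled delay statistics.
"""

from __future__ import annotations

import dataclasses
import json
from collections import defaultdict
from pathlib import Path

import numpy as np

from .emg import EmgOnsetParams, detect_emg_onsets, estimate_rest_sigma, optimize_emg_params
from .features import FeatureConfig, build_dataset, feature_value
from .forest import RfConfig, nested_loso, sample_hyperparams
from .io import CleanSignals, Recording
from .matching import AssignParams, apply_skip, assign_labels, emg_confusion
from .preprocess import PreprocessConfig, preprocess_recording
from .preselect import PreselectParams, preselect_signal
from .relevance import optimize_window_length
from .scores import classification_scores, delay_stats, preselection_scores, summarize_scores


@dataclasses.dataclass
class ExperimentConfig:
    """All stage parameters of the two experiments."""

    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    preselect: PreselectParams = dataclasses.field(default_factory=PreselectParams)
    assign: AssignParams = dataclasses.field(default_factory=AssignParams)
    features: FeatureConfig = dataclasses.field(default_factory=FeatureConfig)
    rf: RfConfig = dataclasses.field(default_factory=RfConfig)
    theta_mu_d: float = 0.05
    n_sigma: int = 250
    n_random_hyperparams: int = 8
    seed: int = 1


def _summary(per_subject: dict[str, list[float]]) -> dict[str, float]:
    out = {}
    for name, vals in per_subject.items():
        arr = np.asarray(vals, float)
        arr = arr[~np.isnan(arr)]
        med, iqr = summarize_scores(arr) if arr.size else (float("nan"), float("nan"))
        out[f"{name}_median"] = med
        out[f"{name}_iqr"] = iqr
    return out


def _group_by_subject(recordings: list[Recording]) -> dict[int, list[Recording]]:
    groups: dict[int, list[Recording]] = defaultdict(list)
    for rec in recordings:
        groups[rec.subject_id].append(rec)
    return dict(sorted(groups.items()))


def run_emg_experiment(recordings: list[Recording],
                       cfg: ExperimentConfig | None = None) -> dict:
    """LOSO evaluation of the EMG-only detector.

    For each held-out subject the (theta0, w) grid search runs on the pooled
    recordings of the remaining subjects under the mean-delay constraint
    ``theta_mu_d``; the tuned detector is then scored on the held-out subject.
    """
    cfg = cfg or ExperimentConfig()
    groups = _group_by_subject(recordings)
    if len(groups) < 2:
        raise ValueError("LOSO needs >= 2 subjects")

    # preprocess once; triple = (eemg, sigma0 trace, reference times)
    triples: dict[int, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
    for subject, recs in groups.items():
        triples[subject] = []
        for rec in recs:
            clean = preprocess_recording(rec, cfg.preprocess)
            sigma0 = estimate_rest_sigma(clean.emg, cfg.n_sigma)
            triples[subject].append((clean.eemg, sigma0,
                                     rec.annotations.reference_times))

    per_subject = {"sensitivity": [], "precision": [], "specificity": [], "f1": []}
    rows = []
    all_delays = []
    for s_test in groups:
        train = [t for subject, ts in triples.items() if subject != s_test for t in ts]
        grid = optimize_emg_params(train, theta_mu_d=cfg.theta_mu_d,
                                   theta_la=cfg.assign.theta_la)
        params = EmgOnsetParams(theta0=grid.theta0, w=grid.w, n_sigma=cfg.n_sigma)
        tp = fp = fn = tn = 0
        for eemg, sigma0, refs in triples[s_test]:
            onsets = detect_emg_onsets(eemg, sigma0, params)
            match = assign_labels(onsets.times_s, refs, cfg.assign)
            c = emg_confusion(match, len(eemg), onsets.n_skip, params.n_start)
            tp, fp, fn, tn = tp + c[0], fp + c[1], fn + c[2], tn + c[3]
            all_delays.append(match.delays)
        s, p, c_, f = classification_scores(tp, fn, fp, tn)
        per_subject["sensitivity"].append(s)
        per_subject["precision"].append(p)
        per_subject["specificity"].append(c_)
        per_subject["f1"].append(f)
        rows.append({"subject": s_test, "theta0": grid.theta0, "w": grid.w,
                     "delay_constraint_met": grid.delay_constraint_met,
                     "sensitivity": s, "precision": p, "specificity": c_, "f1": f})

    delays = np.concatenate(all_delays) if all_delays else np.empty(0)
    mu_d, sigma_d = delay_stats(delays) if delays.size else (float("nan"), float("nan"))
    return {"method": "emg", "per_subject": rows, "summary": _summary(per_subject),
            "mu_d": mu_d, "sigma_d": sigma_d, "n_subjects": len(groups)}


def _preselect_and_label(clean: CleanSignals, refs: np.ndarray,
                         cfg: ExperimentConfig):
    """BI preselection + greedy labeling + post-onset skip for one recording.

    Returns (times, labels, match) where ``times``/``labels`` are the
    surviving candidates in chronological order with their class labels.
    """
    toi = preselect_signal(clean.bi, cfg.preselect, fs=clean.fs_bi)
    match = assign_labels(toi, refs, cfg.assign)
    match = apply_skip(match, cfg.assign.theta_skip)
    times = np.concatenate([match.matched_times, match.false_times])
    labels = np.concatenate([np.ones(match.it, int), np.zeros(match.if_, int)])
    order = np.argsort(times)
    return times[order], labels[order], match


def run_biemg_experiment(recordings: list[Recording],
                         cfg: ExperimentConfig | None = None) -> dict:
    """Preselection → features → nested-LOSO random forest, with reports.

    Per-subject confusion counts are taken at the classifier level on the
    preselected candidate set; swallows missed by the preselection itself are
    reported through the pooled preselection sensitivity.
    """
    cfg = cfg or ExperimentConfig()
    groups = _group_by_subject(recordings)
    if len(groups) < 3:
        raise ValueError("nested LOSO needs >= 3 subjects")

    x_parts, y_parts, s_parts = [], [], []
    it_total = if_total = r_total = 0
    n_dropped = 0
    all_delays = []
    for subject, recs in groups.items():
        for rec in recs:
            clean = preprocess_recording(rec, cfg.preprocess)
            times, labels, match = _preselect_and_label(
                clean, rec.annotations.reference_times, cfg)
            it_total += match.it
            if_total += match.if_
            r_total += match.n_refs
            all_delays.append(match.delays)
            x, y, s, _, dropped = build_dataset(clean, times, labels, subject,
                                                cfg.features)
            n_dropped += dropped
            x_parts.append(x)
            y_parts.append(y)
            s_parts.append(s)

    x = np.concatenate(x_parts)
    y = np.concatenate(y_parts)
    s = np.concatenate(s_parts)
    delays = np.concatenate(all_delays) if all_delays else np.empty(0)
    ratio, s_ps = preselection_scores(it_total, if_total, r_total)
    mu_d, sigma_d = delay_stats(delays) if delays.size else (float("nan"), float("nan"))

    lambda_list = sample_hyperparams(n_random=cfg.n_random_hyperparams, seed=cfg.seed)
    result = nested_loso(x, y, s, lambda_list, cfg.rf)

    per_subject = {"sensitivity": [], "precision": [], "specificity": [], "f1": []}
    rows = []
    for subject, f1, lam, conf in zip(result.subjects, result.f1,
                                      result.chosen_lambda, result.confusions):
        tp, fp, fn, tn = conf
        s_, p_, c_, f_ = classification_scores(tp, fn, fp, tn)
        per_subject["sensitivity"].append(s_)
        per_subject["precision"].append(p_)
        per_subject["specificity"].append(c_)
        per_subject["f1"].append(f_)
        rows.append({"subject": subject, "weight1": lam["weight1"],
                     "sensitivity": s_, "precision": p_, "specificity": c_,
                     "f1": f_})

    return {
        "method": "biemg",
        "per_subject": rows,
        "summary": _summary(per_subject),
        "preselection": {"ratio": ratio, "sensitivity": s_ps,
                         "it": it_total, "if": if_total, "r": r_total,
                         "n_dropped_for_history": n_dropped},
        "mu_d": mu_d, "sigma_d": sigma_d,
        "n_subjects": len(result.subjects),
    }


def tune_feature_windows(recordings: list[Recording],
                         cfg: ExperimentConfig | None = None,
                         n_max: int | None = None) -> tuple[FeatureConfig, dict]:
    """Per-feature window-length optimisation by minimal class overlap.

    Pools the labeled candidates of all supplied recordings, evaluates the
    overlap of each feature for sub-window counts n = 2..n_max and returns an
    updated :class:`FeatureConfig` plus the per-feature overlap curves.
    """
    cfg = cfg or ExperimentConfig()
    prepared = []
    for rec in recordings:
        clean = preprocess_recording(rec, cfg.preprocess)
        times, labels, _ = _preselect_and_label(
            clean, rec.annotations.reference_times, cfg)
        prepared.append((clean, times, labels))

    from .features import INDEX_FEATURES  # local alias for clarity

    new_cfg = FeatureConfig(delta=dict(cfg.features.delta),
                            n_max=dict(cfg.features.n_max))
    etas_report: dict[int, dict[int, float]] = {}
    for j in range(1, 13):
        if j == 10:
            continue  # fixed two-window steepness feature

        def builder(n: int, j=j):
            a_vals, b_vals = [], []
            for clean, times, labels in prepared:
                for t, lab in zip(times, labels):
                    try:
                        v = feature_value(clean, t, j, n, cfg.features.delta[j])
                    except ValueError:
                        continue
                    (a_vals if lab == 1 else b_vals).append(v)
            return np.asarray(a_vals), np.asarray(b_vals)

        n_opt, etas = optimize_window_length(
            builder, n_max or cfg.features.n_max[j],
            discrete=j in INDEX_FEATURES)
        etas_report[j] = etas
        if j in (3, 6, 7, 8, 11, 12):
            new_cfg.w[j] = n_opt
        else:
            new_cfg.m[j] = n_opt * new_cfg.delta[j]
    return FeatureConfig(delta=new_cfg.delta, w=new_cfg.w,
                         m={j: new_cfg.m[j] for j in (1, 2, 4, 5, 9)},
                         n_max=new_cfg.n_max), etas_report


def write_report(report: dict, path: str | Path) -> Path:
    """Serialise a report deterministically (sorted keys, repr floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, sort_keys=True, indent=1, default=float) + "\n")
    return path
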