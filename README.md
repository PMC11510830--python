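# swallowdetect

Causal detection of swallow onsets from neck **bioimpedance (BI)** and
**surface EMG**, with the evaluation machinery needed to compare detectors
fairly across subjects.

During the pharyngeal phase of swallowing the larynx elevates, which
produces a transient valley in the trans-laryngeal bioimpedance and is
preceded (~0.5 s) by submental EMG activity. Detecting the phase onset in
real time is the trigger problem behind closed-loop dysphagia therapy
(e.g. stimulation synchronised to the swallow). This package implements two
online-capable detectors:

* **EMG-only** — threshold the rectified, smoothed EMG envelope against
  `θ_EMG = θ0·σ0`, where σ0 is a running-minimum estimate of the rest-noise
  SD; an onset fires when `w` consecutive envelope samples exceed the
  threshold, with a 1 s refractory. `(θ0, w)` are grid-searched under a
  mean-delay constraint.
* **BI/EMG** — a streaming BI drop detector proposes candidate onsets
  (fires when the signal falls more than `θ_PS = 0.18 Ω` below the last
  local maximum); a 12-dimensional feature vector over trailing BI, EMG and
  EMG-trend windows is extracted per candidate; a class-weighted random
  forest (100 trees) separates swallows from head movements and other
  distractors, with hyperparameters chosen by a nested leave-one-subject-out
  (LOSO) search using a correlation-adjusted one-standard-error rule and a
  lowest-complexity tie-break.

Evaluation follows the event-matching convention: candidates are greedily
assigned to expert reference times within `θ_LA = 0.5 s`, delays are signed
(candidate − reference, population SD), non-swallow events within 1 s after
a detected swallow are discarded, and per-subject scores are summarised as
median [IQR]. A seeded synthetic cohort generator (BI valley morphology and
timing statistics, premonitory EMG bursts, mains interference, spikes,
distractors) makes the whole pipeline testable without clinical data.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

```python
from swallowdetect import SyntheticConfig, generate_dataset, \
    run_biemg_experiment, run_emg_experiment
from swallowdetect.experiments import ExperimentConfig

cohort = generate_dataset(SyntheticConfig(seed=1))   # 10 subjects
cfg = ExperimentConfig(seed=1)

emg = run_emg_experiment(cohort, cfg)
biemg = run_biemg_experiment(cohort, cfg)
print("EMG-only  median F1:", round(emg["summary"]["f1_median"], 3))
print("BI/EMG    median F1:", round(biemg["summary"]["f1_median"], 3))
print("preselection sensitivity:", biemg["preselection"]["sensitivity"],
      " mean delay:", round(biemg["mu_d"], 3), "s")
```

prints

```
EMG-only  median F1: 0.923
BI/EMG    median F1: 1.0
preselection sensitivity: 1.0  mean delay: 0.07 s
```

On this cohort the BI preselection recovers every annotated swallow
(sensitivity 1.0) about 70 ms after the descent start — the time the BI
needs to fall 0.18 Ω — and the BI/EMG classifier rejects the distractors the
EMG-only detector confuses with swallows, so its median F1 is higher. The
synthetic distractors are deliberately one-channel (BI dips without EMG, EMG
bursts without BI), so absolute scores are optimistic relative to clinical
data; the *ordering* of the two methods is the meaningful outcome.

A thin CLI wraps the same functions:

```bash
swallowdetect simulate --n-subjects 10 --seed 1 --out data/
swallowdetect preselect data/subject_001 --theta-ps 0.18
swallowdetect evaluate data/ --method biemg --seed 1 --out report.json
```

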