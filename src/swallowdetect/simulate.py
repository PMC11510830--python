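"""Synthetic two-channel swallow recordings with ground-truth annotations.

The generator emulates the statistical structure of clinical neck BI/EMG
recordings so the whole pipeline is testable without patient data:

* BI swallow valleys whose start-to-minimum drop duration is Normal(0.39 s,
  0.14 s) and whose total duration is Normal(0.763 s, 0.205 s), preceded by a
  small positive BI bump (the oral-phase peak). The descent is a quarter-sine
  (steep at the descent start, smooth at the minimum): clinical preselection
  timing — a mean delay near 0.04 s at a 0.18 Ω drop threshold — implies real
  valleys cross the threshold early in the drop, which a symmetric
  raised-cosine start would not reproduce.
* A surface-EMG burst beginning on average 0.5 s before the annotated
  pharyngeal onset: band-limited white noise under a trapezoidal gain.
* Distractors: "head movement" (slow BI dip, no EMG burst), "speech" and
  "chew" (EMG bursts without a BI valley), mains interference at
  50/150/250 Hz, isolated spikes, slow BI drift and additive noise.

The annotated reference time of every swallow is the start of its BI descent.
All randomness flows from ``SyntheticConfig.seed``; subject-level parameters
(baseline impedance, EMG burst gain, …) are drawn per subject for
inter-subject variability.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import AnnotationSet, Recording

FS = 4000.0


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions of the generated cohort (defaults = the emulated ones)."""

    n_subjects: int = 10
    n_swallows_per_subject: int = 6
    n_distractors_per_subject: int = 6
    bi_baseline_ohm: tuple[float, float] = (400.0, 600.0)
    valley_depth_ohm: tuple[float, float] = (0.3, 1.5)
    drop_duration_s: tuple[float, float] = (0.39, 0.14)      # mean, sd
    drop_duration_bounds: tuple[float, float] = (0.1, 1.0)
    valley_duration_s: tuple[float, float] = (0.763, 0.205)  # mean, sd
    valley_duration_bounds: tuple[float, float] = (0.3, 1.5)
    pre_peak_ohm: tuple[float, float] = (0.03, 0.08)
    emg_lead_s: tuple[float, float] = (0.5, 0.15)            # mean, sd
    emg_lead_bounds: tuple[float, float] = (0.2, 0.8)
    emg_burst_gain: tuple[float, float] = (4.0, 7.0)         # per-subject range
    rest_noise_sigma: float = 1.0
    bi_noise_sigma: float = 0.01
    bi_drift_ohm: float = 0.07
    mains_amplitudes: tuple[float, float, float] = (0.5, 0.2, 0.1)
    spike_rate_hz: float = 0.2
    distractor_types: tuple[str, ...] = ("head_move", "speech", "chew")
    event_spacing_s: tuple[float, float] = (3.2, 4.2)
    warmup_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for lo, hi in (self.drop_duration_bounds, self.valley_duration_bounds,
                       self.emg_lead_bounds):
            if not 0 < lo < hi:
                raise ValueError("duration bounds must be positive and ordered")
        if self.event_spacing_s[0] < 3.0:
            raise ValueError("events must be separated by at least 3 s")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def _add_valley(bi: np.ndarray, t0: float, depth: float, t_drop: float,
                t_total: float, pre_peak: float) -> None:
    """Add a swallow valley whose descent starts at t0 (the annotated onset)."""
    t_total = max(t_total, t_drop + 0.15)
    # oral-phase bump: raised cosine ending at the descent start
    t_bump = 0.3
    i0 = int(round((t0 - t_bump) * FS))
    n_bump = int(round(t_bump * FS))
    tau = np.arange(n_bump) / FS
    bi[i0:i0 + n_bump] += pre_peak * 0.5 * (1 - np.cos(2 * np.pi * tau / t_bump))
    # descent: quarter-sine, steep at onset, flat at the minimum
    i1 = int(round(t0 * FS))
    n_drop = int(round(t_drop * FS))
    tau = np.arange(n_drop) / FS
    bi[i1:i1 + n_drop] -= depth * np.sin(0.5 * np.pi * tau / t_drop)
    # recovery: raised-cosine rise back to baseline
    t_rec = t_total - t_drop
    i2 = i1 + n_drop
    n_rec = int(round(t_rec * FS))
    tau = np.arange(n_rec) / FS
    bi[i2:i2 + n_rec] -= depth * 0.5 * (1 + np.cos(np.pi * tau / t_rec))


def _add_head_move(bi: np.ndarray, t0: float, depth: float, duration: float) -> None:
    """Slow symmetric BI dip (no EMG context): raised-cosine excursion."""
    i0 = int(round(t0 * FS))
    n = int(round(duration * FS))
    tau = np.arange(n) / FS
    bi[i0:i0 + n] -= depth * 0.5 * (1 - np.cos(2 * np.pi * tau / duration))


def _add_burst(emg: np.ndarray, rng: np.random.Generator, t_start: float,
               duration: float, gain: float, attack: float = 0.15,
               release: float = 0.25) -> None:
    """Amplitude-modulated white-noise EMG burst with a trapezoidal profile."""
    i0 = int(round(t_start * FS))
    n = int(round(duration * FS))
    tau = np.arange(n) / FS
    profile = np.minimum(1.0, np.minimum(tau / attack, (duration - tau) / release))
    profile = np.clip(profile, 0.0, 1.0)
    emg[i0:i0 + n] += gain * profile * rng.standard_normal(n)


def generate_recording(cfg: SyntheticConfig, subject: int) -> Recording:
    """One subject's recording; deterministic in (cfg.seed, subject)."""
    rng = np.random.default_rng([cfg.seed % (2**31), int(subject)])

    # per-subject physiology
    baseline = rng.uniform(*cfg.bi_baseline_ohm)
    burst_gain = rng.uniform(*cfg.emg_burst_gain) * cfg.rest_noise_sigma

    # event schedule: shuffled swallows + distractors, spacing >= 3 s
    kinds = (["swallow"] * cfg.n_swallows_per_subject
             + [cfg.distractor_types[k % len(cfg.distractor_types)]
                for k in range(cfg.n_distractors_per_subject)])
    rng.shuffle(kinds)
    spacings = rng.uniform(*cfg.event_spacing_s, size=len(kinds))
    event_times = cfg.warmup_s + np.cumsum(spacings)
    duration = (event_times[-1] if len(kinds) else cfg.warmup_s) + 3.0
    n = int(round(duration * FS))
    if len(kinds) and np.any(np.diff(event_times) < 3.0):
        raise ValueError("events would overlap: reduce event count or raise duration")

    t_axis = np.arange(n) / FS
    bi = np.full(n, baseline)
    bi += cfg.bi_drift_ohm * np.sin(2 * np.pi * t_axis / 47.0 + rng.uniform(0, 2 * np.pi))
    bi += cfg.bi_noise_sigma * rng.standard_normal(n)

    emg = cfg.rest_noise_sigma * rng.standard_normal(n)
    for amp, f0 in zip(cfg.mains_amplitudes, (50.0, 150.0, 250.0)):
        emg += amp * np.sin(2 * np.pi * f0 * t_axis + rng.uniform(0, 2 * np.pi))
    n_spikes = rng.poisson(cfg.spike_rate_hz * duration)
    spike_idx = rng.integers(0, n, size=n_spikes)
    emg[spike_idx] += rng.choice([-1, 1], n_spikes) * rng.uniform(10, 30, n_spikes) \
        * cfg.rest_noise_sigma

    ref_times = []
    for t0, kind in zip(event_times, kinds):
        if kind == "swallow":
            depth = rng.uniform(*cfg.valley_depth_ohm)
            t_drop = _truncated_normal(rng, *cfg.drop_duration_s, *cfg.drop_duration_bounds)
            t_total = _truncated_normal(rng, *cfg.valley_duration_s,
                                        *cfg.valley_duration_bounds)
            pre_peak = rng.uniform(*cfg.pre_peak_ohm)
            _add_valley(bi, t0, depth, t_drop, t_total, pre_peak)
            lead = _truncated_normal(rng, *cfg.emg_lead_s, *cfg.emg_lead_bounds)
            _add_burst(emg, rng, t0 - lead, rng.uniform(0.8, 1.3), burst_gain)
            ref_times.append(t0)
        elif kind == "head_move":
            _add_head_move(bi, t0, rng.uniform(0.25, 0.8), rng.uniform(1.5, 2.5))
        else:  # speech / chew: EMG activity without a BI valley
            _add_burst(emg, rng, t0, rng.uniform(0.6, 1.2),
                       rng.uniform(2.5, 5.0) * cfg.rest_noise_sigma)

    ann = AnnotationSet(np.asarray(ref_times), ["swallow_onset"] * len(ref_times))
    return Recording(subject_id=subject, series_id="synthetic", fs_raw=FS,
                     bi_raw=bi, emg_raw=emg, annotations=ann)


def generate_dataset(cfg: SyntheticConfig) -> list[Recording]:
    """One recording per subject (subject ids 1..n_subjects)."""
    return [generate_recording(cfg, subject) for subject in range(1, cfg.n_subjects + 1)]
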