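"""Synthetic binocular fixational gaze with ground-truth microsaccades.

The generator emulates a pre/post repeated-measures fixation study: each
participant has a stable base microsaccade rate drawn once (between-
participant spread), the post session's expected rate is the pre rate times
a configurable multiplier, and every trial is a 5.5 s binocular recording at
500 Hz composed of

* slow fixational drift — a mean-reverting (discretised Ornstein-Uhlenbeck)
  process shared by the two eyes, so long trials do not wander off target,
* injected microsaccades — raised-cosine velocity pulses whose peak velocity
  follows a linear main sequence, identical displacement in both eyes,
* independent per-eye Gaussian sensor noise, and
* optional blinks, inserted as runs of invalid samples in both eyes.

Microsaccade onsets follow a homogeneous Poisson process with a hard
refractory interval; the candidate intensity is dead-time compensated so the
realised event rate matches the configured rate.

Randomness policy: one root seed; the stream for participant ``p`` uses
``SeedSequence(seed, spawn_key=(p,))`` and the stream for trial ``t`` of
session ``s`` (0=pre, 1=post) of participant ``p`` uses
``SeedSequence(seed, spawn_key=(p, s, t))``, so any subset of the study is
reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.signal import lfilter

from .io import SESSIONS, GazeTrial

DEFAULT_MAIN_SEQUENCE_SLOPE = 120.0  # (deg/s) per degree of amplitude


class ConfigError(ValueError):
    """A SimulationConfig field is invalid; the message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation settings.

    Defaults reproduce the regime of a 22-participant pre/post caffeine
    fixation study: 2 sessions x 60 trials of 5.5 s sampled binocularly at
    500 Hz, base rates centred on 1.4 events/s (between-participant sd
    0.45), and a post-session rate multiplier of 0.85 (~1.18/1.40).
    """

    n_participants: int = 22
    n_trials_per_session: int = 60
    trial_duration: float = 5.5          # s
    sampling_rate: float = 500.0         # Hz
    base_rate_mean: float = 1.4          # events/s
    base_rate_sd: float = 0.45           # events/s, between participants
    post_rate_multiplier: float = 0.85   # in (0, 1]
    within_trial_rate_jitter_sd: float = 0.3   # events/s, per trial
    refractory_interval: float = 0.15    # s, hard dead time between onsets
    amplitude_log_mean: float = math.log(0.5)  # log-degrees (median 0.5 deg)
    amplitude_log_sd: float = 0.35       # log-degrees
    main_sequence_slope: float = DEFAULT_MAIN_SEQUENCE_SLOPE
    drift_sd: float = 0.05               # deg, stationary sd of drift
    drift_mean_reversion: float = 5.0    # 1/s
    noise_sd: float = 0.01               # deg, per-eye independent
    blink_probability_per_trial: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        def check(name, cond):
            if not cond:
                raise ConfigError(f"invalid SimulationConfig field: {name}")
        check("n_participants", int(self.n_participants) >= 1)
        check("n_trials_per_session", int(self.n_trials_per_session) >= 1)
        check("trial_duration", self.trial_duration > 0)
        check("sampling_rate", self.sampling_rate >= 2.0 / self.trial_duration)
        check("base_rate_mean", self.base_rate_mean >= 0)
        check("base_rate_sd", self.base_rate_sd >= 0)
        check("post_rate_multiplier", 0 < self.post_rate_multiplier <= 1)
        check("within_trial_rate_jitter_sd", self.within_trial_rate_jitter_sd >= 0)
        check("refractory_interval", self.refractory_interval >= 0)
        check("amplitude_log_sd", self.amplitude_log_sd >= 0)
        check("main_sequence_slope", self.main_sequence_slope > 0)
        check("drift_sd", self.drift_sd >= 0)
        check("drift_mean_reversion", self.drift_mean_reversion >= 0)
        check("noise_sd", self.noise_sd >= 0)
        check("blink_probability_per_trial",
              0 <= self.blink_probability_per_trial <= 1)

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimulationConfig field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load from a YAML config whose keys are the field names."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroundTruthEvent:
    onset_time: float    # s from trial start
    amplitude: float     # degrees
    direction: float     # radians, 0 = +x
    duration: float      # s


@dataclass
class GroundTruth:
    """Injected events per trial and expected rates per participant."""

    events: dict[tuple[str, str, int], list[GroundTruthEvent]]
    rates: dict[str, tuple[float, float]]   # participant -> (pre, post) events/s

    def count(self, key: tuple[str, str, int]) -> int:
        return len(self.events[key])


@dataclass
class StudyDataset:
    """All trials of a simulated (or loaded) study."""

    trials: list[GazeTrial]
    sampling_rate: float
    trial_duration: float

    def __iter__(self):
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for tr in self.trials:
            seen.setdefault(tr.participant_id, None)
        return list(seen)


def main_sequence_peak_velocity(
    amplitude: float | np.ndarray,
    slope: float = DEFAULT_MAIN_SEQUENCE_SLOPE,
) -> float | np.ndarray:
    """Peak velocity (deg/s) from the linear main sequence: slope * amplitude."""
    amp = np.asarray(amplitude, dtype=float)
    if np.any(amp < 0):
        raise ValueError("amplitude must be >= 0")
    out = slope * amp
    return float(out) if np.isscalar(amplitude) else out


def _pulse_displacement(duration_samples: int) -> np.ndarray:
    """Normalised displacement profile of a raised-cosine velocity pulse.

    Returns ``duration_samples + 1`` values rising smoothly from 0 to 1:
    the integral of ``v(t) ∝ 1 - cos(2 pi t / T)``.
    """
    t = np.linspace(0.0, 1.0, duration_samples + 1)
    return t - np.sin(2.0 * np.pi * t) / (2.0 * np.pi)


def inject_microsaccade(
    x: np.ndarray,
    y: np.ndarray,
    onset_index: int,
    amplitude: float,
    direction: float,
    duration_samples: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Add one microsaccade displacement to a position trace (in place).

    The velocity profile is a raised-cosine pulse over ``duration_samples``
    sample intervals; the total displacement equals ``amplitude`` along
    ``direction`` and every sample after the offset keeps the full
    displacement.
    """
    n = len(x)
    if onset_index < 0 or onset_index + duration_samples > n - 1:
        raise ValueError("event exceeds trial bounds")
    if amplitude == 0:
        return x, y
    profile = _pulse_displacement(duration_samples)
    dxp = amplitude * math.cos(direction)
    dyp = amplitude * math.sin(direction)
    sl = slice(onset_index, onset_index + duration_samples + 1)
    x[sl] += dxp * profile
    y[sl] += dyp * profile
    x[onset_index + duration_samples + 1:] += dxp
    y[onset_index + duration_samples + 1:] += dyp
    return x, y


def event_duration_samples(amplitude: float, config: SimulationConfig) -> int:
    """Pulse duration in samples from the main sequence.

    For a raised-cosine pulse the peak velocity is ``2 * amplitude / T``;
    setting it to ``slope * amplitude`` gives ``T = 2 / slope`` (rounded to
    samples, clamped to >= 3).
    """
    vp = main_sequence_peak_velocity(amplitude, config.main_sequence_slope)
    if vp <= 0:
        return 3
    t = 2.0 * amplitude / vp
    return max(3, int(round(t * config.sampling_rate)))


def _draw_onsets(rate: float, config: SimulationConfig, rng: np.random.Generator,
                 max_duration_s: float) -> list[float]:
    """Poisson onsets with a hard refractory dead time.

    Drawn as a renewal process with gaps ``refractory + Exp(lam)`` where the
    candidate intensity ``lam = r / (1 - r * refractory)`` compensates the
    dead time, so the realised rate matches ``r``.
    """
    if rate <= 0:
        return []
    tau = config.refractory_interval
    if rate * tau >= 1.0:
        raise ConfigError(
            "invalid SimulationConfig field: refractory_interval "
            f"(rate {rate:g}/s unattainable with dead time {tau:g}s)")
    lam = rate / (1.0 - rate * tau)
    onsets = []
    t = rng.exponential(1.0 / lam)
    limit = config.trial_duration - max_duration_s
    while t < limit:
        onsets.append(t)
        t += tau + rng.exponential(1.0 / lam)
    return onsets


def _ou_drift(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Stationary discretised Ornstein-Uhlenbeck drift, one axis."""
    sd = config.drift_sd
    if sd == 0:
        return np.zeros(n)
    a = math.exp(-config.drift_mean_reversion / config.sampling_rate)
    innov = np.empty(n)
    innov[0] = rng.normal(0.0, sd)   # stationary initial state
    innov[1:] = rng.normal(0.0, sd * math.sqrt(max(0.0, 1.0 - a * a)), size=n - 1)
    # AR(1) recursion x[i] = a x[i-1] + innov[i] as an IIR filter
    return lfilter([1.0], [1.0, -a], innov)


def simulate_trial(
    rate: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], list[GroundTruthEvent]]:
    """One binocular fixation trial.

    Returns the raw sample arrays (``time, xl, yl, xr, yr, valid_l,
    valid_r``) and the injected ground-truth events.  ``rate`` is the
    trial's expected microsaccade rate before the per-trial jitter.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    fs = config.sampling_rate
    n = config.n_samples
    time = np.arange(n) / fs

    # per-trial rate jitter, truncated at zero; a zero-rate process stays
    # silent (jitter modulates an existing rate, it does not create one)
    if rate == 0 or config.within_trial_rate_jitter_sd == 0:
        trial_rate = rate
    else:
        trial_rate = max(0.0, rng.normal(rate, config.within_trial_rate_jitter_sd))

    # conjugate signal: drift + events (identical in both eyes)
    conj_x = _ou_drift(n, config, rng)
    conj_y = _ou_drift(n, config, rng)

    max_dur_s = (event_duration_samples(1.0, config) + 1) / fs
    onsets = _draw_onsets(trial_rate, config, rng, max_dur_s)
    events: list[GroundTruthEvent] = []
    for onset in onsets:
        amp = float(rng.lognormal(config.amplitude_log_mean,
                                  config.amplitude_log_sd))
        direction = float(rng.uniform(0.0, 2.0 * np.pi))
        dur = event_duration_samples(amp, config)
        onset_idx = int(round(onset * fs))
        if onset_idx + dur > n - 1:
            continue
        inject_microsaccade(conj_x, conj_y, onset_idx, amp, direction, dur)
        events.append(GroundTruthEvent(onset_time=onset_idx / fs,
                                       amplitude=amp, direction=direction,
                                       duration=dur / fs))

    def eye_signal():
        if config.noise_sd > 0:
            return (conj_x + rng.normal(0, config.noise_sd, n),
                    conj_y + rng.normal(0, config.noise_sd, n))
        return conj_x.copy(), conj_y.copy()

    xl, yl = eye_signal()
    xr, yr = eye_signal()
    valid_l = np.ones(n, dtype=bool)
    valid_r = np.ones(n, dtype=bool)
    if rng.uniform() < config.blink_probability_per_trial:
        blink_len = int(rng.uniform(0.05, 0.15) * fs)   # 50-150 ms
        start = int(rng.integers(0, max(1, n - blink_len)))
        valid_l[start:start + blink_len] = False
        valid_r[start:start + blink_len] = False

    samples = {"time": time, "xl": xl, "yl": yl, "xr": xr, "yr": yr,
               "valid_l": valid_l, "valid_r": valid_r}
    return samples, events


def _participant_rng(config: SimulationConfig, p: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(p,)))


def _trial_rng(config: SimulationConfig, p: int, s: int, t: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(p, s, t)))


def simulate_study(config: SimulationConfig) -> tuple[StudyDataset, GroundTruth]:
    """Simulate the full pre/post study.

    Participant ``i``'s pre-session rate is drawn once from
    ``N(base_rate_mean, base_rate_sd)`` truncated at 0; the post-session
    expected rate is the pre rate times ``post_rate_multiplier``.  Identical
    config (including seed) yields a bit-identical dataset.
    """
    trials: list[GazeTrial] = []
    gt_events: dict[tuple[str, str, int], list[GroundTruthEvent]] = {}
    rates: dict[str, tuple[float, float]] = {}
    width = len(str(config.n_participants))
    for p in range(config.n_participants):
        pid = f"P{p + 1:0{width}d}"
        prng = _participant_rng(config, p)
        pre_rate = max(0.0, prng.normal(config.base_rate_mean, config.base_rate_sd)) \
            if config.base_rate_sd > 0 else config.base_rate_mean
        if config.base_rate_mean == 0:
            pre_rate = 0.0
        post_rate = pre_rate * config.post_rate_multiplier
        rates[pid] = (pre_rate, post_rate)
        for s, session in enumerate(SESSIONS):
            rate = pre_rate if session == "pre" else post_rate
            for t in range(config.n_trials_per_session):
                rng = _trial_rng(config, p, s, t)
                samples, events = simulate_trial(rate, config, rng)
                trial = GazeTrial(
                    participant_id=pid, session=session, trial_index=t + 1,
                    sampling_rate=config.sampling_rate,
                    time=samples["time"],
                    left_x=samples["xl"], left_y=samples["yl"],
                    right_x=samples["xr"], right_y=samples["yr"],
                    valid_left=samples["valid_l"], valid_right=samples["valid_r"],
                )
                trials.append(trial)
                gt_events[trial.key()] = events
    dataset = StudyDataset(trials=trials, sampling_rate=config.sampling_rate,
                           trial_duration=config.n_samples / config.sampling_rate)
    return dataset, GroundTruth(events=gt_events, rates=rates)


def ground_truth_to_records(gt: GroundTruth) -> list[dict]:
    """Flatten ground-truth events for a tab-separated table."""
    rows = []
    for (pid, session, idx), events in gt.events.items():
        for e in events:
            rows.append({
                "participant_id": pid, "session": session, "trial_index": idx,
                "onset_time_s": e.onset_time, "amplitude_deg": e.amplitude,
                "direction_rad": e.direction, "duration_s": e.duration,
            })
    return rows
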