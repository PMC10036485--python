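"""Protocol-faithful synthetic sEMG trial simulator.

Emulates a cued joystick push/pull task recorded from six upper-limb muscle
groups at 500 Hz.  Each trial consists of a randomized idle interval
(uniform 3-10 s) in one of two designated idle regimes -- *relaxed* (low
tonic muscle activity) or *prepared* (elevated isometric activity with slow
fluctuation) -- followed by a visual cue, a reaction-time latency, and a
class-specific multi-channel activation ramp that culminates in the motion
onset, marked by an abrupt joystick deflection.

The sEMG surrogate is band-limited zero-mean Gaussian noise (carrier,
20-240 Hz) amplitude-modulated by a per-channel envelope, the standard
statistical model for rectified surface EMG.  Ground-truth cue and onset
times are carried on every trial so that every downstream stage of the
pipeline can be validated without human data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

__all__ = ["SimConfig", "TrialRecording", "simulate_trial", "simulate_dataset"]

IDLE_CLASSES = ("relaxed", "prepared")
MOTION_CLASSES = ("push", "pull")

# Per-(idle, motion) envelope ramp amplitude reached at motion onset, one entry
# per channel (triceps, biceps, ant. deltoid, post. deltoid, flexor c.r.,
# extensor c.r.).  Push/pull are channel-mirrored within each idle state.  The
# prepared-state patterns emulate initiation out of a co-contracted hold: the
# agonist burst is preceded by antagonist release, so the channel emphasis
# crosses over relative to the relaxed-state patterns and pooling over idle
# states mixes dissimilar dynamics.
DEFAULT_RAMP_PROFILES: dict[tuple[str, str], tuple[float, ...]] = {
    ("relaxed", "push"): (3.0, 0.3, 2.2, 0.3, 0.4, 1.8),
    ("relaxed", "pull"): (0.3, 3.0, 0.3, 2.2, 1.8, 0.4),
    ("prepared", "push"): (0.6, 2.0, 0.8, 2.6, 2.4, 0.6),
    ("prepared", "pull"): (2.0, 0.6, 2.6, 0.8, 0.6, 2.4),
}


@dataclass
class SimConfig:
    """Study-protocol and signal-model parameters for the simulator.

    Amplitudes are in arbitrary units (the recording hardware's gain is not
    modelled); times in seconds; frequencies in Hz.
    """

    sampling_rate: float = 500.0
    n_channels: int = 6
    idle_duration_range: tuple[float, float] = (3.0, 10.0)
    trials_per_condition: int = 30
    idle_classes: tuple[str, ...] = IDLE_CLASSES
    motion_classes: tuple[str, ...] = MOTION_CLASSES
    # reaction time: truncated normal per idle class, seconds
    reaction_time_mean: Mapping[str, float] = field(
        default_factory=lambda: {"relaxed": 0.65, "prepared": 0.63}
    )
    reaction_time_sd: float = 0.10
    reaction_time_min: float = 0.15
    # idle-regime envelopes (amplitude units)
    relaxed_baseline_envelope: float = 0.35
    relaxed_fluctuation_sd: float = 0.12
    prepared_tonic_envelope: float = 0.75
    prepared_fluctuation_sd: float = 0.35
    fluctuation_bandwidth: float = 2.0  # slow isometric drift, < 2 Hz
    envelope_floor: float = 0.05
    # motion-initiation ramp
    initiation_ramp_profiles: Mapping[tuple[str, str], tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_RAMP_PROFILES)
    )
    ramp_duration_mean: float = 0.20
    ramp_duration_sd: float = 0.02
    ramp_duration_range: tuple[float, float] = (0.10, 0.30)
    # trial-to-trial variability of muscle activation (log-normal sd)
    trial_amplitude_jitter: float = 0.40
    trial_baseline_jitter: float = 0.15
    # carrier / noise
    carrier_band: tuple[float, float] = (20.0, 240.0)
    measurement_noise_sd: float = 0.05
    # joystick
    joystick_noise_sd: float = 0.01
    joystick_deflection: float = 0.8
    joystick_rise_tau: float = 0.02
    post_onset_duration: float = 0.5
    # subject heterogeneity (log-normal sd on amplitudes, absolute on RT mean)
    subject_amplitude_jitter: float = 0.12
    subject_reaction_jitter: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.idle_duration_range
        if not (lo >= 0 and lo < hi):
            raise ValueError("idle_duration_range must satisfy 0 <= low < high")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if any(m <= 0 for m in self.reaction_time_mean.values()):
            raise ValueError("reaction_time_mean entries must be > 0")
        for name in ("relaxed_baseline_envelope", "prepared_tonic_envelope",
                     "joystick_deflection"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for key, prof in self.initiation_ramp_profiles.items():
            if len(prof) != self.n_channels:
                raise ValueError(
                    f"ramp profile {key} has {len(prof)} entries, "
                    f"expected n_channels={self.n_channels}"
                )
        f_lo, f_hi = self.carrier_band
        if not (0 < f_lo < f_hi < self.sampling_rate / 2):
            raise ValueError("carrier_band must lie within (0, fs/2)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["initiation_ramp_profiles"] = {
            f"{idle}:{motion}": list(prof)
            for (idle, motion), prof in self.initiation_ramp_profiles.items()
        }
        d["reaction_time_mean"] = dict(self.reaction_time_mean)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "initiation_ramp_profiles" in d:
            profs = {}
            for key, prof in d["initiation_ramp_profiles"].items():
                idle, motion = key.split(":") if isinstance(key, str) else key
                profs[(idle, motion)] = tuple(float(v) for v in prof)
            d["initiation_ramp_profiles"] = profs
        for name in ("idle_duration_range", "ramp_duration_range",
                     "carrier_band"):
            if name in d:
                d[name] = tuple(d[name])
        for name in ("idle_classes", "motion_classes"):
            if name in d:
                d[name] = tuple(d[name])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class TrialRecording:
    """One trial: multichannel sEMG, joystick trace, labels and event times."""

    subject_id: str
    idle_label: str
    motion_label: str
    emg: np.ndarray              # (samples, channels)
    joystick_x: np.ndarray       # (samples,)
    cue_time: float              # s from recording start
    onset_time: float | None     # s; ground truth when synthetic
    sampling_rate: float
    trial_id: str = ""
    valid: bool = True

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.joystick_x = np.asarray(self.joystick_x, dtype=float)
        if self.emg.shape[0] != self.joystick_x.shape[0]:
            raise ValueError("emg and joystick_x must have equal sample counts")
        if self.onset_time is not None and self.onset_time <= self.cue_time:
            raise ValueError("onset_time must follow cue_time")

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def reaction_time(self) -> float | None:
        if self.onset_time is None:
            return None
        return self.onset_time - self.cue_time


def _check_labels(config: SimConfig, idle_label: str, motion_label: str) -> None:
    if idle_label not in config.idle_classes:
        raise ValueError(
            f"unknown idle label {idle_label!r}; valid: {list(config.idle_classes)}"
        )
    if motion_label not in config.motion_classes:
        raise ValueError(
            f"unknown motion label {motion_label!r}; valid: {list(config.motion_classes)}"
        )


def _slow_fluctuation(n: int, fs: float, bandwidth: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-sd low-pass noise emulating slow isometric contraction drift."""
    white = rng.standard_normal(n)
    sos = signal.butter(2, bandwidth, btype="lowpass", fs=fs, output="sos")
    slow = signal.sosfiltfilt(sos, white)
    sd = slow.std()
    if sd < 1e-12:  # pragma: no cover - degenerate n
        return np.zeros(n)
    return slow / sd


def _draw_cue_time(config: SimConfig, rng: np.random.Generator) -> float:
    lo, hi = config.idle_duration_range
    return float(rng.uniform(lo, hi))


def _draw_reaction_time(config: SimConfig, idle_label: str,
                        rng: np.random.Generator,
                        mean_override: float | None = None) -> float:
    mean = mean_override if mean_override is not None \
        else config.reaction_time_mean[idle_label]
    while True:  # truncated normal, lower bound only
        rt = rng.normal(mean, config.reaction_time_sd)
        if rt > config.reaction_time_min:
            return float(rt)


def _carrier(n: int, n_channels: int, band: tuple[float, float], fs: float,
             rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise, independent per channel."""
    white = rng.standard_normal((n, n_channels))
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    car = signal.sosfiltfilt(sos, white, axis=0)
    return car / car.std(axis=0, keepdims=True)


def simulate_trial(
    config: SimConfig,
    idle_label: str,
    motion_label: str,
    seed: int | np.random.Generator = 0,
    *,
    subject_id: str = "sim",
    _ramp_profiles: Mapping[tuple[str, str], np.ndarray] | None = None,
    _baseline_scale: float = 1.0,
    _reaction_mean: float | None = None,
) -> TrialRecording:
    """Simulate one trial with known ground-truth cue and onset times.

    Pre-cue envelope statistics depend only on ``idle_label``; post-cue,
    pre-onset envelopes follow the configured (idle, motion) ramp, which by
    construction starts no earlier than 300 ms before onset.  The joystick
    trace is flat (noise only) before ``onset_time`` and deflects abruptly
    from the onset sample.  Fully reproducible for a given integer seed.
    """
    config.validate()
    _check_labels(config, idle_label, motion_label)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    fs = config.sampling_rate

    cue = _draw_cue_time(config, rng)
    rt = _draw_reaction_time(config, idle_label, rng, _reaction_mean)
    # snap events to the sample grid so ground truth is exactly representable
    cue_idx = int(round(cue * fs))
    onset_idx = int(round((cue + rt) * fs))
    cue_time = cue_idx / fs
    onset_time = onset_idx / fs
    n = onset_idx + int(round(config.post_onset_duration * fs))
    t = np.arange(n) / fs

    # ---- idle-regime baseline envelope, per channel ----
    env = np.empty((n, config.n_channels))
    if idle_label == "relaxed":
        base, fluct_sd = (config.relaxed_baseline_envelope,
                          config.relaxed_fluctuation_sd)
    else:
        base, fluct_sd = (config.prepared_tonic_envelope,
                          config.prepared_fluctuation_sd)
    base = base * _baseline_scale \
        * float(np.exp(rng.normal(0.0, config.trial_baseline_jitter)))
    for ch in range(config.n_channels):
        env[:, ch] = base + fluct_sd * _slow_fluctuation(
            n, fs, config.fluctuation_bandwidth, rng)

    # ---- class-specific initiation ramp ----
    profiles = _ramp_profiles if _ramp_profiles is not None \
        else {k: np.asarray(v, float) for k, v in
              config.initiation_ramp_profiles.items()}
    amp = np.asarray(profiles[(idle_label, motion_label)], dtype=float) \
        * np.exp(rng.normal(0.0, config.trial_amplitude_jitter,
                            size=config.n_channels))
    ramp_dur = float(np.clip(
        rng.normal(config.ramp_duration_mean, config.ramp_duration_sd),
        *config.ramp_duration_range))
    ramp_start = max(onset_time - ramp_dur, cue_time)
    frac = np.clip((t - ramp_start) / (onset_time - ramp_start), 0.0, 1.0)
    env += frac[:, None] * amp[None, :]
    np.maximum(env, config.envelope_floor, out=env)

    # ---- amplitude-modulated carrier + sensor noise ----
    emg = _carrier(n, config.n_channels, config.carrier_band, fs, rng) * env
    emg += config.measurement_noise_sd * rng.standard_normal(emg.shape)

    # ---- joystick: flat noise, abrupt deflection from the onset sample ----
    joy = config.joystick_noise_sd * rng.standard_normal(n)
    sign = 1.0 if motion_label == "push" else -1.0
    tt = (np.arange(n - onset_idx) + 1) / fs
    joy[onset_idx:] += sign * config.joystick_deflection * (
        1.0 - np.exp(-tt / config.joystick_rise_tau))

    return TrialRecording(
        subject_id=subject_id, idle_label=idle_label,
        motion_label=motion_label, emg=emg, joystick_x=joy,
        cue_time=cue_time, onset_time=onset_time, sampling_rate=fs,
    )


def simulate_dataset(
    config: SimConfig,
    n_subjects: int = 1,
    seed: int | None = None,
) -> list[TrialRecording]:
    """Simulate a balanced multi-subject dataset.

    Per subject: exactly ``trials_per_condition`` trials of each of the four
    (idle x motion) conditions, in randomized order, with per-subject jitter
    of envelope/ramp amplitudes and reaction-time means (subject
    heterogeneity).  Deterministic for a given seed.
    """
    config.validate()
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    trials: list[TrialRecording] = []
    for s, subj_ss in enumerate(root.spawn(n_subjects)):
        subj_rng = np.random.default_rng(subj_ss)
        subject_id = f"s{s + 1:02d}"
        jit = config.subject_amplitude_jitter
        profiles = {
            k: np.asarray(v, float)
            * np.exp(subj_rng.normal(0.0, jit, size=config.n_channels))
            for k, v in config.initiation_ramp_profiles.items()
        }
        baseline_scale = float(np.exp(subj_rng.normal(0.0, jit)))
        rt_shift = float(subj_rng.normal(0.0, config.subject_reaction_jitter))
        conditions = [
            (idle, motion)
            for idle in config.idle_classes
            for motion in config.motion_classes
            for _ in range(config.trials_per_condition)
        ]
        order = subj_rng.permutation(len(conditions))
        for k, idx in enumerate(order):
            idle, motion = conditions[idx]
            rt_mean = max(config.reaction_time_mean[idle] + rt_shift,
                          config.reaction_time_min + 0.1)
            trial = simulate_trial(
                config, idle, motion, subj_rng, subject_id=subject_id,
                _ramp_profiles=profiles, _baseline_scale=baseline_scale,
                _reaction_mean=rt_mean,
            )
            trial.trial_id = f"{subject_id}_t{k + 1:03d}"
            trials.append(trial)
    return trials
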