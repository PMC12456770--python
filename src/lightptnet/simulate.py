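"""Synthetic multichannel inertial-signal generator.

The generator emulates the statistical structure a smartphone-HAR
classifier relies on, without any biomechanical realism:

* **periodic** activities (walking, running, stair climbing, ...) are sums
  of a few harmonics of a class-specific fundamental frequency — dynamic
  human movement is quasiperiodic, and distinct gait frequencies are what
  separates these classes spectrally;
* **static** activities (sitting, standing, lying) are near-constant
  channels whose levels encode a class-specific gravity orientation;
* **transient** activities (falls, posture transitions) are a noise floor
  with a single short high-amplitude burst per window.

Each subject carries a multiplicative amplitude scale, a fractional
frequency perturbation and a phase offset, so models that memorise
subject idiosyncrasies do not transfer across a subject-independent
split — which is precisely what makes such splits meaningful to test.
All randomness flows from one seed; identical seeds give bit-identical
arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import RawStream, WindowedDataset
from .preprocess import windows_from_streams
from .readers import UNIMIB_AF17_CLASSES, WISDM_CLASSES

__all__ = [
    "ActivityModel",
    "SubjectModel",
    "default_activity_models",
    "simulate_dataset",
    "simulate_streams",
    "make_benchmark_lookalike",
]


@dataclass
class ActivityModel:
    """Generative description of one activity class."""

    name: str
    kind: str                                   # "periodic" | "static" | "transient"
    fundamental_freq: float = 0.0               # Hz, periodic classes
    harmonic_amps: tuple = (1.0, 0.4, 0.2)
    gravity_vector: tuple = (0.0, 0.0, 1.0)     # static classes, in g
    burst_amplitude: float = 3.0                # transient classes
    burst_width: float = 0.15                   # s, std of the burst envelope
    amplitude: float = 0.5                      # overall dynamic amplitude
    noise_sd: float = 0.1

    def __post_init__(self):
        if self.kind not in ("periodic", "static", "transient"):
            raise ValueError(f"unknown activity kind {self.kind!r}")
        if self.kind == "periodic" and self.fundamental_freq <= 0:
            raise ValueError("periodic activities need fundamental_freq > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not np.all(np.isfinite(self.harmonic_amps)):
            raise ValueError("harmonic amplitudes must be finite")


@dataclass
class SubjectModel:
    """Per-subject perturbations that break cross-subject transfer."""

    subject_id: str
    amp_scale: float = 1.0
    freq_scale: float = 1.0      # multiplicative fundamental perturbation
    phase_offset: float = 0.0    # radians

    def __post_init__(self):
        if self.amp_scale <= 0:
            raise ValueError("amp_scale must be > 0")


# channel geometry: channel c gets a fixed gain and phase lag so the C
# channels are distinct but deterministic functions of the class signal
def _channel_gains(C: int) -> np.ndarray:
    return 1.0 - 0.08 * (np.arange(C) % 3) - 0.15 * (np.arange(C) // 3)


def _channel_phases(C: int) -> np.ndarray:
    return 0.7 * np.arange(C)


def default_activity_models(noise_sd: float = 0.1) -> list[ActivityModel]:
    """Six classes mirroring the common smartphone set: three quasiperiodic
    gaits with distinct fundamentals, three static postures with distinct
    gravity orientations."""
    return [
        ActivityModel("Walking", "periodic", fundamental_freq=1.8,
                      amplitude=0.5, noise_sd=noise_sd),
        ActivityModel("Upstairs", "periodic", fundamental_freq=1.3,
                      amplitude=0.45, noise_sd=noise_sd),
        ActivityModel("Downstairs", "periodic", fundamental_freq=2.4,
                      amplitude=0.55, noise_sd=noise_sd),
        ActivityModel("Sitting", "static", gravity_vector=(0.45, 0.30, 0.84),
                      noise_sd=noise_sd),
        ActivityModel("Standing", "static", gravity_vector=(0.05, 0.10, 0.99),
                      noise_sd=noise_sd),
        ActivityModel("Laying", "static", gravity_vector=(0.90, 0.30, 0.10),
                      noise_sd=noise_sd),
    ]


def _draw_subjects(n_subjects: int, rng: np.random.Generator,
                   freq_jitter: float = 0.10) -> list[SubjectModel]:
    return [
        SubjectModel(subject_id=f"s{i + 1:02d}",
                     amp_scale=float(rng.uniform(0.7, 1.3)),
                     freq_scale=float(rng.uniform(1 - freq_jitter,
                                                  1 + freq_jitter)),
                     phase_offset=float(rng.uniform(0, 2 * np.pi)))
        for i in range(n_subjects)
    ]


def _window(model: ActivityModel, subject: SubjectModel, T: int, C: int,
            sampling_rate: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(T) / sampling_rate
    gains = _channel_gains(C)
    phases = _channel_phases(C)
    out = np.zeros((T, C))
    if model.kind == "periodic":
        f = model.fundamental_freq * subject.freq_scale
        phi = subject.phase_offset + rng.uniform(0, 2 * np.pi)
        for h, amp in enumerate(model.harmonic_amps, start=1):
            arg = 2 * np.pi * f * h * t[:, None] + phi + phases[None, :]
            out += model.amplitude * amp * np.sin(arg) * gains[None, :]
        out *= subject.amp_scale
    elif model.kind == "static":
        g = np.asarray(model.gravity_vector)
        levels = g[np.arange(C) % 3] * gains * subject.amp_scale
        out += levels[None, :]
    else:  # transient: noise floor + one seeded burst
        center = rng.uniform(0.25, 0.75) * T / sampling_rate
        env = np.exp(-0.5 * ((t - center) / model.burst_width) ** 2)
        carrier = np.sin(2 * np.pi * 6.0 * t)
        burst = model.burst_amplitude * subject.amp_scale * env * carrier
        out += burst[:, None] * gains[None, :]
        g = np.asarray(model.gravity_vector)
        out += (g[np.arange(C) % 3] * gains)[None, :] * 0.5
    if model.noise_sd > 0:
        out = out + rng.normal(0.0, model.noise_sd, size=(T, C))
    return out


def simulate_dataset(activity_models: list[ActivityModel], n_subjects: int,
                     windows_per_class_per_subject: int, T: int, C: int,
                     sampling_rate: float, seed: int = 0,
                     name: str = "synthetic") -> WindowedDataset:
    """Balanced labelled windows: every subject contributes
    ``windows_per_class_per_subject`` windows of every class."""
    if len(activity_models) < 2:
        raise ValueError("need at least 2 activity models")
    names = [m.name for m in activity_models]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate activity names in {names}")
    if min(n_subjects, T, C) < 1:
        raise ValueError("n_subjects, T and C must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = _draw_subjects(n_subjects, rng)
    windows, labels, subj_ids = [], [], []
    for subject in subjects:
        for k, model in enumerate(activity_models):
            for _ in range(windows_per_class_per_subject):
                windows.append(_window(model, subject, T, C,
                                       sampling_rate, rng))
                labels.append(k)
                subj_ids.append(subject.subject_id)
    return WindowedDataset(
        np.stack(windows), np.array(labels), np.array(subj_ids), names,
        provenance={"source": name, "seed": seed,
                    "sampling_rate": sampling_rate})


def simulate_streams(activity_models: list[ActivityModel], n_subjects: int,
                     samples_per_class_per_subject: int, C: int,
                     sampling_rate: float, seed: int = 0) -> list[RawStream]:
    """Continuous per-(subject, activity) streams, e.g. to exercise the raw
    WISDM text dialect and sliding-window segmentation end-to-end."""
    rng = np.random.default_rng(seed)
    subjects = _draw_subjects(n_subjects, rng)
    streams = []
    for subject in subjects:
        for model in activity_models:
            sig = _window(model, subject, samples_per_class_per_subject, C,
                          sampling_rate, rng)
            streams.append(RawStream(
                subject_id=subject.subject_id, channels=sig,
                labels=np.full(samples_per_class_per_subject, model.name),
                sampling_rate=sampling_rate))
    return streams


def _wisdm_models(noise_sd: float = 0.1) -> list[ActivityModel]:
    return [
        ActivityModel("Jogging", "periodic", fundamental_freq=2.8,
                      amplitude=0.9, noise_sd=noise_sd),
        ActivityModel("Walking", "periodic", fundamental_freq=1.8,
                      amplitude=0.5, noise_sd=noise_sd),
        ActivityModel("Upstairs", "periodic", fundamental_freq=1.3,
                      amplitude=0.45, noise_sd=noise_sd),
        ActivityModel("Downstairs", "periodic", fundamental_freq=2.3,
                      amplitude=0.55, noise_sd=noise_sd),
        ActivityModel("Sitting", "static", gravity_vector=(0.45, 0.30, 0.84),
                      noise_sd=noise_sd),
        ActivityModel("Standing", "static", gravity_vector=(0.05, 0.10, 0.99),
                      noise_sd=noise_sd),
    ]


def _unimib_models(noise_sd: float = 0.12) -> list[ActivityModel]:
    models = []
    periodic = {"Walking": (1.8, 0.5), "Running": (3.0, 0.9),
                "GoingUpS": (1.3, 0.45), "Jumping": (2.4, 1.0),
                "GoingDownS": (2.0, 0.55)}
    static_like = {"StandingUpFS": 1.2, "StandingUpFL": 1.6,
                   "LyingDownFS": 2.0, "SittingDown": 2.4}
    falls = ["FallingForw", "FallingRight", "FallingBack", "HittingObstacle",
             "FallingwithPS", "FallingBackSC", "Syncope", "FallingLeft"]
    for name in UNIMIB_AF17_CLASSES:
        if name in periodic:
            f, a = periodic[name]
            models.append(ActivityModel(name, "periodic", fundamental_freq=f,
                                        amplitude=a, noise_sd=noise_sd))
        elif name in static_like:
            # posture transitions: soft, slow bursts of distinct amplitude
            models.append(ActivityModel(
                name, "transient", burst_amplitude=static_like[name],
                burst_width=0.45,
                gravity_vector=(0.3, 0.4, 0.85), noise_sd=noise_sd))
        else:
            i = falls.index(name)
            angle = 2 * np.pi * i / len(falls)
            models.append(ActivityModel(
                name, "transient", burst_amplitude=3.0 + 0.5 * i,
                burst_width=0.10 + 0.03 * i,
                gravity_vector=(float(np.cos(angle)), float(np.sin(angle)),
                                0.4),
                noise_sd=noise_sd))
    return models


def make_benchmark_lookalike(name: str, seed: int = 0,
                             windows_per_class_per_subject: int = 8
                             ) -> WindowedDataset:
    """Synthetic dataset with the exact window length, channel count, class
    count and subject count of one of the three benchmark datasets."""
    if name == "ucihar":
        return simulate_dataset(default_activity_models(), n_subjects=30,
                                windows_per_class_per_subject=
                                windows_per_class_per_subject,
                                T=128, C=9, sampling_rate=50.0, seed=seed,
                                name="ucihar-lookalike")
    if name == "wisdm":
        streams = simulate_streams(
            _wisdm_models(), n_subjects=36,
            samples_per_class_per_subject=windows_per_class_per_subject * 200,
            C=3, sampling_rate=20.0, seed=seed)
        ds = windows_from_streams(streams, size=200, step=200,
                                  class_names=WISDM_CLASSES)
        ds.provenance.update({"source": "wisdm-lookalike", "seed": seed})
        return ds
    if name == "unimib":
        return simulate_dataset(_unimib_models(), n_subjects=30,
                                windows_per_class_per_subject=
                                windows_per_class_per_subject,
                                T=151, C=3, sampling_rate=50.0, seed=seed,
                                name="unimib-lookalike")
    raise ValueError(
        f"unknown benchmark name {name!r}; options: ucihar, wisdm, unimib")
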