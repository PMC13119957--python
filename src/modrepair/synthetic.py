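"""Synthetic multimodal recordings driven by a shared latent state.

The generator emulates the one property the detect-and-repair method
actually relies on: *cross-modal redundancy*.  A hidden first-order Markov
state sequence (K discrete states, e.g. rest / stress / activity) drives
every modality through a linear readout, optionally modulated by a
modality-typical carrier:

* ``none``      - direct linear readout (EDA / TEMP-like slow signals),
* ``sinusoid``  - amplitude-modulated oscillation (IMU / RESP-like),
* ``spike-train`` - periodic unit pulses whose inter-pulse interval is
  modulated by the drive (ECG-like rate modulation, no waveform morphology).

Because all modalities observe the same latent drive, a model can in
principle reconstruct a dropped modality from the remaining ones and a
linear probe on good embeddings can decode the state - which is exactly
what the package's training and evaluation code is tested against.

Everything is a pure function of the config: per-subject RNG substreams
are derived from ``(seed, subject_index)`` so any subject can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import ModalityStream, Recording

__all__ = ["ModalitySpec", "SyntheticConfig", "LatentTrajectory",
           "generate_latent", "render_modalities", "generate_dataset",
           "default_config"]

_AR_COEF = 0.9
_AR_SD = 0.05
_SMOOTH_S = 0.5
_SPIKE_BASE_INTERVAL_S = 1.0
_SPIKE_MODULATION = 0.3


@dataclass
class ModalitySpec:
    name: str
    channels: int
    loading: np.ndarray                     # (K, C) state-to-channel readout
    carrier: str = "none"                   # none | sinusoid | spike-train
    carrier_freq_range: tuple[float, float] = (1.0, 3.0)
    noise_sd: float = 0.1

    def __post_init__(self):
        self.loading = np.asarray(self.loading, dtype=np.float64)
        if self.carrier not in ("none", "sinusoid", "spike-train"):
            raise ValueError(f"unknown carrier: {self.carrier!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticConfig:
    n_subjects: int = 5
    n_states: int = 3
    duration_s: float = 600.0
    rate: float = 64.0
    stay_prob: float = 0.9995     # per-step; mean dwell ~31 s at 64 Hz
    modality_specs: list[ModalitySpec] = field(default_factory=list)
    seed: int = 42

    def __post_init__(self):
        if self.n_states < 2:
            raise ValueError("need K >= 2 latent states")
        if not (0 < self.stay_prob <= 1):
            raise ValueError("stay_prob must be in (0, 1]")
        for spec in self.modality_specs:
            if spec.loading.shape != (self.n_states, spec.channels):
                raise ValueError(
                    f"modality '{spec.name}': loading shape "
                    f"{spec.loading.shape} != (K={self.n_states}, "
                    f"C={spec.channels})")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_s * self.rate))


@dataclass
class LatentTrajectory:
    """Markov state sequence plus the smooth real-valued drive it induces."""

    states: np.ndarray   # (T,) ints in [0, K)
    drive: np.ndarray    # (T, K) smoothed one-hot + AR(1) fluctuation


def default_config(n_subjects: int = 5, n_states: int = 3,
                   duration_s: float = 600.0, rate: float = 64.0,
                   stay_prob: float | None = None, noise_sd: float = 0.1,
                   seed: int = 42) -> SyntheticConfig:
    """A five-modality wearable-like setup: IMU, ECG, EDA, RESP, TEMP.

    ``stay_prob`` defaults to a mean state dwell time of ~30 s at the
    requested rate so that 10 s windows are mostly label-pure.
    """
    if stay_prob is None:
        stay_prob = 1.0 - 1.0 / (30.0 * rate)
    rng = np.random.default_rng(seed)

    def loading(c):
        # distinct state levels along a random channel direction, so every
        # modality carries state contrast (a purely random matrix can come
        # out state-degenerate for C=1), plus a small random perturbation
        direction = rng.normal(0.0, 1.0, size=c)
        direction /= max(np.linalg.norm(direction), 1e-9)
        levels = np.linspace(-1.0, 1.0, n_states)
        return np.outer(levels, direction) + 0.15 * rng.normal(
            0.0, 1.0, size=(n_states, c))

    specs = [
        ModalitySpec("imu", 3, loading(3), carrier="sinusoid",
                     carrier_freq_range=(1.0, 3.0), noise_sd=noise_sd),
        ModalitySpec("ecg", 1, loading(1), carrier="spike-train",
                     noise_sd=noise_sd),
        ModalitySpec("eda", 1, loading(1), carrier="none", noise_sd=noise_sd),
        ModalitySpec("resp", 1, loading(1), carrier="sinusoid",
                     carrier_freq_range=(0.2, 0.4), noise_sd=noise_sd),
        ModalitySpec("temp", 1, loading(1), carrier="none",
                     noise_sd=noise_sd / 2),
    ]
    return SyntheticConfig(n_subjects=n_subjects, n_states=n_states,
                           duration_s=duration_s, rate=rate,
                           stay_prob=stay_prob, modality_specs=specs,
                           seed=seed)


def _subject_rng(config: SyntheticConfig, subject_index: int,
                 stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, subject_index, stream])


def generate_latent(config: SyntheticConfig,
                    subject_index: int) -> LatentTrajectory:
    """First-order Markov chain with P(stay) = stay_prob and uniform
    switching, plus a smooth drive: one-hot(state) filtered by a 0.5 s
    moving average, with AR(1) fluctuation (coef 0.9, innovation sd 0.05).
    """
    rng = _subject_rng(config, subject_index, 0)
    t_steps = config.n_steps
    k = config.n_states
    states = np.empty(t_steps, dtype=np.int64)
    states[0] = rng.integers(k)
    u = rng.random(t_steps - 1)
    jumps = rng.integers(1, k, size=t_steps - 1)  # offset among other states
    for t in range(1, t_steps):
        if u[t - 1] < config.stay_prob:
            states[t] = states[t - 1]
        else:
            states[t] = (states[t - 1] + jumps[t - 1]) % k

    onehot = np.zeros((t_steps, k))
    onehot[np.arange(t_steps), states] = 1.0
    width = max(int(round(_SMOOTH_S * config.rate)), 1)
    kernel = np.ones(width) / width
    smooth = np.empty_like(onehot)
    for j in range(k):
        smooth[:, j] = np.convolve(onehot[:, j], kernel, mode="same")

    ar = np.empty((t_steps, k))
    innov = rng.normal(0.0, _AR_SD, size=(t_steps, k))
    ar[0] = innov[0]
    for t in range(1, t_steps):
        ar[t] = _AR_COEF * ar[t - 1] + innov[t]
    return LatentTrajectory(states=states, drive=smooth + ar)


def _spike_train(drive1: np.ndarray, rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Unit pulses; inter-pulse interval = 1 s * (1 + 0.3 * drive[0])."""
    t_steps = len(drive1)
    out = np.zeros(t_steps)
    t = float(rng.random())  # random phase within the first second
    while True:
        idx = int(round(t * rate))
        if idx >= t_steps:
            break
        out[idx] = 1.0
        interval = _SPIKE_BASE_INTERVAL_S * (1.0 + _SPIKE_MODULATION * drive1[idx])
        t += max(interval, 0.1)
    return out


def render_modalities(latent: LatentTrajectory, config: SyntheticConfig,
                      subject_index: int = 0,
                      subject_id: str | None = None) -> Recording:
    """Render every modality from the latent drive and package a Recording."""
    rng = _subject_rng(config, subject_index, 1)
    t_steps = len(latent.states)
    t_axis = np.arange(t_steps) / config.rate
    streams: dict[str, ModalityStream] = {}
    for spec in config.modality_specs:
        if spec.loading.shape != (config.n_states, spec.channels):
            raise ValueError(
                f"modality '{spec.name}': loading shape mismatch")
        base = latent.drive @ spec.loading                    # (T, C)
        if spec.carrier == "sinusoid":
            f = rng.uniform(*spec.carrier_freq_range)
            base = base * np.sin(2 * np.pi * f * t_axis)[:, None]
        elif spec.carrier == "spike-train":
            pulses = _spike_train(latent.drive[:, 0], config.rate, rng)
            base = np.repeat(pulses[:, None], spec.channels, axis=1)
        if spec.noise_sd > 0:
            base = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
        streams[spec.name] = ModalityStream(
            name=spec.name, rate=config.rate, samples=base)
    return Recording(
        subject_id=subject_id or f"S{subject_index:02d}",
        streams=streams, labels=latent.states, label_rate=config.rate)


def generate_dataset(config: SyntheticConfig) -> list[Recording]:
    """n_subjects recordings with distinct ids; pure function of config."""
    if config.n_subjects < 1:
        raise ValueError("need at least one subject")
    out = []
    for i in range(config.n_subjects):
        latent = generate_latent(config, i)
        out.append(render_modalities(latent, config, subject_index=i))
    return out
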