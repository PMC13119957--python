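"""Reading, writing, resampling, normalizing and windowing multimodal recordings.

A :class:`Recording` is one subject's set of uniformly sampled sensor
streams (IMU, ECG, EDA, ...) plus a per-time-step integer label timeline.
Recordings are described on disk by a JSON manifest pointing at one CSV or
HDF5 file per modality::

    {"subject_id": "S1",
     "modalities": [{"name": "imu", "path": "imu.csv", "rate_hz": 64.0,
                     "channels": ["ax", "ay", "az"]}, ...],
     "labels": {"path": "labels.csv", "rate_hz": 64.0},
     "label_set": [0, 1, 2]}

CSV files hold one row per time step and one column per channel (header =
channel names); HDF5 files hold one dataset per modality plus a ``labels``
dataset.  Timestamps are implicit: uniform sampling from t=0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ModalityStream", "Recording", "WindowBatch",
    "read_recording", "write_recording", "resample", "zscore",
    "channel_stats", "make_windows", "concat_batches",
]

_EPS_STD = 1e-8


class ManifestError(ValueError):
    """Malformed dataset manifest."""


class AlignmentError(ValueError):
    """Streams of one recording disagree in duration beyond one sample."""


@dataclass
class ModalityStream:
    """One uniformly sampled sensor stream: a T x C matrix at ``rate`` Hz."""

    name: str
    rate: float
    samples: np.ndarray  # (T, C)
    units: list[str] | None = None

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 2:
            raise ValueError(f"{self.name}: samples must be a T x C matrix")
        if self.rate <= 0:
            raise ValueError(f"{self.name}: sampling rate must be > 0")
        if self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise ValueError(f"{self.name}: need T >= 1 and C >= 1")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"{self.name}: non-finite sample values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class Recording:
    """One subject's streams plus an integer label timeline."""

    subject_id: str
    streams: dict[str, ModalityStream]
    labels: np.ndarray  # (L,) integers at label_rate
    label_rate: float

    def __post_init__(self):
        if not self.streams:
            raise ValueError("recording needs at least one stream")
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if self.label_rate <= 0:
            raise ValueError("label rate must be > 0")
        dur = self.duration
        expected = dur * self.label_rate
        if abs(len(self.labels) - expected) > 1 + 1e-9:
            raise AlignmentError(
                f"subject {self.subject_id}: label timeline has "
                f"{len(self.labels)} steps, expected ~{expected:.1f} "
                f"at {self.label_rate} Hz for {dur:.2f} s")

    @property
    def duration(self) -> float:
        return next(iter(self.streams.values())).duration

    @property
    def modality_names(self) -> list[str]:
        return list(self.streams)


@dataclass
class WindowBatch:
    """Aligned fixed-length windows per modality.

    ``windows[m]`` has shape (N, T_w(m), C(m)); all modalities share N and
    the same window duration in seconds.  ``presence`` is the N x M
    availability mask over the slots in ``modalities`` (every row has at
    least one present modality).
    """

    windows: dict[str, np.ndarray]
    labels: np.ndarray          # (N,)
    presence: np.ndarray        # (N, M) bool
    subject_ids: np.ndarray     # (N,) str
    modalities: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.modalities:
            self.modalities = list(self.windows)
        ns = {m: w.shape[0] for m, w in self.windows.items()}
        if len(set(ns.values())) != 1:
            raise ValueError(f"window counts differ across modalities: {ns}")
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        self.presence = np.asarray(self.presence, dtype=bool)
        self.subject_ids = np.asarray(self.subject_ids)
        n = self.n_windows
        if not (len(self.labels) == n == self.presence.shape[0] == len(self.subject_ids)):
            raise ValueError("labels/presence/subject_ids length mismatch")
        if self.presence.shape[1] != len(self.modalities):
            raise ValueError("presence has wrong number of modality slots")
        if n and not self.presence.any(axis=1).all():
            raise ValueError("every window needs at least one present modality")

    @property
    def n_windows(self) -> int:
        return next(iter(self.windows.values())).shape[0]

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    def select(self, idx) -> "WindowBatch":
        """Row subset (windows) of the batch."""
        return WindowBatch(
            windows={m: w[idx] for m, w in self.windows.items()},
            labels=self.labels[idx], presence=self.presence[idx],
            subject_ids=self.subject_ids[idx], modalities=list(self.modalities))


def concat_batches(batches: list[WindowBatch]) -> WindowBatch:
    """Stack several batches with identical modality slots into one."""
    if not batches:
        raise ValueError("no batches to concatenate")
    mods = batches[0].modalities
    for b in batches[1:]:
        if b.modalities != mods:
            raise ValueError("batches have different modality slots")
    return WindowBatch(
        windows={m: np.concatenate([b.windows[m] for b in batches]) for m in mods},
        labels=np.concatenate([b.labels for b in batches]),
        presence=np.concatenate([b.presence for b in batches]),
        subject_ids=np.concatenate([b.subject_ids for b in batches]),
        modalities=list(mods))


# ---------------------------------------------------------------------- I/O
def _load_matrix(path: Path, modality: str, h5_key: str | None = None) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"modality '{modality}': file not found: {path}")
    if path.suffix in (".h5", ".hdf5"):
        import h5py
        with h5py.File(path, "r") as f:
            key = h5_key or modality
            if key not in f:
                raise FileNotFoundError(
                    f"modality '{modality}': dataset '{key}' missing in {path}")
            return np.asarray(f[key], dtype=np.float64)
    return pd.read_csv(path, float_precision="round_trip").to_numpy(
        dtype=np.float64)


def read_recording(manifest_path: str | Path) -> Recording:
    """Load a recording described by a JSON manifest (CSV or HDF5 payloads)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as f:
        manifest = json.load(f)
    base = manifest_path.parent
    names = [m["name"] for m in manifest["modalities"]]
    if len(set(names)) != len(names):
        raise ManifestError(f"duplicate modality names in manifest: {names}")
    streams: dict[str, ModalityStream] = {}
    for spec in manifest["modalities"]:
        mat = _load_matrix(base / spec["path"], spec["name"])
        streams[spec["name"]] = ModalityStream(
            name=spec["name"], rate=float(spec["rate_hz"]), samples=mat,
            units=spec.get("channels"))
    lab_spec = manifest["labels"]
    lab_path = base / lab_spec["path"]
    if lab_path.suffix in (".h5", ".hdf5"):
        labels = _load_matrix(lab_path, "labels", h5_key="labels").reshape(-1)
    else:
        labels = pd.read_csv(lab_path)["label"].to_numpy()
    return Recording(subject_id=str(manifest["subject_id"]), streams=streams,
                     labels=labels.astype(np.int64),
                     label_rate=float(lab_spec["rate_hz"]))


def write_recording(recording: Recording, out_dir: str | Path,
                    fmt: str = "csv") -> Path:
    """Write a recording (manifest + per-modality files); returns manifest path.

    CSV is written at full float precision ('%.17g') so that a write/read
    round trip reproduces the samples bit-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"subject_id": recording.subject_id, "modalities": [],
                "labels": {"path": "labels.csv", "rate_hz": recording.label_rate},
                "label_set": sorted(int(v) for v in np.unique(recording.labels))}
    if fmt == "csv":
        for name, s in recording.streams.items():
            path = out_dir / f"{name}.csv"
            cols = s.units if s.units and len(s.units) == s.n_channels \
                else [f"ch{i}" for i in range(s.n_channels)]
            with open(path, "w") as f:
                f.write(",".join(cols) + "\n")
                np.savetxt(f, s.samples, fmt="%.17g", delimiter=",")
            manifest["modalities"].append(
                {"name": name, "path": path.name, "rate_hz": s.rate, "channels": cols})
        pd.DataFrame({"label": recording.labels}).to_csv(out_dir / "labels.csv",
                                                         index=False)
    elif fmt == "h5":
        import h5py
        h5_path = out_dir / "data.h5"
        with h5py.File(h5_path, "w") as f:
            for name, s in recording.streams.items():
                f.create_dataset(name, data=s.samples)
                manifest["modalities"].append(
                    {"name": name, "path": h5_path.name, "rate_hz": s.rate,
                     "channels": s.units or [f"ch{i}" for i in range(s.n_channels)]})
            f.create_dataset("labels", data=recording.labels)
        manifest["labels"] = {"path": h5_path.name, "rate_hz": recording.label_rate}
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest_path


# ----------------------------------------------------------- transformations
def resample(stream: ModalityStream, target_rate: float,
             antialias: bool = False) -> ModalityStream:
    """Resample to ``target_rate`` by linear interpolation on the common
    time grid; duration is preserved to within one sample period.

    ``antialias`` optionally low-pass filters (4th-order Butterworth at 80%%
    of the target Nyquist, zero-phase) before downsampling.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    if target_rate == stream.rate:
        return replace(stream, samples=stream.samples.copy())
    x = stream.samples
    if antialias and target_rate < stream.rate:
        from scipy.signal import butter, filtfilt
        b, a = butter(4, 0.8 * (target_rate / 2) / (stream.rate / 2))
        x = filtfilt(b, a, x, axis=0)
    n_out = int(round(stream.n_samples * target_rate / stream.rate))
    n_out = max(n_out, 1)
    t_old = np.arange(stream.n_samples) / stream.rate
    t_new = np.arange(n_out) / target_rate
    out = np.empty((n_out, stream.n_channels))
    for c in range(stream.n_channels):
        out[:, c] = np.interp(t_new, t_old, x[:, c])
    return replace(stream, rate=float(target_rate), samples=out)


def channel_stats(stream: ModalityStream) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel population mean and standard deviation."""
    return stream.samples.mean(axis=0), stream.samples.std(axis=0)


def zscore(stream: ModalityStream,
           stats: tuple[np.ndarray, np.ndarray] | None = None) -> ModalityStream:
    """Per-channel z-score normalization.

    Without ``stats`` the stream's own per-recording population statistics
    are used.  Channels with std below 1e-8 (constant channels) map to all
    zeros rather than dividing by ~0.
    """
    mean, std = channel_stats(stream) if stats is None else stats
    mean = np.asarray(mean, dtype=np.float64).reshape(-1)
    std = np.asarray(std, dtype=np.float64).reshape(-1)
    degenerate = std < _EPS_STD
    safe_std = np.where(degenerate, 1.0, std)
    out = (stream.samples - mean) / safe_std
    out[:, degenerate] = 0.0
    return replace(stream, samples=out)


def zscore_recording(recording: Recording) -> Recording:
    """z-score every stream of a recording with its own statistics."""
    return replace(recording,
                   streams={m: zscore(s) for m, s in recording.streams.items()})


# ------------------------------------------------------------------ windows
def window_count(n_samples: int, t_w: int, stride: int) -> int:
    """Number of full windows of length ``t_w`` at the given stride."""
    if n_samples < t_w:
        return 0
    return (n_samples - t_w) // stride + 1


def _window_params(rate: float, window_s: float, overlap: float) -> tuple[int, int]:
    t_w = int(round(rate * window_s))
    stride = int(round(t_w * (1.0 - overlap)))
    return t_w, max(stride, 1)


def _majority_label(window: np.ndarray) -> int:
    # ties broken toward the smallest label id (bincount argmax convention)
    shifted = window - window.min()
    return int(np.bincount(shifted).argmax() + window.min())


def make_windows(recording: Recording, window_s: float, overlap: float = 0.5,
                 label_policy: str = "majority") -> WindowBatch:
    """Segment a recording into aligned fixed-length overlapping windows.

    Per modality, T_w = round(rate * window_s) and
    stride = round(T_w * (1 - overlap)); the window count
    N = floor((T - T_w) / stride) + 1 must agree across modalities (streams
    are required to share their duration to within one sample).  Window
    labels are the majority per-step label, ties broken toward the smallest
    label id.  The presence mask starts all-true.
    """
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    if label_policy != "majority":
        raise ValueError(f"unknown label policy: {label_policy!r}")
    durations = {m: s.duration for m, s in recording.streams.items()}
    ref = min(durations.values())
    for m, d in durations.items():
        tol = 1.0 / recording.streams[m].rate + 1e-9
        if d - ref > tol:
            raise AlignmentError(
                f"stream durations inconsistent beyond one sample: {durations}")

    counts: dict[str, int] = {}
    windows: dict[str, np.ndarray] = {}
    for m, s in recording.streams.items():
        t_w, stride = _window_params(s.rate, window_s, overlap)
        n = window_count(s.n_samples, t_w, stride)
        if n == 0:
            raise ValueError(
                f"stream '{m}' ({s.duration:.2f} s) is shorter than one "
                f"{window_s} s window")
        counts[m] = n
        starts = np.arange(n) * stride
        windows[m] = np.stack([s.samples[s0:s0 + t_w] for s0 in starts])
    if len(set(counts.values())) != 1:
        raise AlignmentError(f"window counts differ across modalities: {counts}")
    n = next(iter(counts.values()))

    lab_t_w, lab_stride = _window_params(recording.label_rate, window_s, overlap)
    labels = np.empty(n, dtype=np.int64)
    for i in range(n):
        s0 = i * lab_stride
        chunk = recording.labels[s0:s0 + lab_t_w]
        if len(chunk) == 0:  # duration off-by-one at the tail
            chunk = recording.labels[-1:]
        labels[i] = _majority_label(chunk)

    mods = recording.modality_names
    return WindowBatch(
        windows=windows, labels=labels,
        presence=np.ones((n, len(mods)), dtype=bool),
        subject_ids=np.full(n, recording.subject_id, dtype=object),
        modalities=mods)
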