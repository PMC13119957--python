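"""The detect-and-repair network.

Architecture (one instance per modality where noted):

* **Encoder** (per modality): three 1-D convolutions, kernels (5, 3, 3),
  channels (64, 128, 128), stride 1, zero same-padding, each followed by
  ReLU and batch normalization; global average pooling over time yields a
  D=128 embedding z(m).
* **Attention fusion**: a shared additive scoring map
  ``score(z) = w . tanh(W z + b)`` produces one score per (window,
  modality); a softmax restricted to the *present* modalities turns the
  scores into weights (absent modalities get weight exactly 0), and the
  fused representation is the weighted sum of a shared linear value
  transform of the embeddings.
* **Presence head**: a 2-layer MLP on the fused vector with logistic
  outputs, one probability per modality slot (multi-label detection).
* **Decoder** (per modality): a 2-layer MLP on the fused vector
  concatenated with the presence mask, emitting the full window
  (T_w x C); reconstructions are produced for all modalities and the
  masked loss selects the dropped ones.
* **Projection head**: D -> D -> 64 MLP feeding the contrastive loss.

All forward passes are deterministic in evaluation mode (batch norm then
uses running statistics, making rows independent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, stack
from .nn import Adam, BatchNorm1d, Conv1d, Linear, Module  # noqa: F401  (Adam re-export)

__all__ = ["EncoderSpec", "EmbeddingSet", "ModalityEncoder",
           "AttentionFusion", "ProjectionHead", "PresenceHead",
           "ModalityDecoder", "RepairNet"]


@dataclass
class EncoderSpec:
    """Hyperparameters of the shallow convolutional encoders."""

    kernels: tuple[int, ...] = (5, 3, 3)
    channels: tuple[int, ...] = (64, 128, 128)
    proj_dim: int = 64
    attn_hidden: int = 64
    decoder_hidden: int = 256

    def __post_init__(self):
        if len(self.kernels) != len(self.channels):
            raise ValueError("kernels and channels must have equal length")

    @property
    def embed_dim(self) -> int:
        return self.channels[-1]


@dataclass
class EmbeddingSet:
    """Per-modality embeddings, fused embedding and attention weights."""

    per_modality: dict[str, Tensor]
    fused: Tensor                 # (N, D)
    attention: np.ndarray         # (N, M), rows sum to 1 over present slots


class ModalityEncoder(Module):
    """Conv(5)-ReLU-BN, Conv(3)-ReLU-BN, Conv(3)-ReLU-BN, global avg pool."""

    def __init__(self, n_channels: int, spec: EncoderSpec,
                 rng: np.random.Generator):
        super().__init__()
        self.n_channels = n_channels
        convs, bns = [], []
        c_in = n_channels
        for k, c_out in zip(spec.kernels, spec.channels):
            convs.append(Conv1d(c_in, c_out, k, rng))
            bns.append(BatchNorm1d(c_out))
            c_in = c_out
        self.convs = convs
        self.bns = bns

    def __call__(self, x: Tensor) -> Tensor:
        """x: (N, T_w, C) -> (N, D) embedding."""
        if x.shape[-1] != self.n_channels:
            raise ValueError(
                f"encoder expects {self.n_channels} channels, got {x.shape[-1]}")
        h = x.transpose(0, 2, 1)  # (N, C, T)
        for conv, bn in zip(self.convs, self.bns):
            h = bn(conv(h).relu())
        return h.mean(axis=2)     # global average pool over time


class AttentionFusion(Module):
    """Additive attention over present modalities; absent weight exactly 0."""

    def __init__(self, d: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.score_map = Linear(d, hidden, rng)
        self.score_vec = Linear(hidden, 1, rng)
        self.value = Linear(d, d, rng)

    def __call__(self, embeddings: list[Tensor],
                 presence: np.ndarray) -> tuple[Tensor, np.ndarray]:
        """embeddings: M tensors of shape (N, D); presence: (N, M) bool."""
        presence = np.asarray(presence, dtype=bool)
        n, m = presence.shape
        if not presence.any(axis=1).all():
            raise ValueError("fusion requires >= 1 present modality per window")
        z = stack(embeddings, axis=1)                       # (N, M, D)
        d = z.shape[2]
        flat = z.reshape(n * m, d)
        scores = self.score_vec(self.score_map(flat).tanh()).reshape(n, m)
        # softmax over present slots only (max-shift for stability); absent
        # slots are driven to -1e9 so their exponential underflows to 0.0
        maskf = presence.astype(scores.data.dtype)
        masked = scores * Tensor(maskf) + Tensor((1.0 - maskf) * -1e9)
        shift = masked.data.max(axis=1, keepdims=True)
        e = (masked - Tensor(shift)).exp() * Tensor(maskf)
        weights = e * (e.sum(axis=1, keepdims=True) ** -1.0)  # (N, M)
        values = self.value(flat).reshape(n, m, d)
        fused = (values * weights.reshape(n, m, 1)).sum(axis=1)
        return fused, weights.data.copy()


class ProjectionHead(Module):
    """D -> D -> proj_dim with ReLU; L2-normalization happens in the loss."""

    def __init__(self, d: int, proj_dim: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(d, d, rng)
        self.fc2 = Linear(d, proj_dim, rng)

    def __call__(self, z: Tensor) -> Tensor:
        return self.fc2(self.fc1(z).relu())


class PresenceHead(Module):
    """Fused embedding -> per-modality availability logits."""

    def __init__(self, d: int, n_modalities: int, hidden: int,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(d, hidden, rng)
        self.fc2 = Linear(hidden, n_modalities, rng)

    def __call__(self, fused: Tensor) -> Tensor:
        """Returns logits (N, M); apply sigmoid for probabilities."""
        return self.fc2(self.fc1(fused).relu())


class ModalityDecoder(Module):
    """(fused ++ presence mask) -> full window reconstruction for one modality."""

    def __init__(self, d_in: int, t_w: int, c: int, hidden: int,
                 rng: np.random.Generator):
        super().__init__()
        self.t_w, self.c = t_w, c
        self.fc1 = Linear(d_in, hidden, rng)
        self.fc2 = Linear(hidden, t_w * c, rng)

    def __call__(self, h: Tensor) -> Tensor:
        n = h.shape[0]
        return self.fc2(self.fc1(h).relu()).reshape(n, self.t_w, self.c)


def _scatter_rows(values: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """Place rows of ``values`` at positions ``idx`` of an (n, D) zero tensor."""
    d = values.shape[1]
    out_data = np.zeros((n, d), dtype=values.data.dtype)
    out_data[idx] = values.data
    if not (values.requires_grad or values._parents):
        return Tensor(out_data)

    def backward(g, out):
        return (g[idx],)

    return Tensor(out_data, _parents=(values,), _backward=backward)


class RepairNet(Module):
    """Full detect-and-repair model over a fixed set of modality slots."""

    def __init__(self, modality_shapes: dict[str, tuple[int, int]],
                 spec: EncoderSpec | None = None, seed: int = 42):
        super().__init__()
        self.spec = spec or EncoderSpec()
        self.modalities = list(modality_shapes)
        self.modality_shapes = dict(modality_shapes)
        self.seed = seed
        rng = np.random.default_rng(seed)
        d = self.spec.embed_dim
        m = len(self.modalities)
        self.encoders = {name: ModalityEncoder(c, self.spec, rng)
                         for name, (_, c) in modality_shapes.items()}
        self.fusion = AttentionFusion(d, self.spec.attn_hidden, rng)
        self.projection = ProjectionHead(d, self.spec.proj_dim, rng)
        self.presence_head = PresenceHead(d, m, self.spec.attn_hidden, rng)
        self.decoders = {name: ModalityDecoder(d + m, t_w, c,
                                               self.spec.decoder_hidden, rng)
                         for name, (t_w, c) in modality_shapes.items()}

    # ------------------------------------------------------------- encoding
    def encode_modality(self, name: str, x) -> Tensor:
        """Encode one modality's windows (N, T_w, C) -> (N, D)."""
        if name not in self.encoders:
            raise KeyError(f"unknown modality: {name!r}")
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        return self.encoders[name](x)

    def embed(self, windows: dict[str, np.ndarray],
              presence: np.ndarray | None = None,
              encode_absent: bool = False) -> EmbeddingSet:
        """Encode and fuse a multimodal batch.

        ``presence`` marks which (window, modality) entries are available;
        ``None`` means all available (the *blind* mode used for presence
        detection, where the true mask is unknown).  By default only the
        present rows of each modality are encoded - absent rows receive a
        zero embedding that the fusion weight (exactly 0) never touches.
        ``encode_absent=True`` encodes the placeholder contents of absent
        rows too (their fusion weight is still 0).
        """
        n = next(iter(windows.values())).shape[0]
        m = len(self.modalities)
        if presence is None:
            presence = np.ones((n, m), dtype=bool)
        presence = np.asarray(presence, dtype=bool)
        per: dict[str, Tensor] = {}
        for j, name in enumerate(self.modalities):
            x = windows[name]
            pres_rows = np.flatnonzero(presence[:, j])
            if encode_absent or len(pres_rows) == n:
                per[name] = self.encode_modality(name, x)
            elif len(pres_rows) == 0:
                per[name] = Tensor(np.zeros((n, self.spec.embed_dim),
                                            dtype=np.float32))
            else:
                z_sub = self.encode_modality(name, np.asarray(x)[pres_rows])
                per[name] = _scatter_rows(z_sub, pres_rows, n)
        fused, attn = self.fusion([per[name] for name in self.modalities],
                                  presence)
        return EmbeddingSet(per_modality=per, fused=fused, attention=attn)

    # ---------------------------------------------------------------- heads
    def presence_logits(self, fused: Tensor) -> Tensor:
        return self.presence_head(fused)

    def predict_presence(self, windows: dict[str, np.ndarray]) -> np.ndarray:
        """Blind presence probabilities (N, M) for a possibly corrupted batch."""
        emb = self.embed(windows, presence=None)
        return self.presence_logits(emb.fused).sigmoid().data

    def decode_missing(self, fused: Tensor,
                       presence: np.ndarray) -> dict[str, Tensor]:
        """Reconstruct every modality conditioned on (fused ++ presence)."""
        pres = Tensor(np.asarray(presence, dtype=fused.data.dtype))
        h = concat([fused, pres], axis=1)
        return {name: self.decoders[name](h) for name in self.modalities}

    def project(self, z: Tensor) -> Tensor:
        return self.projection(z)

    def reconstruct(self, windows: dict[str, np.ndarray],
                    presence: np.ndarray) -> dict[str, np.ndarray]:
        """End-to-end repair: embed the present modalities, decode all."""
        emb = self.embed(windows, presence)
        recon = self.decode_missing(emb.fused, presence)
        return {name: r.data for name, r in recon.items()}

    # ----------------------------------------------------------- checkpoints
    def save(self, path: str | Path) -> None:
        path = Path(path)
        hyper = {"modalities": self.modalities,
                 "modality_shapes": {k: list(v) for k, v in
                                     self.modality_shapes.items()},
                 "seed": self.seed,
                 "spec": {"kernels": list(self.spec.kernels),
                          "channels": list(self.spec.channels),
                          "proj_dim": self.spec.proj_dim,
                          "attn_hidden": self.spec.attn_hidden,
                          "decoder_hidden": self.spec.decoder_hidden}}
        state = self.named_state()
        np.savez(path, __hyper__=np.frombuffer(
            json.dumps(hyper).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path: str | Path) -> "RepairNet":
        with np.load(path) as data:
            hyper = json.loads(bytes(data["__hyper__"]).decode())
            state = {k: data[k] for k in data.files if k != "__hyper__"}
        spec = EncoderSpec(kernels=tuple(hyper["spec"]["kernels"]),
                           channels=tuple(hyper["spec"]["channels"]),
                           proj_dim=hyper["spec"]["proj_dim"],
                           attn_hidden=hyper["spec"]["attn_hidden"],
                           decoder_hidden=hyper["spec"]["decoder_hidden"])
        net = cls({k: tuple(v) for k, v in hyper["modality_shapes"].items()},
                  spec=spec, seed=hyper["seed"])
        net.load_state(state)
        return net
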