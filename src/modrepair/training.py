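"""Three-phase self-supervised training.

1. **Unimodal pretraining** - SimCLR on one designated modality (the
   IMU-like one by default): two stochastic augmentations per window
   (additive jitter N(0, 0.05) and channel scaling U(0.9, 1.1)), NT-Xent
   with tau=0.5.  Optionally a BYOL-style momentum target encoder supplies
   the second view's embeddings (off by default).
2. **Multimodal masked pretraining** - encoders, fusion, decoder and
   presence head are trained with the masked reconstruction loss (plus the
   auxiliary presence loss), with a fresh modality-dropout mask sampled
   every batch.
3. **Joint fine-tuning** - both heads active: the full hybrid objective
   L = lambda_rec * L_masked + lambda_con * L_contrastive
   (+ lambda_pres * L_presence), with dropout continuing.

Ablations zero one weight: ``masked_only`` sets lambda_con=0,
``contrastive_only`` sets lambda_rec=0.

Optimization is Adam (lr 1e-3, batch 32 by default); a fixed seed makes
single-threaded runs bit-reproducible.  Every optimization step logs a
loss breakdown; per-epoch curves can be exported as CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .dropout import DropoutPolicy, apply_mask, sample_mask
from .model import EncoderSpec, ModalityEncoder, ProjectionHead, RepairNet
from .nn import Adam
from .objectives import (LossWeights, contrastive_loss, masked_loss,
                         momentum_update, ntxent_pairwise, presence_loss,
                         total_loss)
from .signal_io import WindowBatch

__all__ = ["TrainConfig", "phase1_unimodal_pretrain", "phase2_masked_pretrain",
           "phase3_joint_finetune", "train_full", "epoch_curve"]

ABLATIONS = ("hybrid", "masked_only", "contrastive_only")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs_phase1: int = 10
    epochs_phase2: int = 20
    epochs_phase3: int = 20
    seed: int = 42
    loss_weights: LossWeights = field(default_factory=LossWeights)
    dropout: DropoutPolicy = field(default_factory=lambda: DropoutPolicy(
        rate=0.3, fill="zeros"))
    ablation: str = "hybrid"
    phases: tuple[int, ...] = (1, 2, 3)
    pretrain_modality: str | None = None    # phase-1 target; default: first slot
    use_momentum_target: bool = False       # BYOL target for phase-1 positives
    encoder_spec: EncoderSpec = field(default_factory=EncoderSpec)

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")

    def effective_weights(self) -> LossWeights:
        """Loss weights after applying the ablation (weight zeroing)."""
        w = self.loss_weights
        if self.ablation == "masked_only":
            return replace(w, lambda_con=0.0)
        if self.ablation == "contrastive_only":
            return replace(w, lambda_rec=0.0)
        return w


def _minibatches(n: int, batch_size: int,
                 rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def epoch_curve(history: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-step loss log to one row per (phase, epoch)."""
    cols = ["l_masked", "l_contrastive", "l_presence", "l_total"]
    return (history.groupby(["phase", "epoch"], as_index=False)[cols]
            .mean())


# ---------------------------------------------------------------- phase 1
def _augment(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Jitter (additive N(0, 0.05)) + scaling (U(0.9, 1.1) per window)."""
    scale = rng.uniform(0.9, 1.1, size=(x.shape[0], 1, 1)).astype(x.dtype)
    noise = rng.normal(0.0, 0.05, size=x.shape).astype(x.dtype)
    return x * scale + noise


def phase1_unimodal_pretrain(batch: WindowBatch, config: TrainConfig,
                             modality: str | None = None
                             ) -> tuple[ModalityEncoder, pd.DataFrame]:
    """SimCLR pretraining of a single modality's encoder.

    Returns the trained encoder and the per-step loss log.
    """
    modality = modality or config.pretrain_modality or batch.modalities[0]
    x_all = np.asarray(batch.windows[modality], dtype=np.float32)
    n, _, c = x_all.shape
    if n < 2:
        warnings.warn("fewer than 2 windows: contrastive loss is degenerate")
    init_rng = np.random.default_rng([config.seed, 1, 0])
    encoder = ModalityEncoder(c, config.encoder_spec, init_rng)
    proj = ProjectionHead(config.encoder_spec.embed_dim,
                          config.encoder_spec.proj_dim, init_rng)
    target = None
    if config.use_momentum_target:
        t_rng = np.random.default_rng([config.seed, 1, 0])
        target = ModalityEncoder(c, config.encoder_spec, t_rng)
        target.load_state(encoder.named_state())
        target.eval()
    opt = Adam(encoder.parameters() + proj.parameters(),
               lr=config.learning_rate)
    data_rng = np.random.default_rng([config.seed, 1, 1])
    tau = config.loss_weights.tau
    rows = []
    step = 0
    for epoch in range(config.epochs_phase1):
        for idx in _minibatches(n, config.batch_size, data_rng):
            x = x_all[idx]
            va = Tensor(_augment(x, data_rng))
            vb = Tensor(_augment(x, data_rng))
            za = proj(encoder(va))
            if target is not None:
                zb = proj(target(vb).detach())
            else:
                zb = proj(encoder(vb))
            loss = ntxent_pairwise(za, zb, tau)
            opt.zero_grad()
            loss.backward()
            opt.step()
            if target is not None:
                momentum_update(encoder, target,
                                m=config.loss_weights.momentum)
            rows.append({"phase": 1, "epoch": epoch, "step": step,
                         "l_masked": 0.0, "l_contrastive": loss.item(),
                         "l_presence": 0.0, "l_total": loss.item()})
            step += 1
    return encoder, pd.DataFrame(rows)


# ------------------------------------------------------------ phases 2 & 3
def _build_net(batch: WindowBatch, config: TrainConfig,
               init_encoders: dict[str, ModalityEncoder] | None) -> RepairNet:
    shapes = {m: (batch.windows[m].shape[1], batch.windows[m].shape[2])
              for m in batch.modalities}
    net = RepairNet(shapes, spec=config.encoder_spec, seed=config.seed)
    if init_encoders:
        for name, enc in init_encoders.items():
            if name not in net.encoders:
                raise KeyError(f"unknown modality in init encoders: {name!r}")
            if enc.n_channels != net.encoders[name].n_channels:
                raise ValueError(
                    f"cannot transfer encoder for {name!r}: channel counts "
                    f"differ ({enc.n_channels} vs "
                    f"{net.encoders[name].n_channels})")
            net.encoders[name].load_state(enc.named_state())
    return net


def _ssl_epochs(net: RepairNet, batch: WindowBatch, config: TrainConfig,
                phase: int, with_contrastive: bool,
                weights: LossWeights) -> pd.DataFrame:
    """Shared masked(+contrastive)+presence optimization loop."""
    x_all = {m: np.asarray(batch.windows[m], dtype=np.float32)
             for m in batch.modalities}
    n = batch.n_windows
    m_count = batch.n_modalities
    opt = Adam(net.parameters(), lr=config.learning_rate)
    data_rng = np.random.default_rng([config.seed, phase, 1])
    mask_rng = np.random.default_rng([config.seed, phase,
                                      config.dropout.seed, 2])
    epochs = config.epochs_phase2 if phase == 2 else config.epochs_phase3
    net.train()
    rows = []
    step = 0
    for epoch in range(epochs):
        for idx in _minibatches(n, config.batch_size, data_rng):
            xb = {m: x_all[m][idx] for m in batch.modalities}
            mask = sample_mask(config.dropout, len(idx), m_count, mask_rng)
            mini = WindowBatch(windows=xb, labels=batch.labels[idx],
                               presence=np.ones_like(mask),
                               subject_ids=batch.subject_ids[idx],
                               modalities=list(batch.modalities))
            filled = apply_mask(mini, mask, config.dropout, mask_rng)
            # one encoder pass over the filled batch serves both heads
            emb = net.embed(filled.windows, presence=None)
            per = [emb.per_modality[m] for m in net.modalities]
            fused_masked, _ = net.fusion(per, mask)
            recon = net.decode_missing(fused_masked, mask)
            dropped = {m: ~mask[:, j]
                       for j, m in enumerate(net.modalities)}
            lm = masked_loss(xb, recon, dropped)
            if with_contrastive and weights.lambda_con > 0:
                projs = {m: net.project(emb.per_modality[m])
                         for m in net.modalities}
                lc = contrastive_loss(projs, mask, net.modalities,
                                      tau=weights.tau)
            else:
                lc = Tensor(np.float64(0.0))
            lp = presence_loss(net.presence_logits(emb.fused).sigmoid(), mask)
            lt, bd = total_loss(lm, lc, lp, weights)
            opt.zero_grad()
            lt.backward()
            opt.step()
            rows.append({"phase": phase, "epoch": epoch, "step": step,
                         **bd.__dict__})
            step += 1
    return pd.DataFrame(rows)


def phase2_masked_pretrain(batch: WindowBatch, config: TrainConfig,
                           init_encoders: dict[str, ModalityEncoder] | None = None
                           ) -> tuple[RepairNet, pd.DataFrame]:
    """Masked-modeling pretraining of the full network (no contrastive term)."""
    if batch.n_modalities < 2:
        raise ValueError("multimodal pretraining needs >= 2 modalities")
    net = _build_net(batch, config, init_encoders)
    w = replace(config.effective_weights(), lambda_con=0.0)
    history = _ssl_epochs(net, batch, config, phase=2,
                          with_contrastive=False, weights=w)
    return net, history


def phase3_joint_finetune(batch: WindowBatch, config: TrainConfig,
                          net: RepairNet | None = None
                          ) -> tuple[RepairNet, pd.DataFrame]:
    """Joint optimization of the hybrid objective, starting from phase-2
    parameters (or fresh ones when ``net`` is None)."""
    if net is None:
        net = _build_net(batch, config, None)
    w = config.effective_weights()
    history = _ssl_epochs(net, batch, config, phase=3,
                          with_contrastive=True, weights=w)
    return net, history


def train_full(batch: WindowBatch, config: TrainConfig
               ) -> tuple[RepairNet, pd.DataFrame]:
    """Run the configured subset of the three phases on one batch."""
    histories = []
    init_encoders = None
    if 1 in config.phases:
        modality = config.pretrain_modality or batch.modalities[0]
        enc, h1 = phase1_unimodal_pretrain(batch, config, modality)
        init_encoders = {modality: enc}
        histories.append(h1)
    net = None
    if 2 in config.phases:
        net, h2 = phase2_masked_pretrain(batch, config, init_encoders)
        histories.append(h2)
    if 3 in config.phases:
        net, h3 = phase3_joint_finetune(batch, config, net)
        histories.append(h3)
    if net is None:
        raise ValueError("config.phases must include phase 2 or 3")
    history = pd.concat(histories, ignore_index=True) if histories \
        else pd.DataFrame()
    return net, history
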