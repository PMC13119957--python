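"""Model / Results interface over the detect-and-repair pipeline.

:class:`ModalityRepairModel` is constructed from data (a
:class:`~modrepair.signal_io.WindowBatch`, or recordings via
:meth:`ModalityRepairModel.from_recordings`) plus a training
configuration; :meth:`ModalityRepairModel.fit` runs the configured
training phases and returns a :class:`ModalityRepairResults` carrying the
fitted network, the loss log, and evaluation / repair / visualization
methods.

    >>> recs = generate_dataset(default_config())
    >>> model = ModalityRepairModel.from_recordings(recs[:-1])
    >>> res = model.fit()
    >>> print(res.summary())
    >>> report = res.evaluate(test_batch)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dropout import DropoutPolicy, apply_mask, sample_mask
from .evaluation import EvalReport, evaluate_model, fused_embeddings
from .model import RepairNet
from .signal_io import (Recording, WindowBatch, concat_batches, make_windows,
                        zscore_recording)
from .training import TrainConfig, epoch_curve, train_full

__all__ = ["ModalityRepairModel", "ModalityRepairResults"]


class ModalityRepairModel:
    """Self-supervised detect-and-repair model bound to a training batch."""

    def __init__(self, batch: WindowBatch, config: TrainConfig | None = None):
        self.batch = batch
        self.config = config or TrainConfig()

    @classmethod
    def from_recordings(cls, recordings: list[Recording],
                        window_s: float = 10.0, overlap: float = 0.5,
                        normalize: bool = True,
                        config: TrainConfig | None = None
                        ) -> "ModalityRepairModel":
        """Z-score each recording (per-subject statistics), window it, and
        stack all subjects into one training batch."""
        batch = cls.prepare_batch(recordings, window_s, overlap, normalize)
        return cls(batch, config=config)

    @staticmethod
    def prepare_batch(recordings: list[Recording], window_s: float = 10.0,
                      overlap: float = 0.5,
                      normalize: bool = True) -> WindowBatch:
        if normalize:
            recordings = [zscore_recording(r) for r in recordings]
        return concat_batches([make_windows(r, window_s, overlap)
                               for r in recordings])

    def fit(self, phases: tuple[int, ...] | None = None
            ) -> "ModalityRepairResults":
        """Run the configured training phases and return the results."""
        config = self.config
        if phases is not None:
            from dataclasses import replace
            config = replace(config, phases=tuple(phases))
        net, history = train_full(self.batch, config)
        return ModalityRepairResults(self, net, history)


class ModalityRepairResults:
    """Fitted parameters, training diagnostics, and inference methods."""

    def __init__(self, model: ModalityRepairModel, net: RepairNet,
                 history: pd.DataFrame):
        self.model = model
        self.net = net
        self.history = history

    # ----------------------------------------------------------- inference
    def embed(self, batch: WindowBatch,
              presence: np.ndarray | None = None) -> np.ndarray:
        """Fused embeddings (N, D) in evaluation mode."""
        pres = batch.presence if presence is None else presence
        return fused_embeddings(self.net, batch.windows, pres)

    def detect_presence(self, windows: dict[str, np.ndarray]) -> np.ndarray:
        """Blind per-modality availability probabilities (N, M)."""
        return self.net.predict_presence(windows)

    def reconstruct(self, batch: WindowBatch,
                    presence: np.ndarray | None = None
                    ) -> dict[str, np.ndarray]:
        """Reconstruct all modalities conditioned on the present ones."""
        pres = batch.presence if presence is None else presence
        self.net.eval()
        return self.net.reconstruct(batch.windows, pres)

    def repair(self, batch: WindowBatch,
               threshold: float = 0.5
               ) -> tuple[WindowBatch, np.ndarray]:
        """Detect-and-repair: predict which modalities are missing, then
        replace the windows detected absent with their reconstructions.

        Returns the repaired batch and the detected presence mask.
        """
        self.net.eval()
        probs = self.detect_presence(batch.windows)
        detected = probs >= threshold
        # the fusion contract requires >= 1 present slot per window
        empty = ~detected.any(axis=1)
        if empty.any():
            detected[empty, np.argmax(probs[empty], axis=1)] = True
        recon = self.net.reconstruct(batch.windows, detected)
        windows = {}
        for j, m in enumerate(batch.modalities):
            w = np.asarray(batch.windows[m]).copy()
            rows = np.flatnonzero(~detected[:, j])
            if rows.size:
                w[rows] = recon[m][rows]
            windows[m] = w
        repaired = WindowBatch(windows=windows, labels=batch.labels.copy(),
                               presence=np.ones_like(detected),
                               subject_ids=batch.subject_ids.copy(),
                               modalities=list(batch.modalities))
        return repaired, detected

    def evaluate(self, test_batch: WindowBatch,
                 policy: DropoutPolicy | None = None,
                 detection_policy: DropoutPolicy | None = None,
                 rates=(0.1, 0.3, 0.5), n_repeats: int = 5,
                 seed: int = 0, fold_id: str = "") -> EvalReport:
        return evaluate_model(self.net, self.model.batch, test_batch,
                              policy=policy,
                              detection_policy=detection_policy,
                              rates=rates, n_repeats=n_repeats, seed=seed,
                              fold_id=fold_id)

    # --------------------------------------------------------- diagnostics
    @property
    def loss_curve(self) -> pd.DataFrame:
        """Per-(phase, epoch) mean losses."""
        return epoch_curve(self.history)

    def summary(self) -> str:
        cfg = self.model.config
        batch = self.model.batch
        lines = [
            "Modality repair model",
            "=" * 58,
            f"{'modalities:':<22}{', '.join(batch.modalities)}",
            f"{'windows (train):':<22}{batch.n_windows}",
            f"{'subjects:':<22}{len(set(batch.subject_ids.tolist()))}",
            f"{'parameters:':<22}{self.net.n_parameters()}",
            f"{'ablation:':<22}{cfg.ablation}",
            f"{'dropout rate / fill:':<22}{cfg.dropout.rate} / {cfg.dropout.fill}",
            f"{'weights:':<22}rec={cfg.effective_weights().lambda_rec} "
            f"con={cfg.effective_weights().lambda_con} "
            f"pres={cfg.effective_weights().lambda_pres}",
            f"{'tau / momentum:':<22}{cfg.loss_weights.tau} / "
            f"{cfg.loss_weights.momentum}",
            f"{'optimizer:':<22}Adam lr={cfg.learning_rate} "
            f"batch={cfg.batch_size} seed={cfg.seed}",
            "-" * 58,
            f"{'phase':>6}{'epochs':>8}{'final L_masked':>16}"
            f"{'final L_total':>14}",
        ]
        curve = self.loss_curve
        for phase in sorted(curve["phase"].unique()):
            sub = curve[curve["phase"] == phase]
            last = sub.iloc[-1]
            lines.append(f"{int(phase):>6}{len(sub):>8}"
                         f"{last['l_masked']:>16.4f}"
                         f"{last['l_total']:>14.4f}")
        return "\n".join(lines)

    # -------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        """Checkpoint (npz parameter archive) + loss log CSV next to it."""
        path = Path(path)
        self.net.save(path)
        self.history.to_csv(path.with_suffix(".losses.csv"), index=False)

    @staticmethod
    def load_net(path: str | Path) -> RepairNet:
        return RepairNet.load(path)
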