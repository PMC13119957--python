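"""Modality-dropout simulation: presence-mask sampling and fill policies.

Dropout is applied per window and per modality, i.i.d. with a marginal
drop probability ``rate``; a guard resamples any all-absent row so every
window keeps at least one modality (the model contract requires it).

Fill policies control what the tensor placeholder of a dropped modality
contains:

* ``zeros``              - all-zero window (training default),
* ``gaussian-noise``     - i.i.d. N(0,1), matching the z-scored signal
  scale; this emulates a corrupted-but-active sensor and is the default
  for presence-detection evaluation, where zero-fill would make the
  detection task trivially easy,
* ``last-window-hold``   - the previous present window of that modality
  (zeros if there is none), emulating a stale buffer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .signal_io import WindowBatch

__all__ = ["DropoutPolicy", "sample_mask", "apply_mask"]

FILL_POLICIES = ("zeros", "gaussian-noise", "last-window-hold")


@dataclass
class DropoutPolicy:
    rate: float = 0.3
    fill: str = "zeros"
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        if self.fill not in FILL_POLICIES:
            raise ValueError(f"unknown fill policy {self.fill!r}; "
                             f"choose from {FILL_POLICIES}")


def sample_mask(policy: DropoutPolicy, n_windows: int, n_modalities: int,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Sample an (N, M) presence mask.

    Each entry is independently present with probability ``1 - rate``;
    all-absent rows are resampled until at least one modality survives
    (for rate r and M modalities the guard bias on the marginal is < r^M).
    """
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    mask = rng.random((n_windows, n_modalities)) >= policy.rate
    bad = ~mask.any(axis=1)
    while bad.any():
        mask[bad] = rng.random((int(bad.sum()), n_modalities)) >= policy.rate
        bad = ~mask.any(axis=1)
    return mask


def apply_mask(batch: WindowBatch, mask: np.ndarray,
               policy: DropoutPolicy,
               rng: np.random.Generator | None = None) -> WindowBatch:
    """Replace dropped (window, modality) entries per the fill policy and
    set ``batch.presence`` to ``mask``.  The input batch is not modified."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (batch.n_windows, batch.n_modalities):
        raise ValueError(
            f"mask shape {mask.shape} != "
            f"({batch.n_windows}, {batch.n_modalities})")
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    windows: dict[str, np.ndarray] = {}
    for j, m in enumerate(batch.modalities):
        w = batch.windows[m].copy()
        dropped = np.flatnonzero(~mask[:, j])
        if dropped.size:
            if policy.fill == "zeros":
                w[dropped] = 0.0
            elif policy.fill == "gaussian-noise":
                w[dropped] = rng.standard_normal((dropped.size,) + w.shape[1:])
            elif policy.fill == "last-window-hold":
                for i in dropped:  # dropped is sorted: holds may chain
                    prev = np.flatnonzero(mask[:i, j])
                    w[i] = batch.windows[m][prev[-1]] if prev.size else 0.0
        windows[m] = w
    return WindowBatch(windows=windows, labels=batch.labels.copy(),
                       presence=mask.copy(),
                       subject_ids=batch.subject_ids.copy(),
                       modalities=list(batch.modalities))
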