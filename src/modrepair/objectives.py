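"""Self-supervised training objectives.

The hybrid objective is

    L_total = lambda_rec * L_masked + lambda_con * L_contrastive
              (+ lambda_pres * L_presence)

where ``L_masked`` is the mean-squared reconstruction error over the
*dropped* modalities, ``L_contrastive`` is NT-Xent agreement between
projections of the same window seen through different modalities, and the
auxiliary ``L_presence`` is the multi-label binary cross-entropy of the
presence head.  Defaults: lambda_rec=1.0, lambda_con=0.5, tau=0.5, and
BYOL-style momentum m=0.996 for optional target-network updates.

All loss functions accept either plain numpy arrays (evaluation) or
autodiff :class:`~modrepair.autodiff.Tensor` inputs (training) and return
a Tensor; use ``.item()`` for the scalar value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .autodiff import Tensor, concat
from .nn import Module

__all__ = ["LossWeights", "LossBreakdown", "masked_loss", "ntxent_pairwise",
           "contrastive_loss", "presence_loss", "total_loss",
           "momentum_update"]

_NORM_EPS = 1e-12
_PROB_CLIP = 1e-7


@dataclass
class LossWeights:
    lambda_rec: float = 1.0
    lambda_con: float = 0.5
    lambda_pres: float = 0.1
    tau: float = 0.5
    momentum: float = 0.996

    def __post_init__(self):
        if min(self.lambda_rec, self.lambda_con, self.lambda_pres) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.tau <= 0:
            raise ValueError("temperature tau must be > 0")
        if not (0 <= self.momentum <= 1):
            raise ValueError("momentum must be in [0, 1]")


@dataclass
class LossBreakdown:
    l_masked: float
    l_contrastive: float
    l_presence: float
    l_total: float


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


# ------------------------------------------------------------------- masked
def masked_loss(x: Mapping[str, object], x_hat: Mapping[str, object],
                dropped) -> Tensor:
    """Mean squared error over dropped modalities.

    ``dropped`` is either an iterable of modality names (the same set for
    every window) or a mapping name -> (N,) boolean array of per-window
    drops.  Per window, the element-wise MSE of each dropped modality is
    averaged over the dropped set (1/|Mdrop| * sum); the result is the mean
    over windows with at least one drop.  No drops at all -> 0.
    """
    if isinstance(dropped, Mapping):
        drop_vecs = {m: np.asarray(v, dtype=bool) for m, v in dropped.items()}
    else:
        names = set(dropped)
        drop_vecs = {}
        for m in names:
            if m not in x:
                raise KeyError(f"dropped modality {m!r} not in batch")
            n = _t(x[m]).shape[0]
            drop_vecs[m] = np.ones(n, dtype=bool)
    mods = [m for m, v in drop_vecs.items() if v.any()]
    if not mods:
        return Tensor(np.float64(0.0))

    n = _t(x[mods[0]]).shape[0]
    n_drop = np.zeros(n)
    for m in mods:
        n_drop += drop_vecs[m]
    active = n_drop > 0
    n_active = int(active.sum())

    total = Tensor(np.float64(0.0))
    for m in mods:
        xt, ht = _t(x[m]), _t(x_hat[m])
        if xt.shape != ht.shape:
            raise ValueError(f"modality {m!r}: shape mismatch "
                             f"{xt.shape} vs {ht.shape}")
        per_win = ((ht - xt) ** 2.0).mean(
            axis=tuple(range(1, len(xt.shape))))            # (N,)
        w = np.where(drop_vecs[m], 1.0 / np.maximum(n_drop, 1.0), 0.0)
        total = total + (per_win * Tensor(w)).sum()
    return total * (1.0 / n_active)


# -------------------------------------------------------------- contrastive
def _l2_normalize(z: Tensor) -> Tensor:
    norm = ((z ** 2.0).sum(axis=1, keepdims=True)) ** 0.5
    return z * ((norm + _NORM_EPS) ** -1.0)


def ntxent_pairwise(proj_a, proj_b, tau: float = 0.5) -> Tensor:
    """Normalized-temperature cross-entropy between two views.

    Rows are L2-normalized; the 2N stacked projections form the batch; for
    each anchor the positive is the same instance in the other view and
    the denominator runs over all 2N-1 non-self samples.  Returns the mean
    over the 2N anchors.  N=1 degenerates to 0 (a single positive and no
    negatives).
    """
    a, b = _t(proj_a), _t(proj_b)
    if a.shape != b.shape:
        raise ValueError("projection shapes differ")
    n = a.shape[0]
    if n < 2:
        return Tensor(np.float64(0.0))
    z = _l2_normalize(concat([a, b], axis=0))               # (2N, P)
    sim = (z @ z.T) * (1.0 / tau)                           # (2N, 2N)
    eye = np.eye(2 * n, dtype=sim.data.dtype)
    sim = sim + Tensor(eye * -1e9)                          # exclude self
    shift = sim.data.max(axis=1, keepdims=True)
    lse = ((sim - Tensor(shift)).exp().sum(axis=1, keepdims=True)).log() \
        + Tensor(shift)                                     # (2N, 1)
    rows = np.arange(2 * n)
    cols = np.concatenate([rows[n:], rows[:n]])             # positive index
    pos = sim[rows, cols]                                   # (2N,)
    return (lse.reshape(2 * n) - pos).mean()


def contrastive_loss(projections: Mapping[str, object], presence,
                     modalities: Sequence[str] | None = None,
                     tau: float = 0.5) -> Tensor:
    """Mean NT-Xent over all unordered modality pairs.

    Each pair (i, j) is evaluated on the windows where *both* members are
    present; pairs with fewer than 2 shared windows are skipped.  Returns
    0 when no valid pair exists.
    """
    modalities = list(modalities) if modalities is not None \
        else list(projections)
    presence = np.asarray(presence, dtype=bool)
    terms = []
    for i in range(len(modalities)):
        for j in range(i + 1, len(modalities)):
            shared = np.flatnonzero(presence[:, i] & presence[:, j])
            if len(shared) < 2:
                continue
            a = _t(projections[modalities[i]])[shared]
            b = _t(projections[modalities[j]])[shared]
            terms.append(ntxent_pairwise(a, b, tau))
    if not terms:
        return Tensor(np.float64(0.0))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


# ----------------------------------------------------------------- presence
def presence_loss(probs, true_mask) -> Tensor:
    """Mean binary cross-entropy over all N*M presence entries."""
    p = _t(probs).clamp(_PROB_CLIP, 1.0 - _PROB_CLIP)
    y = np.asarray(true_mask, dtype=float)
    bce = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log())
    return bce.mean()


# -------------------------------------------------------------------- total
def total_loss(l_masked, l_contrastive, l_presence=0.0,
               weights: LossWeights | None = None):
    """Weighted combination; returns (Tensor total, LossBreakdown)."""
    w = weights or LossWeights()
    lm, lc, lp = _t(l_masked), _t(l_contrastive), _t(l_presence)
    lt = lm * w.lambda_rec + lc * w.lambda_con + lp * w.lambda_pres
    return lt, LossBreakdown(l_masked=float(lm.data),
                             l_contrastive=float(lc.data),
                             l_presence=float(lp.data),
                             l_total=float(lt.data))


# ----------------------------------------------------------------- momentum
def momentum_update(online, target, m: float = 0.996) -> None:
    """BYOL-style EMA: target <- m * target + (1 - m) * online, in place.

    Accepts two :class:`~modrepair.nn.Module` instances (all parameters
    and buffers are updated) or two sequences of tensors/arrays.
    """
    if isinstance(online, Module) and isinstance(target, Module):
        so, st = online.named_state(), target.named_state()
        if so.keys() != st.keys():
            raise ValueError("online/target parameter structures differ")
        new = {k: m * st[k] + (1 - m) * so[k] for k in st}
        target.load_state(new)
        return
    online = list(online)
    target = list(target)
    if len(online) != len(target):
        raise ValueError("online/target parameter structures differ")
    for po, pt in zip(online, target):
        o = po.data if isinstance(po, Tensor) else np.asarray(po)
        t = pt.data if isinstance(pt, Tensor) else np.asarray(pt)
        if o.shape != t.shape:
            raise ValueError("online/target parameter structures differ")
        if isinstance(pt, Tensor):
            pt.data = m * t + (1 - m) * o
        else:
            pt[...] = m * t + (1 - m) * o
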