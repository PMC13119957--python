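"""Evaluation: reconstruction error, downstream probing, presence
detection, dropout-robustness sweeps and latent-space projection.

The downstream classifier is a multinomial logistic probe on frozen fused
embeddings - the standard self-supervised evaluation protocol.  All
metrics operate on z-scored signals (the domain the model is trained in),
so the RMSE of an all-zeros predictor is ~1 by construction, a convenient
baseline for judging repair quality.  Subject-level generalization uses
leave-one-subject-out (LOSO) folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, f1_score,
                             precision_recall_fscore_support)

from .dropout import DropoutPolicy, apply_mask, sample_mask
from .model import RepairNet
from .signal_io import Recording, WindowBatch

__all__ = ["EvalReport", "reconstruction_rmse", "split_loso", "linear_probe",
           "presence_metrics", "robustness_sweep", "project_embeddings",
           "fused_embeddings", "repair_rmse", "evaluate_model"]


@dataclass
class EvalReport:
    rmse_per_modality: dict[str, float] = field(default_factory=dict)
    probe_accuracy: float = float("nan")
    probe_macro_f1: float = float("nan")
    presence_metrics: dict = field(default_factory=dict)
    robustness_curve: dict[float, dict[str, float]] = field(default_factory=dict)
    fold_id: str = ""

    def to_dict(self) -> dict:
        return {"fold_id": self.fold_id,
                "rmse_per_modality": self.rmse_per_modality,
                "probe_accuracy": self.probe_accuracy,
                "probe_macro_f1": self.probe_macro_f1,
                "presence_metrics": self.presence_metrics,
                "robustness_curve": {str(k): v for k, v in
                                     self.robustness_curve.items()}}


# ------------------------------------------------------------------ metrics
def reconstruction_rmse(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Root mean squared error over all N*T_w*C entries."""
    x, x_hat = np.asarray(x, dtype=float), np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.sqrt(np.mean((x - x_hat) ** 2)))


def split_loso(dataset: list[Recording]) -> list[tuple[list[Recording],
                                                       list[Recording]]]:
    """Leave-one-subject-out folds, ordered by subject id."""
    subjects = sorted({r.subject_id for r in dataset})
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    folds = []
    for s in subjects:
        test = [r for r in dataset if r.subject_id == s]
        train = [r for r in dataset if r.subject_id != s]
        folds.append((train, test))
    return folds


def linear_probe(train_embeddings: np.ndarray, train_labels: np.ndarray,
                 test_embeddings: np.ndarray, test_labels: np.ndarray,
                 seed: int = 0) -> dict:
    """Multinomial logistic probe on frozen embeddings (L2-regularized)."""
    train_labels = np.asarray(train_labels)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("probe training set has a single class")
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(train_embeddings, train_labels)
    pred = clf.predict(test_embeddings)
    prec, rec, f1, _ = precision_recall_fscore_support(
        test_labels, pred, zero_division=0,
        labels=np.unique(np.concatenate([train_labels, test_labels])))
    return {"accuracy": float(accuracy_score(test_labels, pred)),
            "macro_f1": float(f1_score(test_labels, pred, average="macro",
                                       zero_division=0)),
            "per_class_precision": prec.tolist(),
            "per_class_recall": rec.tolist()}


def presence_metrics(probs: np.ndarray, true_mask: np.ndarray,
                     threshold: float = 0.5,
                     modalities: list[str] | None = None) -> dict:
    """Per-modality and macro binary detection metrics at ``threshold``.

    Zero-denominator precision/recall/F1 follow the 0 convention.
    """
    probs = np.asarray(probs, dtype=float)
    true_mask = np.asarray(true_mask, dtype=bool)
    pred = probs >= threshold
    mods = modalities or [f"m{j}" for j in range(true_mask.shape[1])]
    per = {}
    for j, name in enumerate(mods):
        p, r, f1, _ = precision_recall_fscore_support(
            true_mask[:, j], pred[:, j], average="binary", zero_division=0)
        per[name] = {"accuracy": float(accuracy_score(true_mask[:, j],
                                                      pred[:, j])),
                     "precision": float(p), "recall": float(r),
                     "f1": float(f1)}
    macro = {k: float(np.mean([per[m][k] for m in mods]))
             for k in ("accuracy", "precision", "recall", "f1")}
    return {"per_modality": per, "macro": macro}


# --------------------------------------------------------------- embeddings
def fused_embeddings(net: RepairNet, windows: dict[str, np.ndarray],
                     presence: np.ndarray | None = None,
                     chunk: int = 256) -> np.ndarray:
    """Evaluation-mode fused embeddings, computed in chunks."""
    net.eval()
    n = next(iter(windows.values())).shape[0]
    out = []
    for s in range(0, n, chunk):
        pres = None if presence is None else presence[s:s + chunk]
        emb = net.embed({m: w[s:s + chunk] for m, w in windows.items()}, pres)
        out.append(emb.fused.data)
    return np.concatenate(out, axis=0)


def repair_rmse(net: RepairNet, batch: WindowBatch,
                mask: np.ndarray) -> dict[str, dict[str, float]]:
    """RMSE of the model's reconstruction of dropped windows, per modality,
    against the zero-imputation and per-channel-mean-imputation baselines.
    """
    net.eval()
    emb = net.embed(batch.windows, mask)
    recon = net.decode_missing(emb.fused, mask)
    out = {}
    for j, m in enumerate(batch.modalities):
        rows = np.flatnonzero(~mask[:, j])
        if rows.size == 0:
            continue
        truth = batch.windows[m][rows]
        model_hat = recon[m].data[rows]
        mean_hat = np.broadcast_to(
            batch.windows[m].mean(axis=(0, 1)), truth.shape)
        out[m] = {"model": reconstruction_rmse(truth, model_hat),
                  "zeros": reconstruction_rmse(truth, np.zeros_like(truth)),
                  "mean": reconstruction_rmse(truth, mean_hat)}
    return out


def robustness_sweep(net: RepairNet, train_batch: WindowBatch,
                     test_batch: WindowBatch,
                     rates=(0.1, 0.3, 0.5),
                     policy: DropoutPolicy | None = None,
                     n_repeats: int = 10, seed: int = 0,
                     probe_seed: int = 0) -> dict[float, dict[str, float]]:
    """Probe accuracy under test-time modality dropout, per rate.

    The probe is trained once on full-modality train embeddings; each rate
    is evaluated with ``n_repeats`` freshly seeded masks and reported as
    mean +/- sd.  Rate 0 reproduces the full-modality accuracy exactly.
    """
    policy = policy or DropoutPolicy(rate=0.3, fill="zeros")
    train_emb = fused_embeddings(net, train_batch.windows)
    clf = LogisticRegression(max_iter=2000, random_state=probe_seed)
    clf.fit(train_emb, train_batch.labels)
    curve: dict[float, dict[str, float]] = {}
    rng = np.random.default_rng(seed)
    for rate in rates:
        accs = []
        if rate == 0:
            emb = fused_embeddings(net, test_batch.windows)
            accs = [accuracy_score(test_batch.labels, clf.predict(emb))]
        else:
            pol = DropoutPolicy(rate=rate, fill=policy.fill,
                                seed=policy.seed)
            for _ in range(n_repeats):
                mask = sample_mask(pol, test_batch.n_windows,
                                   test_batch.n_modalities, rng)
                filled = apply_mask(test_batch, mask, pol, rng)
                emb = fused_embeddings(net, filled.windows, mask)
                accs.append(accuracy_score(test_batch.labels,
                                           clf.predict(emb)))
        curve[float(rate)] = {"mean_accuracy": float(np.mean(accs)),
                              "sd_accuracy": float(np.std(accs)),
                              "n_repeats": len(accs)}
    return curve


def project_embeddings(embeddings: np.ndarray, method: str = "pca",
                       seed: int = 0) -> np.ndarray:
    """2-D projection of embeddings for visualization (PCA or t-SNE)."""
    embeddings = np.asarray(embeddings)
    if embeddings.shape[0] < 3:
        raise ValueError("need at least 3 points to project")
    if method == "pca":
        from sklearn.decomposition import PCA
        return PCA(n_components=2, random_state=seed).fit_transform(embeddings)
    if method == "tsne":
        from sklearn.manifold import TSNE
        perplexity = max(1.0, min(30.0, (embeddings.shape[0] - 1) / 3.0))
        return TSNE(n_components=2, random_state=seed,
                    perplexity=perplexity, init="pca").fit_transform(embeddings)
    raise ValueError(f"unknown projection method: {method!r}")


# ------------------------------------------------------------- full report
def evaluate_model(net: RepairNet, train_batch: WindowBatch,
                   test_batch: WindowBatch,
                   policy: DropoutPolicy | None = None,
                   detection_policy: DropoutPolicy | None = None,
                   rates=(0.1, 0.3, 0.5), n_repeats: int = 5,
                   seed: int = 0, fold_id: str = "") -> EvalReport:
    """One-stop evaluation used by the results API and the CLI.

    Reconstruction RMSE and the robustness curve use ``policy`` (zero-fill
    by default); presence detection uses ``detection_policy``
    (gaussian-noise fill by default, which - unlike zero-fill - emulates a
    corrupted-but-active sensor and keeps the detection task non-trivial).
    """
    policy = policy or DropoutPolicy(rate=0.3, fill="zeros")
    detection_policy = detection_policy or DropoutPolicy(
        rate=0.3, fill="gaussian-noise")
    rng = np.random.default_rng(seed)
    net.eval()

    mask = sample_mask(policy, test_batch.n_windows,
                       test_batch.n_modalities, rng)
    rmse = {m: v["model"]
            for m, v in repair_rmse(net, test_batch, mask).items()}

    train_emb = fused_embeddings(net, train_batch.windows)
    test_emb = fused_embeddings(net, test_batch.windows)
    probe = linear_probe(train_emb, train_batch.labels,
                         test_emb, test_batch.labels, seed=seed)

    det_mask = sample_mask(detection_policy, test_batch.n_windows,
                           test_batch.n_modalities, rng)
    det_filled = apply_mask(test_batch, det_mask, detection_policy, rng)
    probs = net.predict_presence(det_filled.windows)
    pres = presence_metrics(probs, det_mask, modalities=test_batch.modalities)

    curve = robustness_sweep(net, train_batch, test_batch, rates=rates,
                             policy=policy, n_repeats=n_repeats, seed=seed)
    return EvalReport(rmse_per_modality=rmse,
                      probe_accuracy=probe["accuracy"],
                      probe_macro_f1=probe["macro_f1"],
                      presence_metrics=pres,
                      robustness_curve=curve, fold_id=fold_id)
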