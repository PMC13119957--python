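"""YAML run configuration with strict schema validation.

Unknown keys anywhere in the file are errors - this protects against
silently misspelled loss weights or dropout rates.  Every block is
optional; omitted values fall back to the package defaults (which follow
the published training constants: Adam lr 1e-3, batch 32, tau=0.5,
lambda_rec=1.0, lambda_con=0.5, momentum m=0.996, seed 42).
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .dropout import DropoutPolicy
from .model import EncoderSpec
from .objectives import LossWeights
from .synthetic import SyntheticConfig, default_config
from .training import TrainConfig

__all__ = ["ConfigError", "load_config", "build_synthetic_config",
           "build_train_config", "build_encoder_spec", "echo_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


_SCHEMA: dict = {
    "seed": int,
    "output_dir": str,
    "dataset": {
        "manifests": list,
        "synthetic": {
            "n_subjects": int, "n_states": int, "duration_s": float,
            "rate": float, "stay_prob": float, "noise_sd": float,
            "seed": int,
        },
        "window_s": float, "overlap": float, "normalize": bool,
    },
    "model": {
        "kernels": list, "channels": list, "proj_dim": int,
        "attn_hidden": int, "decoder_hidden": int,
    },
    "training": {
        "learning_rate": float, "batch_size": int,
        "epochs_phase1": int, "epochs_phase2": int, "epochs_phase3": int,
        "ablation": str, "phases": list, "pretrain_modality": str,
        "use_momentum_target": bool,
        "loss_weights": {
            "lambda_rec": float, "lambda_con": float, "lambda_pres": float,
            "tau": float, "momentum": float,
        },
        "dropout": {"rate": float, "fill": str, "seed": int},
    },
    "evaluation": {
        "rates": list, "n_repeats": int, "test_subject": str,
        "detection_fill": str,
    },
}


def _validate(node, schema, path="") -> None:
    if not isinstance(node, dict):
        raise ConfigError(f"expected a mapping at '{path or '<root>'}'")
    for key, value in node.items():
        if key not in schema:
            raise ConfigError(f"unknown config key: '{path}{key}'")
        expected = schema[key]
        if isinstance(expected, dict):
            _validate(value, expected, path=f"{path}{key}.")
        elif expected is float:
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"'{path}{key}' must be a number")
        elif expected is int:
            if not isinstance(value, int) or isinstance(value, bool):
                raise ConfigError(f"'{path}{key}' must be an integer")
        elif not isinstance(value, expected):
            raise ConfigError(
                f"'{path}{key}' must be of type {expected.__name__}")


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run configuration."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    _validate(raw, _SCHEMA)
    return raw


def build_synthetic_config(cfg: dict) -> SyntheticConfig:
    d = cfg.get("dataset", {}).get("synthetic", {}) or {}
    kwargs = {k: d[k] for k in ("n_subjects", "n_states", "duration_s",
                                "rate", "stay_prob", "noise_sd", "seed")
              if k in d}
    kwargs.setdefault("seed", cfg.get("seed", 42))
    return default_config(**kwargs)


def build_encoder_spec(cfg: dict) -> EncoderSpec:
    d = cfg.get("model", {}) or {}
    kwargs = {}
    if "kernels" in d:
        kwargs["kernels"] = tuple(d["kernels"])
    if "channels" in d:
        kwargs["channels"] = tuple(d["channels"])
    for k in ("proj_dim", "attn_hidden", "decoder_hidden"):
        if k in d:
            kwargs[k] = d[k]
    return EncoderSpec(**kwargs)


def build_train_config(cfg: dict) -> TrainConfig:
    d = cfg.get("training", {}) or {}
    lw = d.get("loss_weights", {}) or {}
    dp = d.get("dropout", {}) or {}
    kwargs = {k: d[k] for k in ("learning_rate", "batch_size",
                                "epochs_phase1", "epochs_phase2",
                                "epochs_phase3", "ablation",
                                "pretrain_modality", "use_momentum_target")
              if k in d}
    if "phases" in d:
        kwargs["phases"] = tuple(int(p) for p in d["phases"])
    kwargs["seed"] = cfg.get("seed", 42)
    kwargs["loss_weights"] = LossWeights(**lw)
    kwargs["dropout"] = DropoutPolicy(**dp)
    kwargs["encoder_spec"] = build_encoder_spec(cfg)
    return TrainConfig(**kwargs)


def echo_config(cfg: dict, out_dir: str | Path) -> Path:
    """Write the effective configuration next to the run's artifacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "effective_config.yaml"
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)
    return path
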