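"""Checkpoint archive: update-rule weights plus the config that made them."""

from __future__ import annotations

import json
from typing import Optional

import numpy as np

from .config import ModelConfig, TrainConfig
from .core import PARAM_FIELDS, UpdateRuleParams

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(
    path,
    params: UpdateRuleParams,
    model_config: ModelConfig,
    train_config: Optional[TrainConfig] = None,
) -> None:
    """Write weights and full configuration to a single .npz archive."""
    meta = {"model": model_config.to_dict()}
    if train_config is not None:
        meta["train"] = train_config.to_dict()
    arrays = {f: getattr(params, f) for f in PARAM_FIELDS}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[UpdateRuleParams, ModelConfig, Optional[TrainConfig]]:
    with np.load(path) as archive:
        meta = json.loads(archive["meta"].tobytes().decode())
        params = UpdateRuleParams(**{f: archive[f].astype(np.float32) for f in PARAM_FIELDS})
    model_config = ModelConfig.from_dict(meta["model"])
    train_config = TrainConfig.from_dict(meta["train"]) if "train" in meta else None
    return params, model_config, train_config
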