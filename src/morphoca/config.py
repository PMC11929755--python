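"""Model and training configuration.

Defaults describe the full-scale model: a 16-channel cell state (RGBA +
12 hidden channels) plus 2 read-only environment channels, an update
network of two hidden layers (100 and 200 units) and 16 output units,
stochastic cell firing at rate 0.5, an alive threshold of 0.1 on the
3x3 alpha max-pool, a 60-iteration developmental period and a
100-iteration evaluation horizon.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import yaml

N_MODEL_CHANNELS = 16
N_ENV_CHANNELS = 2


@dataclass
class ModelConfig:
    """Architecture and rollout constants of the cellular model."""

    height: int = 56
    width: int = 56
    n_model_channels: int = N_MODEL_CHANNELS
    n_env_channels: int = N_ENV_CHANNELS
    hidden1: int = 100
    hidden2: int = 200
    fire_rate: float = 0.5
    alive_threshold: float = 0.1
    # maternal-gradient geometry
    organizer_offset: float = 0.9
    decay_radius_frac: float = 0.6
    # developmental time axis (iterations)
    developmental_period: int = 60
    evaluation_iterations: int = 100
    # analysis phase windows, inclusive iteration ranges
    early_window: tuple[int, int] = (0, 9)
    mid_window: tuple[int, int] = (11, 30)
    late_window: tuple[int, int] = (31, 60)
    # window used to rank "late active" units in knockout analysis
    late_active_window: tuple[int, int] = (30, 60)

    @property
    def n_channels(self) -> int:
        return self.n_model_channels + self.n_env_channels

    @property
    def perception_size(self) -> int:
        # identity + x-gradient + y-gradient kernels over all channels
        return 3 * self.n_channels

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("early_window", "mid_window", "late_window", "late_active_window"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TrainConfig:
    """Sample-pool training hyperparameters.

    The pool makes the target an attractor: rollout outcomes are written
    back and reused as start states, so the rule learns both to grow the
    pattern from a seed and to maintain it. ``angle_max`` controls the
    orientation distribution of the maternal environment: each pool slot
    carries one angle drawn uniformly from [0, angle_max), resampled when
    the slot is reset to a seed.
    """

    n_steps: int = 8000
    pool_capacity: int = 1024
    batch_size: int = 8
    iters_min: int = 64
    iters_max: int = 96
    learning_rate: float = 2e-3
    lr_decay_frac: float = 0.7      # step fraction at which lr drops 10x
    lr_decay_factor: float = 0.1
    reseed_worst: int = 1           # worst-of-batch slots reset to seed
    damage_count: int = 3           # batch members damaged per step
    damage_warmup: int = 1000       # steps before damage begins
    damage_radius_frac: float = 0.25
    angle_max: float = 2.0 * math.pi
    seed: int = 0
    evaluation_iterations: int = 100
    grad_norm_eps: float = 1e-8

    def __post_init__(self) -> None:
        if not (1 <= self.iters_min <= self.iters_max <= 200):
            raise ValueError("iters_per_step range must lie within [1, 200]")
        if self.batch_size > self.pool_capacity:
            raise ValueError("batch_size must not exceed pool_capacity")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


def load_config(path) -> tuple[ModelConfig, TrainConfig]:
    """Read a YAML file with optional ``model:`` and ``train:`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model = ModelConfig.from_dict(raw.get("model", {}))
    train = TrainConfig.from_dict(raw.get("train", {}))
    return model, train


def save_config(path, model: ModelConfig, train: Optional[TrainConfig] = None) -> None:
    payload = {"model": model.to_dict()}
    if train is not None:
        payload["train"] = train.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
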