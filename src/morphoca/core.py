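"""Cellular substrate: state, perception, learned update rule, rollout.

Each cell carries 16 model channels (RGBA + 12 hidden) and reads, but can
never write, 2 environment channels holding the maternal gradients. At
every iteration each cell builds a 54-value perception vector (identity,
x-gradient and y-gradient responses of a fixed 3x3 kernel bank over all
18 channels), feeds it through a fully connected network
54 -> 100 -> 200 -> 16 (ReLU after each hidden layer), and adds the
16-channel output as a residual update. Updates fire stochastically and
independently per cell, and cells whose 3x3 alpha max-pool falls below
the alive threshold either before or after the update have all model
channels zeroed (cell death / empty space).

Perturbation hooks can clamp chosen hidden-unit activations before they
feed the next layer, implementing knockout (clamp to zero at all pixels)
and constitutive activation (clamp to a level at alive pixels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import ModelConfig

__all__ = [
    "SOBEL_X",
    "SOBEL_Y",
    "UpdateRuleParams",
    "Hook",
    "knockout_hook",
    "constitutive_hook",
    "Trajectory",
    "seed_grid",
    "alive_mask",
    "count_living",
    "perceive",
    "update_step",
    "run_development",
    "render_rgba",
]

# Fixed perception kernels (parent-model convention), applied as
# cross-correlations with zero padding. The 1/8 factor normalises the
# Sobel responses to unit gradient on a unit ramp.
SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]], dtype=np.float32) / 8.0
SOBEL_Y = SOBEL_X.T.copy()

ALPHA = 3  # channel index of alpha within the model channels


def _shift_accumulate(field: np.ndarray, kernel: np.ndarray, out: np.ndarray) -> None:
    """Accumulate the 3x3 cross-correlation of `field` into `out` (zero pad).

    `field` has shape (..., H, W, C); kernel is (3, 3).
    """
    h, w = field.shape[-3], field.shape[-2]
    pad = [(0, 0)] * field.ndim
    pad[-3] = pad[-2] = (1, 1)
    padded = np.pad(field, pad)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            k = kernel[dr + 1, dc + 1]
            if k != 0.0:
                out += k * padded[..., 1 + dr : h + 1 + dr, 1 + dc : w + 1 + dc, :]


def conv3(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """3x3 cross-correlation with zero padding, channel-wise."""
    out = np.zeros_like(field)
    _shift_accumulate(field, np.asarray(kernel, dtype=field.dtype), out)
    return out


def _maxpool3(alpha: np.ndarray) -> np.ndarray:
    """3x3 max filter with zero padding; alpha has shape (..., H, W)."""
    h, w = alpha.shape[-2], alpha.shape[-1]
    pad = [(0, 0)] * alpha.ndim
    pad[-2] = pad[-1] = (1, 1)
    padded = np.pad(alpha, pad)
    out = np.full_like(alpha, -np.inf)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            np.maximum(out, padded[..., 1 + dr : h + 1 + dr, 1 + dc : w + 1 + dc], out=out)
    return out


@dataclass
class UpdateRuleParams:
    """Weights of the update network — the model's 'genome'.

    Layer shapes are perception(3*C) -> hidden1 -> hidden2 -> n_model_channels.
    The output layer is zero-initialised so an untrained rule is the zero
    map, which keeps early training stable (residual updates start as
    no-ops).
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    w3: np.ndarray
    b3: np.ndarray

    @classmethod
    def initialise(cls, config: ModelConfig, rng: np.random.Generator) -> "UpdateRuleParams":
        p, h1, h2, out = (
            config.perception_size,
            config.hidden1,
            config.hidden2,
            config.n_model_channels,
        )
        w1 = rng.normal(0.0, 1.0 / np.sqrt(p), size=(p, h1)).astype(np.float32)
        w2 = rng.normal(0.0, 1.0 / np.sqrt(h1), size=(h1, h2)).astype(np.float32)
        return cls(
            w1=w1,
            b1=np.zeros(h1, dtype=np.float32),
            w2=w2,
            b2=np.zeros(h2, dtype=np.float32),
            w3=np.zeros((h2, out), dtype=np.float32),
            b3=np.zeros(out, dtype=np.float32),
        )

    def copy(self) -> "UpdateRuleParams":
        return UpdateRuleParams(*(getattr(self, f).copy() for f in PARAM_FIELDS))

    @property
    def layer_sizes(self) -> tuple[int, int, int, int]:
        return (self.w1.shape[0], self.w1.shape[1], self.w2.shape[1], self.w3.shape[1])


PARAM_FIELDS = ("w1", "b1", "w2", "b2", "w3", "b3")


@dataclass(frozen=True)
class Hook:
    """Clamp of hidden-unit activations, applied before they feed forward.

    mode "zero" fixes the units' activity at 0; mode "set" fixes it at
    ``level``. With ``alive_only`` the clamp applies only at pixels alive
    in the pre-update state (3x3 alpha max-pool above threshold).
    """

    layer: int
    units: tuple[int, ...]
    mode: str = "zero"
    level: float = 0.0
    alive_only: bool = False

    def __post_init__(self):
        if self.layer not in (1, 2):
            raise ValueError(f"hook layer must be 1 or 2, got {self.layer}")
        if self.mode not in ("zero", "set"):
            raise ValueError(f"unknown hook mode {self.mode!r}")
        object.__setattr__(self, "units", tuple(int(u) for u in self.units))


def knockout_hook(layer: int, units: Sequence[int]) -> Hook:
    """Loss-of-function clamp: activity fixed at 0 for all pixels."""
    return Hook(layer=layer, units=tuple(units), mode="zero", alive_only=False)


def constitutive_hook(layer: int, units: Sequence[int], level: float = 0.5) -> Hook:
    """Gain-of-function clamp: activity fixed at `level` where cells are alive."""
    return Hook(layer=layer, units=tuple(units), mode="set", level=level, alive_only=True)


def _check_hooks(hooks: Sequence[Hook], config: ModelConfig) -> None:
    sizes = {1: config.hidden1, 2: config.hidden2}
    for hook in hooks:
        n = sizes[hook.layer]
        for u in hook.units:
            if not (0 <= u < n):
                raise IndexError(f"hook unit {u} out of range for layer {hook.layer} ({n} units)")


def _apply_hooks(
    h: np.ndarray, layer: int, hooks: Sequence[Hook], alive: Optional[np.ndarray]
) -> np.ndarray:
    """Apply clamps in place to an activation field (..., H, W, U)."""
    for hook in hooks:
        if hook.layer != layer:
            continue
        idx = list(hook.units)
        value = 0.0 if hook.mode == "zero" else hook.level
        if hook.alive_only:
            if alive is None:
                raise ValueError("alive mask required for alive_only hook")
            region = alive[..., None]
            sub = h[..., idx]
            h[..., idx] = np.where(region, value, sub)
        else:
            h[..., idx] = value
    return h


@dataclass
class Trajectory:
    """Recorded developmental rollout.

    ``states`` stacks the grid at iterations 0..T. When activation
    recording is on, ``h1_record[t]`` / ``h2_record[t]`` hold the hidden
    activations computed from ``states[t]`` (for t < T these are the
    activations that produced the update t -> t+1; the final entry comes
    from one extra evaluation of the last state, with any hooks still
    applied).
    """

    states: np.ndarray  # (T+1, H, W, 16)
    alive_counts: np.ndarray  # (T+1,)
    h1_record: Optional[np.ndarray] = None  # (T+1, H, W, hidden1)
    h2_record: Optional[np.ndarray] = None  # (T+1, H, W, hidden2)

    @property
    def n_iterations(self) -> int:
        return self.states.shape[0] - 1

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def seed_grid(height: int, width: int, config: Optional[ModelConfig] = None) -> np.ndarray:
    """A zero grid with one seed cell at the centre.

    The seed has alpha and all hidden channels set to 1 and RGB at 0.
    """
    if height < 3 or width < 3:
        raise ValueError("grid must be at least 3x3")
    n_ch = (config or ModelConfig()).n_model_channels
    grid = np.zeros((height, width, n_ch), dtype=np.float32)
    grid[height // 2, width // 2, ALPHA:] = 1.0
    return grid


def alive_mask(grid: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Boolean (..., H, W) mask: 3x3 alpha max-pool strictly above threshold.

    This is the masking notion (a dead cell adjacent to a mature cell
    counts as alive so growth can spread into it); see `count_living`
    for the cell-census notion.
    """
    return _maxpool3(grid[..., ALPHA]) > threshold


def count_living(grid: np.ndarray, threshold: float = 0.1) -> int:
    """Number of cells whose own alpha exceeds the threshold."""
    return int(np.count_nonzero(grid[..., ALPHA] > threshold))


def perceive(grid: np.ndarray, env: np.ndarray) -> np.ndarray:
    """Perception field (..., H, W, 3*(Cm+Ce)).

    Blocks are [identity | x-gradient | y-gradient] of the concatenated
    model + environment channels, with zero-padded borders.
    """
    if grid.shape[:-1] != env.shape[:-1]:
        raise ValueError(
            f"grid {grid.shape[:-1]} and environment {env.shape[:-1]} sizes differ"
        )
    full = np.concatenate([grid, env.astype(grid.dtype, copy=False)], axis=-1)
    return np.concatenate([full, conv3(full, SOBEL_X), conv3(full, SOBEL_Y)], axis=-1)


def _forward_network(
    perception: np.ndarray,
    params: UpdateRuleParams,
    hooks: Sequence[Hook] = (),
    alive: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the update network at every pixel; returns (ds, h1, h2) fields."""
    h1 = np.maximum(perception @ params.w1 + params.b1, 0.0)
    if hooks:
        h1 = _apply_hooks(h1, 1, hooks, alive)
    h2 = np.maximum(h1 @ params.w2 + params.b2, 0.0)
    if hooks:
        h2 = _apply_hooks(h2, 2, hooks, alive)
    ds = h2 @ params.w3 + params.b3
    return ds, h1, h2


def update_step(
    grid: np.ndarray,
    env: np.ndarray,
    params: UpdateRuleParams,
    fire_rate: float = 0.5,
    rng: Optional[np.random.Generator] = None,
    hooks: Sequence[Hook] = (),
    config: Optional[ModelConfig] = None,
    return_hidden: bool = False,
):
    """One stochastic asynchronous update of the whole grid.

    Every cell computes its residual update from its perception vector;
    an independent Bernoulli(fire_rate) draw decides which cells apply
    it; cells not alive in both the pre- and post-update alpha max-pool
    have all model channels zeroed. Environment channels are read-only.
    """
    if not (0.0 <= fire_rate <= 1.0):
        raise ValueError(f"fire_rate must be in [0, 1], got {fire_rate}")
    config = config or ModelConfig()
    if hooks:
        _check_hooks(hooks, config)
    rng = rng or np.random.default_rng()

    pre_alive = alive_mask(grid, config.alive_threshold)
    ds, h1, h2 = _forward_network(perceive(grid, env), params, hooks, pre_alive)
    fire = rng.random(grid.shape[:-1], dtype=np.float32) < fire_rate
    updated = grid + ds * fire[..., None].astype(grid.dtype)
    life = pre_alive & alive_mask(updated, config.alive_threshold)
    updated *= life[..., None].astype(grid.dtype)
    if return_hidden:
        return updated, h1, h2
    return updated


def run_development(
    seed: np.ndarray,
    env: np.ndarray,
    params: UpdateRuleParams,
    n_iter: int,
    record_activations: bool = False,
    hooks: Sequence[Hook] = (),
    fire_rate: float = 0.5,
    rng: Optional[np.random.Generator] = None,
    config: Optional[ModelConfig] = None,
) -> Trajectory:
    """Roll the update rule for ``n_iter`` iterations, recording the path.

    Deterministic for a given `rng` seed. With ``record_activations``
    the full hidden-activation fields of both layers are stored for
    every iteration (see `Trajectory`).
    """
    if n_iter < 0:
        raise ValueError("n_iter must be nonnegative")
    config = config or ModelConfig()
    if hooks:
        _check_hooks(hooks, config)
    rng = rng or np.random.default_rng()

    states = np.empty((n_iter + 1,) + seed.shape, dtype=np.float32)
    states[0] = seed
    counts = np.empty(n_iter + 1, dtype=np.int64)
    counts[0] = count_living(seed, config.alive_threshold)
    h1_rec = h2_rec = None
    if record_activations:
        h, w = seed.shape[:2]
        h1_rec = np.empty((n_iter + 1, h, w, params.w1.shape[1]), dtype=np.float32)
        h2_rec = np.empty((n_iter + 1, h, w, params.w2.shape[1]), dtype=np.float32)

    grid = states[0]
    for t in range(n_iter):
        grid, h1, h2 = update_step(
            grid, env, params, fire_rate, rng, hooks, config, return_hidden=True
        )
        if record_activations:
            h1_rec[t] = h1
            h2_rec[t] = h2
        states[t + 1] = grid
        counts[t + 1] = count_living(grid, config.alive_threshold)
    if record_activations:
        # activations of the final state (not consumed by any update)
        alive = alive_mask(grid, config.alive_threshold)
        _, h1, h2 = _forward_network(perceive(grid, env), params, hooks, alive)
        h1_rec[n_iter] = h1
        h2_rec[n_iter] = h2
    return Trajectory(states=states, alive_counts=counts, h1_record=h1_rec, h2_record=h2_rec)


def render_rgba(grid: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Visible RGBA image of a grid: channels clipped to [0,1], cells whose
    own alpha is at or below the threshold rendered fully transparent."""
    rgba = np.clip(grid[..., :4], 0.0, 1.0)
    visible = grid[..., ALPHA] > threshold
    return rgba * visible[..., None].astype(rgba.dtype)
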