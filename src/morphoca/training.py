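"""Sample-pool training of the update rule by backpropagation through time.

Training makes the target pattern an attractor of development: each step
draws a batch of start states from a persistent pool (initially all seed
grids), replaces the worst batch member with a fresh seed, optionally
damages a few members, rolls the rule out for a random number of
iterations, backpropagates the pixel loss through the whole rollout, and
writes the outcomes back to the pool. Because later steps start from
previous outcomes, the rule learns both to grow the pattern and to
maintain (and with damage enabled, regenerate) it.

Each pool slot carries its own environment orientation, drawn uniformly
and resampled on reseed, so the rule is trained to read the
anterior-posterior axis from the maternal gradients rather than from the
grid axes.

Gradients of the update network are derived by hand (the rollout is a
chain of residual updates, fixed convolutions and dense layers; firing
and alive masks are treated as constants), per-layer normalised to unit
norm, and applied with Adam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import ModelConfig, TrainConfig
from .core import (
    ALPHA,
    PARAM_FIELDS,
    SOBEL_X,
    SOBEL_Y,
    Hook,
    UpdateRuleParams,
    conv3,
    perceive,
    render_rgba,
    seed_grid,
    update_step,
)
from .environment import make_environment, rotate_field

__all__ = ["loss", "SamplePool", "train", "retrain", "evaluate", "EvalResult"]


def loss(grid: np.ndarray, target: np.ndarray) -> float:
    """Sum of squared differences between the rendered grid and the target.

    Both sides are premultiplied RGBA; the sum runs over every pixel and
    all four visible channels.
    """
    rendered = render_rgba(grid)
    if rendered.shape != target.shape:
        raise ValueError(f"render shape {rendered.shape} != target shape {target.shape}")
    diff = rendered - target
    return float(np.sum(diff * diff))


# ---------------------------------------------------------------------------
# differentiable rollout


def _maxpool3_batch(alpha: np.ndarray) -> np.ndarray:
    b, h, w = alpha.shape
    padded = np.pad(alpha, ((0, 0), (1, 1), (1, 1)))
    out = np.full_like(alpha, -np.inf)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            np.maximum(out, padded[:, 1 + dr : h + 1 + dr, 1 + dc : w + 1 + dc], out=out)
    return out


def _rollout_grad(
    states: np.ndarray,
    envs: np.ndarray,
    targets: np.ndarray,
    params: UpdateRuleParams,
    n_iter: int,
    fire_rate: float,
    threshold: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Forward + backward through a batched rollout.

    Computation is restricted per iteration to the pre-update alive
    region dilated by one cell: cells further out are zeroed by alive
    masking whatever their update would have been, and cannot influence
    any surviving cell's post-update alpha max-pool, so skipping them
    reproduces the full-grid computation exactly. Returns final states,
    per-sample losses, and parameter gradients of the batch-mean loss.
    """
    b, h, w, n_ch = states.shape
    n_px = h * w
    dtype = params.w1.dtype
    x = states.astype(dtype).copy()
    tape = []
    for _ in range(n_iter):
        pre_alive = _maxpool3_batch(x[..., ALPHA]) > threshold
        # one-cell dilation: needed so surviving cells see the exact
        # post-update alpha of their (doomed but updated) neighbours
        region = _maxpool3_batch(pre_alive.astype(np.float32)) > 0.5
        idx = np.flatnonzero(region.reshape(-1))
        fire = rng.random((b, h, w), dtype=np.float32) < fire_rate
        if idx.size == 0:
            tape.append(None)
            continue
        perc = perceive(x, envs)
        rows = perc.reshape(b * n_px, -1)[idx]
        h1 = np.maximum(rows @ params.w1 + params.b1, 0.0)
        h2 = np.maximum(h1 @ params.w2 + params.b2, 0.0)
        ds = h2 @ params.w3 + params.b3
        fire_rows = fire.reshape(-1)[idx]
        updated = x.copy()
        updated.reshape(b * n_px, n_ch)[idx] += ds * fire_rows[:, None]
        life = pre_alive & (_maxpool3_batch(updated[..., ALPHA]) > threshold)
        x = updated * life[..., None]
        tape.append((idx, rows, h1, h2, fire_rows, life))

    diff = x[..., :4] - targets
    sample_losses = np.sum(diff * diff, axis=(1, 2, 3))

    grads = {f: np.zeros_like(getattr(params, f)) for f in PARAM_FIELDS}
    g = np.zeros_like(x)
    g[..., :4] = (2.0 / b) * diff
    flip_x = np.flip(SOBEL_X).copy()
    flip_y = np.flip(SOBEL_Y).copy()
    for entry in reversed(tape):
        if entry is None:
            continue
        idx, rows, h1, h2, fire_rows, life = entry
        g *= life[..., None]
        gd = g.reshape(b * n_px, n_ch)[idx] * fire_rows[:, None]
        grads["w3"] += h2.T @ gd
        grads["b3"] += gd.sum(axis=0)
        gh2 = (gd @ params.w3.T) * (h2 > 0)
        grads["w2"] += h1.T @ gh2
        grads["b2"] += gh2.sum(axis=0)
        gh1 = (gh2 @ params.w2.T) * (h1 > 0)
        grads["w1"] += rows.T @ gh1
        grads["b1"] += gh1.sum(axis=0)
        gp_rows = gh1 @ params.w1.T
        gp = np.zeros((b * n_px, gp_rows.shape[1]), dtype=dtype)
        gp[idx] = gp_rows
        gp = gp.reshape(b, h, w, -1)
        # adjoint of the fixed-kernel perception, model channels only
        # (environment gradients are discarded: cells cannot write there)
        block = gp.shape[-1] // 3
        g = g + gp[..., :n_ch]
        g += conv3(gp[..., block : block + n_ch], flip_x)
        g += conv3(gp[..., 2 * block : 2 * block + n_ch], flip_y)
    return x, sample_losses, grads


# ---------------------------------------------------------------------------
# pool and optimiser


@dataclass
class SamplePool:
    """Persistent pool of developmental start states.

    Each slot stores a grid state together with its environment angle,
    the environment field at that angle, and the angle-rotated target.
    """

    states: np.ndarray   # (capacity, H, W, 16)
    angles: np.ndarray   # (capacity,)
    envs: np.ndarray     # (capacity, H, W, 2)
    targets: np.ndarray  # (capacity, H, W, 4)

    @property
    def capacity(self) -> int:
        return self.states.shape[0]

    @classmethod
    def initialise(
        cls,
        capacity: int,
        target: np.ndarray,
        model_config: ModelConfig,
        rng: np.random.Generator,
        angle_max: float,
    ) -> "SamplePool":
        h, w = target.shape[:2]
        seed = seed_grid(h, w, model_config)
        states = np.broadcast_to(seed, (capacity,) + seed.shape).copy()
        angles = rng.uniform(0.0, angle_max, size=capacity).astype(np.float64)
        envs = np.empty((capacity, h, w, 2), dtype=np.float32)
        targets = np.empty((capacity, h, w, 4), dtype=np.float32)
        for i in range(capacity):
            envs[i] = make_environment(h, w, angles[i], config=model_config)
            targets[i] = rotate_field(target, angles[i])
        return cls(states=states, angles=angles, envs=envs, targets=targets)

    def reseed(
        self,
        slot: int,
        target: np.ndarray,
        model_config: ModelConfig,
        rng: np.random.Generator,
        angle_max: float,
    ) -> None:
        h, w = self.states.shape[1:3]
        self.states[slot] = seed_grid(h, w, model_config)
        angle = float(rng.uniform(0.0, angle_max))
        self.angles[slot] = angle
        self.envs[slot] = make_environment(h, w, angle, config=model_config)
        self.targets[slot] = rotate_field(target, angle)


class _Adam:
    def __init__(self, params: UpdateRuleParams, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {f: np.zeros_like(getattr(params, f)) for f in PARAM_FIELDS}
        self.v = {f: np.zeros_like(getattr(params, f)) for f in PARAM_FIELDS}
        self.t = 0
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def step(self, params: UpdateRuleParams, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for f in PARAM_FIELDS:
            g = grads[f]
            self.m[f] = b1 * self.m[f] + (1 - b1) * g
            self.v[f] = b2 * self.v[f] + (1 - b2) * g * g
            m_hat = self.m[f] / (1 - b1**self.t)
            v_hat = self.v[f] / (1 - b2**self.t)
            getattr(params, f)[...] -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _damage(state: np.ndarray, radius: float, rng: np.random.Generator) -> None:
    """Zero all model channels inside a random disc (in place)."""
    h, w = state.shape[:2]
    cr = rng.uniform(0, h - 1)
    cc = rng.uniform(0, w - 1)
    rr, cc_grid = np.mgrid[0:h, 0:w]
    mask = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= radius**2
    state[mask] = 0.0


# ---------------------------------------------------------------------------
# public training API


def train(
    params: UpdateRuleParams,
    target: np.ndarray,
    config: TrainConfig,
    model_config: Optional[ModelConfig] = None,
    progress: bool = False,
) -> tuple[UpdateRuleParams, list[float]]:
    """Train the update rule so `target` becomes an attractor of development.

    `target` is a premultiplied RGBA array whose square canvas defines
    the grid size. Returns the trained parameters (the input params are
    not modified) and the per-step batch-mean loss history. Fully
    deterministic given ``config.seed``.
    """
    if target.ndim != 3 or target.shape[-1] != 4 or target.shape[0] != target.shape[1]:
        raise ValueError("target must be a square (S, S, 4) RGBA array")
    model_config = model_config or ModelConfig(height=target.shape[0], width=target.shape[1])
    params = params.copy()
    history: list[float] = []
    if config.n_steps == 0:
        return params, history

    rng = np.random.default_rng(config.seed)
    target = target.astype(np.float32)
    pool = SamplePool.initialise(config.pool_capacity, target, model_config, rng, config.angle_max)
    opt = _Adam(params)
    decay_at = int(math.ceil(config.lr_decay_frac * config.n_steps))
    damage_radius = config.damage_radius_frac * min(target.shape[:2]) / 2.0

    bar = None
    iterator = range(config.n_steps)
    if progress:
        from tqdm import tqdm

        bar = tqdm(iterator, desc="train")
        iterator = bar
    for step in iterator:
        batch_idx = rng.choice(config.pool_capacity, size=config.batch_size, replace=False)
        pre_losses = np.array(
            [loss(pool.states[i], pool.targets[i]) for i in batch_idx]
        )
        order = np.argsort(-pre_losses)  # worst first
        for j in order[: config.reseed_worst]:
            pool.reseed(int(batch_idx[j]), target, model_config, rng, config.angle_max)
        if config.damage_count > 0 and step >= config.damage_warmup:
            for j in order[len(order) - config.damage_count :]:
                _damage(pool.states[batch_idx[j]], damage_radius, rng)

        states = pool.states[batch_idx].copy()
        envs = pool.envs[batch_idx]
        targets = pool.targets[batch_idx]
        n_it = int(rng.integers(config.iters_min, config.iters_max + 1))
        finals, sample_losses, grads = _rollout_grad(
            states,
            envs,
            targets,
            params,
            n_it,
            model_config.fire_rate,
            model_config.alive_threshold,
            rng,
        )
        mean_loss = float(np.mean(sample_losses))
        if not np.isfinite(mean_loss):
            raise RuntimeError(
                f"training diverged at step {step}: loss is not finite "
                "(lower the learning rate or shorten iters_per_step)"
            )
        for f in PARAM_FIELDS:
            g = grads[f]
            grads[f] = g / (np.linalg.norm(g) + config.grad_norm_eps)
        lr = config.learning_rate * (config.lr_decay_factor if step >= decay_at else 1.0)
        opt.step(params, grads, lr)
        pool.states[batch_idx] = finals
        history.append(mean_loss)
        if bar is not None:
            bar.set_postfix(loss=f"{mean_loss:.1f}", refresh=False)
    return params, history


def retrain(
    params: UpdateRuleParams,
    new_target: np.ndarray,
    config: TrainConfig,
    model_config: Optional[ModelConfig] = None,
    progress: bool = False,
) -> tuple[UpdateRuleParams, list[float]]:
    """Continue training an already-trained rule on a new target.

    Transfer learning across morphologies: the loop is identical to
    `train` (so histories are comparable step-for-step with a naive run
    of the same config) but starts from the given parameters instead of
    fresh ones.
    """
    return train(params, new_target, config, model_config, progress)


@dataclass
class EvalResult:
    """Loss statistics over replicate stochastic rollouts."""

    mean: float
    sd: float
    losses: np.ndarray

    def __float__(self) -> float:
        return self.mean


def evaluate(
    params: UpdateRuleParams,
    target: np.ndarray,
    env: np.ndarray,
    n_iter: int = 100,
    n_replicates: int = 8,
    seed: int | Sequence[int] = 0,
    hooks: Sequence[Hook] = (),
    model_config: Optional[ModelConfig] = None,
) -> EvalResult:
    """Mean and sd of the developed-pattern loss over stochastic rollouts.

    Each replicate grows from a fresh seed for ``n_iter`` iterations and
    is scored against the target. ``seed`` may be a single master seed
    or an explicit per-replicate seed list (useful for common-random-
    number comparisons across perturbation arms).
    """
    h, w = target.shape[:2]
    model_config = model_config or ModelConfig(height=h, width=w)
    if np.isscalar(seed):
        seeds = [s.generate_state(1)[0] % (2**31) for s in np.random.SeedSequence(int(seed)).spawn(n_replicates)]
    else:
        seeds = list(seed)[:n_replicates]
    losses = np.empty(len(seeds))
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        grid = seed_grid(h, w, model_config)
        for _ in range(n_iter):
            grid = update_step(
                grid, env, params, model_config.fire_rate, rng, hooks, model_config
            )
        losses[i] = loss(grid, target)
    return EvalResult(mean=float(losses.mean()), sd=float(losses.std(ddof=1)) if len(seeds) > 1 else 0.0, losses=losses)
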