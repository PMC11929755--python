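"""Desk-scale study recipes: small, CPU-friendly training conditions.

The full-scale model (56x56 canvas, pool of 1024, thousands of steps) is
sized for long GPU-class runs. The desk-scale recipe reproduces the same
phenomena — attractor growth, rotation-invariant development, transfer
learning, unit conservation, vestigial structures — on a 32x32 canvas
with a pool of 256, batches of 4 and a few hundred training steps, so a
complete train / retrain / analyse cycle fits on a single CPU core in
minutes. The update-network architecture is unchanged (54 -> 100 -> 200
-> 16); only the canvas and the training schedule shrink.

All randomness flows from one master seed; derived seeds stay below 2^31.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .config import ModelConfig, TrainConfig
from .core import UpdateRuleParams
from .targets import BodyPlanSpec, make_target
from .training import retrain, train

__all__ = [
    "DESK_SIZE",
    "desk_model_config",
    "desk_train_config",
    "desk_target",
    "train_desk_model",
    "desk_transfer_pair",
    "knockout_class_losses",
]

DESK_SIZE = 32
DESK_STEPS_PRIMARY = 1300  # fresh training on the lizard
DESK_STEPS_TRANSFER = 350  # retraining / naive-comparison runs


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(int(seed)).spawn(n)]


def desk_model_config(size: int = DESK_SIZE) -> ModelConfig:
    return ModelConfig(height=size, width=size)


def desk_train_config(
    seed: int,
    n_steps: int = DESK_STEPS_PRIMARY,
    damage: bool = True,
) -> TrainConfig:
    """Scaled-down schedule; damage (for regeneration training) starts
    after step 700 on the primary run and is off for transfer runs."""
    return TrainConfig(
        n_steps=n_steps,
        pool_capacity=256,
        batch_size=4,
        iters_min=30,
        iters_max=50,
        learning_rate=2e-3,
        lr_decay_frac=0.8,
        reseed_worst=1,
        damage_count=1 if damage else 0,
        damage_warmup=700,
        seed=int(seed) % (2**31),
    )


def desk_target(variant: str, size: int = DESK_SIZE) -> np.ndarray:
    return make_target(BodyPlanSpec(variant=variant, size=size))


def train_desk_model(
    variant: str,
    seed: int,
    n_steps: int = DESK_STEPS_PRIMARY,
    damage: bool = True,
    from_params: Optional[UpdateRuleParams] = None,
    progress: bool = False,
) -> tuple[UpdateRuleParams, list[float], ModelConfig]:
    """Train (or, given ``from_params``, retrain) a desk-scale model."""
    config = desk_model_config()
    target = desk_target(variant)
    tc = desk_train_config(seed, n_steps=n_steps, damage=damage)
    if from_params is None:
        init_seed, = _child_seeds(seed, 1)
        params = UpdateRuleParams.initialise(config, np.random.default_rng(init_seed))
        params, history = train(params, target, tc, config, progress=progress)
    else:
        params, history = retrain(from_params, target, tc, config, progress=progress)
    return params, history, config


def desk_transfer_pair(
    lizard_params: UpdateRuleParams, seed: int, variant: str = "legless",
    progress: bool = False,
) -> tuple[tuple[UpdateRuleParams, list[float]], tuple[UpdateRuleParams, list[float]]]:
    """Retrained-vs-naive comparison on a new morphology.

    Both runs use the same schedule and master seed, so their loss
    histories are comparable step for step; they differ only in the
    initial parameters (trained lizard rule vs fresh initialisation).
    """
    retrained, hist_r, _ = train_desk_model(
        variant, seed, n_steps=DESK_STEPS_TRANSFER, damage=False,
        from_params=lizard_params, progress=progress,
    )
    naive, hist_n, _ = train_desk_model(
        variant, seed, n_steps=DESK_STEPS_TRANSFER, damage=False, progress=progress,
    )
    return (retrained, hist_r), (naive, hist_n)


def knockout_class_losses(
    params: UpdateRuleParams,
    config: ModelConfig,
    seed: int,
    k: int = 20,
    layer: int = 1,
    n_replicates: int = 4,
    variant: str = "lizard",
    env: Optional[np.ndarray] = None,
) -> dict[str, float]:
    """Developed-pattern loss after silencing each unit class (plus baseline).

    Classifies units from a standardised recorded rollout, then scores
    knockout of the k early-active, late-active and inactive units with
    common random numbers across arms.
    """
    from .core import knockout_hook
    from .environment import make_environment
    from .perturbation import classify_units
    from .conservation import profile_from_params
    from .training import evaluate

    h, w = config.height, config.width
    if env is None:
        env = make_environment(h, w, 0.0, config=config)
    target = make_target(BodyPlanSpec(variant=variant, size=h))
    profile_seed, eval_seed = _child_seeds(seed, 2)
    profile = profile_from_params(
        params, layer, n_iter=config.developmental_period,
        seed=profile_seed, config=config, env=env,
    )
    classes = classify_units(profile, k=k)
    replicate_seeds = _child_seeds(eval_seed, n_replicates)
    out = {}
    arms = {
        "unperturbed": [],
        "early": classes.early_active,
        "late": classes.late_active,
        "inactive": classes.inactive,
    }
    for name, units in arms.items():
        hooks = [knockout_hook(layer, units)] if units else []
        res = evaluate(
            params, target, env,
            n_iter=config.evaluation_iterations, n_replicates=n_replicates,
            seed=replicate_seeds, hooks=hooks, model_config=config,
        )
        out[name] = res.mean
    return out
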