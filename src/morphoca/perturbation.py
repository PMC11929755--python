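"""Hidden-unit activity profiling and in-silico perturbation experiments.

The analysis treats hidden units of the update network like candidate
regulatory factors. Summing a unit's (post-ReLU) activation over every
grid pixel at each iteration gives its temporal activity profile; units
are classified as early active (most active over the early window),
late active (most active over the late window, excluding early units)
or inactive (least active over the early window). Knockout fixes a
unit's activity at zero for all pixels throughout development
(loss-of-function); constitutive activation fixes it at a level — 0.5
by default — at alive pixels (gain-of-function). Sequentially knocking
out growing prefixes of each class and scoring the developed pattern
quantifies how much morphology depends on each class of unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import ModelConfig
from .core import (
    Hook,
    Trajectory,
    UpdateRuleParams,
    constitutive_hook,
    knockout_hook,
    run_development,
    seed_grid,
)
from .training import EvalResult, evaluate

__all__ = [
    "ActivityProfile",
    "UnitClassification",
    "activity_profile",
    "classify_units",
    "spatial_activity_map",
    "knockout_run",
    "constitutive_run",
    "sequential_knockout_curve",
]


@dataclass
class ActivityProfile:
    """Per-unit, per-iteration summed activation matrix.

    ``matrix[u, t]`` is unit u's activation summed over all grid pixels
    at iteration t (post-nonlinearity, hence nonnegative).
    """

    matrix: np.ndarray  # (n_units, T+1)
    layer: int
    early_window: tuple[int, int] = (0, 9)
    mid_window: tuple[int, int] = (11, 30)
    late_window: tuple[int, int] = (31, 60)
    late_active_window: tuple[int, int] = (30, 60)

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.matrix.shape[1] - 1

    def window_scores(self, window) -> np.ndarray:
        """Summed activity per unit over an inclusive (start, stop) window
        or an explicit iteration collection."""
        if isinstance(window, tuple) and len(window) == 2:
            lo, hi = window
            cols = range(int(lo), int(hi) + 1)
        else:
            cols = sorted(int(t) for t in window)
        cols = [t for t in cols]
        if not cols:
            raise ValueError("empty iteration window")
        if cols[0] < 0 or cols[-1] > self.n_iterations:
            raise ValueError(
                f"window {cols[0]}..{cols[-1]} outside recorded range 0..{self.n_iterations}"
            )
        return self.matrix[:, cols].sum(axis=1)


@dataclass
class UnitClassification:
    """Disjoint early-active / late-active / inactive unit lists."""

    early_active: list[int]
    late_active: list[int]
    inactive: list[int]
    k: int
    layer: int


def _get_record(trajectory: Trajectory, layer: int) -> np.ndarray:
    if layer not in (1, 2):
        raise ValueError(f"layer must be 1 or 2, got {layer}")
    rec = trajectory.h1_record if layer == 1 else trajectory.h2_record
    if rec is None:
        raise ValueError(
            f"trajectory has no layer-{layer} activation record; "
            "run development with record_activations=True"
        )
    return rec


def activity_profile(
    trajectory: Trajectory, layer: int, config: Optional[ModelConfig] = None
) -> ActivityProfile:
    """Temporal activity profile of every hidden unit in a layer."""
    rec = _get_record(trajectory, layer)  # (T+1, H, W, U)
    matrix = rec.sum(axis=(1, 2)).T.astype(np.float64)  # (U, T+1)
    kwargs = {}
    if config is not None:
        kwargs = dict(
            early_window=config.early_window,
            mid_window=config.mid_window,
            late_window=config.late_window,
            late_active_window=config.late_active_window,
        )
    return ActivityProfile(matrix=matrix, layer=layer, **kwargs)


def _topk_stable(scores: np.ndarray, k: int, largest: bool = True) -> list[int]:
    """Indices of the k largest (or smallest) scores, ties to lower index."""
    order = np.argsort(-scores if largest else scores, kind="stable")
    return [int(i) for i in order[:k]]


def classify_units(profile: ActivityProfile, k: int = 20) -> UnitClassification:
    """Rank units into early-active, late-active and inactive sets.

    Early = top-k by summed activity over the early window; late = top-k
    over the late-activity window after excluding early members
    (refilled to k); inactive = bottom-k over the early window. Ties
    break to the lower unit index.
    """
    n = profile.n_units
    if k > n:
        raise ValueError(f"k={k} exceeds {n} available units")
    early_scores = profile.window_scores(profile.early_window)
    late_scores = profile.window_scores(profile.late_active_window)
    early = _topk_stable(early_scores, k)
    early_set = set(early)
    late_order = _topk_stable(late_scores, n)
    late = [u for u in late_order if u not in early_set][:k]
    if len(late) < k:
        raise ValueError(f"cannot select {k} late-active units disjoint from early set")
    inactive = _topk_stable(early_scores, k, largest=False)
    return UnitClassification(
        early_active=early, late_active=late, inactive=inactive, k=k, layer=profile.layer
    )


def spatial_activity_map(
    trajectory: Trajectory, layer: int, unit: int, iteration: int
) -> np.ndarray:
    """The unit's raw activation image at one iteration."""
    rec = _get_record(trajectory, layer)
    if not (0 <= unit < rec.shape[-1]):
        raise IndexError(f"unit {unit} out of range for layer {layer}")
    if not (0 <= iteration < rec.shape[0]):
        raise IndexError(f"iteration {iteration} outside recorded range")
    return rec[iteration, :, :, unit]


def _perturbed_run(
    params: UpdateRuleParams,
    env: np.ndarray,
    hooks: Sequence[Hook],
    n_iter: int,
    seed: Optional[np.ndarray],
    rng,
    record_activations: bool,
    config: Optional[ModelConfig],
) -> Trajectory:
    h, w = env.shape[:2]
    config = config or ModelConfig(height=h, width=w)
    start = seed if seed is not None else seed_grid(h, w, config)
    return run_development(
        start,
        env,
        params,
        n_iter,
        record_activations=record_activations,
        hooks=hooks,
        fire_rate=config.fire_rate,
        rng=rng,
        config=config,
    )


def knockout_run(
    params: UpdateRuleParams,
    env: np.ndarray,
    layer: int,
    units: Sequence[int],
    n_iter: int,
    seed: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    record_activations: bool = True,
    config: Optional[ModelConfig] = None,
) -> Trajectory:
    """Development with the listed units' activity fixed at zero for all
    pixels throughout the run."""
    hooks = [knockout_hook(layer, units)] if len(units) else []
    return _perturbed_run(params, env, hooks, n_iter, seed, rng, record_activations, config)


def constitutive_run(
    params: UpdateRuleParams,
    env: np.ndarray,
    layer: int,
    units: Sequence[int],
    level: float = 0.5,
    n_iter: int = 100,
    seed: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    record_activations: bool = True,
    config: Optional[ModelConfig] = None,
) -> Trajectory:
    """Development with the listed units' activity fixed at ``level``
    wherever cells are alive, throughout the run."""
    if not np.isfinite(level):
        raise ValueError("activation level must be finite")
    hooks = [constitutive_hook(layer, units, level)] if len(units) else []
    return _perturbed_run(params, env, hooks, n_iter, seed, rng, record_activations, config)


def sequential_knockout_curve(
    params: UpdateRuleParams,
    env: np.ndarray,
    ordered_units: Sequence[int],
    layer: int,
    target: np.ndarray,
    n_iter: int = 100,
    n_replicates: int = 8,
    seed: int = 0,
    config: Optional[ModelConfig] = None,
) -> list[EvalResult]:
    """Loss statistics after knocking out growing prefixes of a unit list.

    Entry j scores rollouts with the first j units knocked out; entry 0
    is the unperturbed loss. All prefixes (and any curves computed with
    the same master seed, e.g. for a control unit class) share the same
    replicate random streams, so differences reflect the knockouts.
    """
    replicate_seeds = [
        s.generate_state(1)[0] % (2**31)
        for s in np.random.SeedSequence(int(seed)).spawn(n_replicates)
    ]
    curve = []
    for j in range(len(ordered_units) + 1):
        hooks = [knockout_hook(layer, ordered_units[:j])] if j else []
        curve.append(
            evaluate(
                params,
                target,
                env,
                n_iter=n_iter,
                n_replicates=n_replicates,
                seed=replicate_seeds,
                hooks=hooks,
                model_config=config,
            )
        )
    return curve
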