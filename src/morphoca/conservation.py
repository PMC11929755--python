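"""Conservation analysis of hidden units across retraining.

After transfer learning to a new morphology, how much of the original
developmental program is reused? Conservation at a developmental time is
the overlap between the top-k most-active unit sets of the original and
retrained models at that time. Under a null in which unit identities are
unrelated, the overlap is hypergeometric with mean k^2 / n_units, which
serves as the chance baseline. The phase table refines this per
developmental phase (early expansion, mid differentiation, late pruning)
and annotates conserved units that are redeployed in a different phase
after retraining ("shifted employment").

The vestigial trajectory quantifies transient ancestral structures: the
summed squared visible-channel difference between each developing state
of the new morphology and the developed reference morphology. A dip in
mid-development signals a structure that is grown and then pruned away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import ModelConfig
from .core import Trajectory, UpdateRuleParams, render_rgba, run_development, seed_grid
from .environment import make_environment
from .perturbation import ActivityProfile, _topk_stable, activity_profile

__all__ = [
    "topk_active_units",
    "conservation_count",
    "conservation_series",
    "chance_conservation",
    "PhaseConservation",
    "phase_conservation_table",
    "vestigial_trajectory",
    "profile_from_params",
]


def topk_active_units(profile: ActivityProfile, window, k: int = 20) -> list[int]:
    """Top-k units by summed activity over an iteration window.

    ``window`` is an inclusive (start, stop) pair, a single iteration,
    or any iterable of iterations. Ties break to the lower unit index.
    """
    if np.isscalar(window):
        window = (int(window), int(window))
    scores = profile.window_scores(window)
    if k > profile.n_units:
        raise ValueError(f"k={k} exceeds {profile.n_units} units")
    return _topk_stable(scores, k)


def _check_pair(a: ActivityProfile, b: ActivityProfile) -> None:
    if a.n_units != b.n_units:
        raise ValueError(
            f"profiles have different unit counts ({a.n_units} vs {b.n_units}); "
            "conservation requires same-architecture models"
        )


def conservation_count(
    profile_original: ActivityProfile,
    profile_retrained: ActivityProfile,
    window,
    k: int = 20,
) -> int:
    """Number of units in both models' top-k most-active sets for a window."""
    _check_pair(profile_original, profile_retrained)
    a = set(topk_active_units(profile_original, window, k))
    b = set(topk_active_units(profile_retrained, window, k))
    return len(a & b)


def chance_conservation(k: int, n_units: int) -> float:
    """Expected overlap of two independent k-subsets of n units (k^2/n)."""
    return k * k / n_units


def conservation_series(
    profile_original: ActivityProfile,
    profile_retrained: ActivityProfile,
    k: int = 20,
    developmental_period: Optional[int] = None,
) -> np.ndarray:
    """Per-iteration conservation counts over the developmental period."""
    _check_pair(profile_original, profile_retrained)
    if developmental_period is None:
        developmental_period = min(
            profile_original.n_iterations, profile_retrained.n_iterations, 60
        )
    return np.array(
        [
            conservation_count(profile_original, profile_retrained, t, k)
            for t in range(developmental_period + 1)
        ],
        dtype=np.int64,
    )


@dataclass
class PhaseConservation:
    """Conservation of one developmental phase's most-active units."""

    phase: str
    window: tuple[int, int]
    top_original: list[int]
    top_retrained: list[int]
    conserved: list[int]        # in both models' top-k for this phase
    shifted: list[int]          # original top-k units redeployed in another phase

    @property
    def n_conserved(self) -> int:
        return len(self.conserved)


def phase_conservation_table(
    profile_original: ActivityProfile,
    profile_retrained: ActivityProfile,
    phases: Optional[dict[str, tuple[int, int]]] = None,
    k: int = 20,
) -> dict[str, PhaseConservation]:
    """Per-phase top-k sets, their overlap, and shifted-employment notes.

    A unit from the original model's top-k of a phase is "conserved"
    if it is in the retrained model's top-k of the same phase, and
    "shifted" if it instead appears in the retrained top-k of a
    different phase only.
    """
    _check_pair(profile_original, profile_retrained)
    if phases is None:
        phases = {
            "early": profile_original.early_window,
            "mid": profile_original.mid_window,
            "late": profile_original.late_window,
        }
    spans = sorted(phases.values())
    for (lo1, hi1), (lo2, _) in zip(spans, spans[1:]):
        if lo2 <= hi1:
            raise ValueError("phase windows must not overlap")

    top_a = {p: topk_active_units(profile_original, w, k) for p, w in phases.items()}
    top_b = {p: topk_active_units(profile_retrained, w, k) for p, w in phases.items()}
    table = {}
    for phase, window in phases.items():
        same = set(top_a[phase]) & set(top_b[phase])
        elsewhere = set().union(*(set(top_b[q]) for q in phases if q != phase)) if len(phases) > 1 else set()
        shifted = (set(top_a[phase]) - same) & elsewhere
        table[phase] = PhaseConservation(
            phase=phase,
            window=tuple(window),
            top_original=top_a[phase],
            top_retrained=top_b[phase],
            conserved=sorted(same),
            shifted=sorted(shifted),
        )
    return table


def vestigial_trajectory(
    trajectory_new: Trajectory, reference_final: np.ndarray
) -> np.ndarray:
    """Squared visible-channel distance to a developed reference, per iteration.

    ``reference_final`` may be a developed grid state (rendered here) or
    an RGBA image. Entry t is the sum over pixels and the four visible
    channels of the squared difference between the rendered developing
    state and the reference.
    """
    if reference_final.shape[-1] == 4:
        ref = np.asarray(reference_final, dtype=np.float32)
    else:
        ref = render_rgba(reference_final)
    if ref.shape[:2] != trajectory_new.states.shape[1:3]:
        raise ValueError(
            f"reference canvas {ref.shape[:2]} != trajectory canvas "
            f"{trajectory_new.states.shape[1:3]}"
        )
    out = np.empty(trajectory_new.states.shape[0], dtype=np.float64)
    for t, state in enumerate(trajectory_new.states):
        diff = render_rgba(state) - ref
        out[t] = float(np.sum(diff * diff))
    return out


def profile_from_params(
    params: UpdateRuleParams,
    layer: int,
    n_iter: int = 60,
    seed: int = 0,
    angle: float = 0.0,
    n_rollouts: int = 1,
    config: Optional[ModelConfig] = None,
    env: Optional[np.ndarray] = None,
) -> ActivityProfile:
    """Activity profile of a model from standardised rollouts.

    Rollouts share the master seed and environment angle so profiles of
    two models differ only through their parameters; optionally the
    profile is averaged over several rollouts.
    """
    config = config or ModelConfig()
    h, w = (env.shape[:2] if env is not None else (config.height, config.width))
    if env is None:
        env = make_environment(h, w, angle, config=config)
    seeds = [
        s.generate_state(1)[0] % (2**31)
        for s in np.random.SeedSequence(int(seed)).spawn(n_rollouts)
    ]
    acc = None
    for s in seeds:
        traj = run_development(
            seed_grid(h, w, config),
            env,
            params,
            n_iter,
            record_activations=True,
            fire_rate=config.fire_rate,
            rng=np.random.default_rng(int(s)),
            config=config,
        )
        prof = activity_profile(traj, layer, config)
        acc = prof.matrix if acc is None else acc + prof.matrix
    prof.matrix = acc / n_rollouts
    return prof
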