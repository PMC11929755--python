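# morphoca

**Environment-conditioned neural cellular automata for morphogenesis, with a
complete in-silico genetics toolkit.**

`morphoca` is for computational and developmental biologists who want a small,
fully inspectable model of development: a lattice of cells that grows a target
body plan from a single seed, guided by maternal morphogen gradients, whose
"genome" (a trainable local update rule) can be profiled, mutated and compared
across "evolutionary" changes of body plan.

## The model

Each cell on an H×W grid carries a state vector **s** ∈ ℝ¹⁶ — four visible
RGBA channels plus 12 hidden channels — and reads, but can never write, two
environment channels **e** ∈ [0,1]² holding radial gradients centred on an
anterior and a posterior organizer (the maternal axis cue). At every iteration
each cell forms a perception vector

p = [ x ; K_x ∗ x ; K_y ∗ x ],  x = (s, e) ∈ ℝ¹⁸,

from fixed 3×3 identity and Sobel kernels over its neighbourhood, then applies
a learned residual update through a fully connected network
54 → 100 → 200 → 16 (ReLU after each hidden layer):

s ← s + f_θ(p) · B,  B ~ Bernoulli(0.5) per cell,

after which any cell whose 3×3 alpha max-pool is ≤ 0.1 before or after the
update has its state zeroed (death / empty space). Training makes a target
image an attractor of these dynamics: rollouts start from a persistent sample
pool of previous outcomes (plus reseeded and damaged members), the summed
squared RGBA error against the (orientation-matched) target is backpropagated
through the whole rollout, and per-layer normalised gradients are applied with
Adam. Because each pool slot carries a random environment orientation, the
grown pattern aligns to the maternal axis rather than to the grid.

On top of the substrate the package implements the interrogation suite:

- **Activity profiling** — per-unit activation summed over the grid at every
  iteration; classification into early-active, late-active and inactive units.
- **Perturbation** — knockout (activity clamped to 0 at all pixels) and
  constitutive activation (clamped to 0.5 at alive pixels), including
  sequential-knockout loss curves.
- **Transfer learning** — retraining a trained rule on a new body plan, with
  step-for-step comparable loss histories against naive training.
- **Conservation analysis** — overlap of top-k most-active unit sets between
  a model and its retrained descendant, per iteration and per developmental
  phase, against the hypergeometric chance level k²/n; plus the vestigial
  trajectory D(t) = ‖render(state_t) − reference‖² that detects transiently
  grown ancestral structures.

Synthetic targets (a lizard with full/small/no legs, a recoloured legless
variant, and a compact spotted disc) are generated by the package itself.

## Worked example

```python
import numpy as np
import morphoca as mc
from morphoca import recipes

# train a 32x32 lizard model (a few minutes on one CPU core)
params, history, config = recipes.train_desk_model("lizard", seed=7)

env = mc.make_environment(32, 32, 0.0, config=config)
target = recipes.desk_target("lizard")
res = mc.evaluate(params, target, env, n_iter=100, n_replicates=4, seed=7,
                  model_config=config)
print(f"step-0 loss {history[0]:.1f} -> developed loss {res.mean:.1f}")

# which hidden units matter most?
losses = recipes.knockout_class_losses(params, config, seed=7, env=env)
for arm, value in losses.items():
    print(f"{arm:>12}: {value:.1f}")
```

Output (seed 7):

```
step-0 loss 203.0 -> developed loss 18.3
unperturbed: 18.9
       early: 595.7
        late: 3229.5
    inactive: 208.5
```

The developed-pattern loss falls below a tenth of its starting value, and
silencing the 20 most-active hidden units (early- or late-classified) is an
order of magnitude more destructive than silencing inactive units. At this
small training scale the late-active knockout can even exceed the
early-active one, because removing the second tier of units leaves growth
unregulated and the pattern overruns the grid — see the known-limitations
section of `docs/methods.md` for why this differs from a fully converged
model. Numbers vary with the seed; the active-vs-inactive gap is stable.

A command-line interface mirrors the library:

```sh
morphoca targets make --variant legless --size 56 --out snake.png
morphoca train --target lizard --out lizard.npz --history loss.csv
morphoca grow --ckpt lizard.npz --angle 1.57 --out grown.png
morphoca perturb --ckpt lizard.npz --layer 1 --mode knockout --units auto-early:20 --out report/
morphoca conserve --ckpt-a lizard.npz --ckpt-b snake.npz --layer 1 --out report/
```

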