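# Methods

## The cellular model

Cells live on a regular H×W grid. Each carries 16 *model channels* — RGBA in
channels 0–3 (channel 3 is alpha, the maturity/visibility signal) plus 12
hidden channels the rule may use freely — and reads two *environment
channels* it can never write. Development starts from a single seed cell at
the grid centre with alpha and all hidden channels at 1 and RGB at 0;
everything else is zero.

One iteration of developmental time:

1. **Perception.** Each cell concatenates its 16 model channels with the 2
   environment channels and applies three fixed 3×3 kernels depthwise —
   identity, Sobel-x and Sobel-y (scaled 1/8), zero-padded — giving a
   54-value perception vector containing its own state and the local
   gradients of every channel.
2. **Update rule.** A fully connected network 54 → 100 → 200 → 16 with ReLU
   after each hidden layer maps perception to a residual state update. The
   output layer starts at exactly zero, so an untrained rule is the identity
   map — training begins from stable dynamics. Hidden layers use Gaussian
   fan-in initialisation.
3. **Stochastic firing.** Each cell applies its update independently with
   probability 0.5 (`fire_rate`), breaking the biologically implausible
   global synchrony of classic cellular automata.
4. **Alive masking.** A cell is considered alive when the 3×3 maximum of the
   alpha channel around it exceeds 0.1 (strictly). Cells alive neither
   before nor after the update have all 16 model channels zeroed. Requiring
   life in *both* the pre- and post-update state keeps an empty world an
   exact fixed point for any parameters (no spontaneous generation off the
   environment gradients) while still letting growth spread one cell per
   iteration from live tissue; we adopt this conjunction as the masking
   rule.

Two distinct "alive" notions coexist deliberately: the max-pool mask above
(masking semantics — a dead cell adjacent to mature tissue counts, so growth
can spread into it) and the cell census used for developmental curves, which
counts cells whose *own* alpha exceeds 0.1 (a fresh seed grid has census 1
but 9 mask-true cells).

Hidden-activation records attach one entry per state: entry *t* holds the
activations computed from state *t* (those that produced update *t* → *t*+1);
the final state gets one extra forward evaluation so profiles span all T+1
iterations.

## Environment

The two environment channels are cosine-tapered radial bumps,
max(0, cos(π·d / 2R)), centred on an anterior and a posterior organizer
placed at the grid centre ± 0.9·min(H,W)/2 along an orientation angle
(counter-clockwise; angle 0 puts the anterior organizer at the top). Default
taper radius R = 0.6·min(H,W)/2. The functional form and extent are free
choices — only the existence of two smooth, bounded, distinguishable
gradients matters — made once for smoothness and compact support. Rotations
of targets use bilinear interpolation with zero fill, except exact array
quarter-turns at multiples of π/2.

## Targets

The synthetic body-plan family is drawn analytically on a shared square
canvas with binary alpha: a lizard (head disc, trunk tapering toward the
tail, a rightward-curving tail of stamped discs, four elliptical leg lobes,
three dark dorsal spots), a small-legged variant (leg lobes scaled by 0.45),
a legless variant (leg scale 0 — identical to the lizard outside the leg
lobes by construction), a recoloured legless variant (same silhouette,
yellow palette) and a compact spotted disc. The body spans ~70 % of the
canvas height; default canvas 56×56, desk-scale canvas 32×32. Targets are
premultiplied RGBA (trivially so when generated, explicitly on PNG load), so
colour under transparent pixels carries no loss signal.

## Training

Sample-pool training with backpropagation through time. Each step:

1. Draw `batch_size` slots from the pool (capacity `pool_capacity`, all
   fresh seeds at start). Each slot permanently carries an orientation angle
   drawn uniformly from [0, 2π), its environment field, and the
   angle-rotated target; reseeding a slot resamples all three.
2. Replace the highest-loss batch member with a fresh seed (so the
   grow-from-seed task is never forgotten); once past the damage warm-up,
   zero a random disc (radius 0.25·H/2) in the lowest-loss members
   (regeneration pressure).
3. Roll out a uniformly random number of iterations in
   [`iters_min`, `iters_max`], backpropagate the summed squared RGBA error
   against each member's rotated target through the entire rollout,
   normalise each parameter tensor's gradient to unit norm, and apply Adam.
4. Write final states back to their slots; record the batch-mean loss.

The rollout, its gradients and the optimiser are implemented directly in
NumPy (float32): the computation per iteration is restricted to the one-cell
dilation of the pre-update alive region, which is exactly equivalent to the
full-grid update (verified against it in the tests) and several-fold
cheaper; firing and alive masks are treated as constants of the backward
pass; the training gradient is taken on the raw visible channels (identical
to the rendered loss once channels are in range, but without the clip's dead
zones). Gradient correctness is pinned by central-finite-difference tests in
float64.

Divergence (non-finite loss) aborts with an explicit error rather than
continuing silently.

### Scales

Full-scale defaults follow the parent conventions for this model family:
56×56 canvas, pool 1024, batch 8, iterations per step in [64, 96], learning
rate 2·10⁻³ with a 10× decay at 70 % of training, 8000 steps, damage 3
members per batch after 1000 steps. These are sized for GPU-class runs.

The *desk-scale recipe* (`morphoca.recipes`), used by the test suite and the
acceptance script, reproduces the phenomena on one CPU core: 32×32 canvas,
pool 256, batch 4, iterations per step in [30, 50] (shorter rollouts buy
more optimisation steps per CPU-minute at this canvas), learning-rate decay
at 80 % of training, 1300 steps for the primary model (damage 1 per batch
from step 700) and 350 steps for each transfer run (damage off, so
retrained and naive histories differ only in their initial parameters).
Desk-scale models are under-converged relative to
long runs — silhouettes and colours are right, fine detail is soft — which
is sufficient for every comparative property (persistence, transfer,
knockout ordering, conservation, vestigial structures) though absolute
losses remain above what a full-scale run would reach.

## Analysis conventions

- **Developmental period** is iterations 0–60; evaluation of developed
  patterns uses 100 iterations; phase windows are early [0, 9], mid
  [11, 30], late [31, 60] (iteration 10 deliberately belongs to no phase).
- **Activity** is post-ReLU (nonnegative by construction), summed over all
  grid pixels — including off-body pixels, whose units still respond to the
  environment gradients.
- **Classification:** early-active = top-20 by summed activity over [0, 9];
  late-active = top-20 over [30, 60] *excluding* early members, refilled to
  20; inactive = bottom-20 over [0, 9]. Ties break to the lower unit index
  everywhere.
- **Knockout** clamps a unit's activation to 0 at *all* pixels;
  **constitutive activation** clamps to 0.5 only at alive pixels. The
  asymmetry is intentional and preserved: loss of function is a property of
  the factor (gone everywhere), gain of function acts where there are cells
  to act on. Perturbation comparisons always share replicate random streams
  across arms (common random numbers).
- **Conservation** between two same-architecture models is the overlap of
  their top-20 most-active unit sets, computed from rollouts sharing the
  master seed and angle-0 environment so differences reflect parameters,
  not rollout noise. The chance level is the hypergeometric mean
  k²/n (= 4.0 for k = 20, n = 100), confirmed by a permutation Monte-Carlo
  in the tests; the per-iteration series defaults to layer 1, the layer
  being selectable.
- **Vestigial trajectory:** D(t) = Σ pixels, RGBA ‖render(state_t) − ref‖²
  against the developed ancestral pattern; a transient dip of D(t) in
  mid-development (we inspect iterations 25–50) signals an ancestral
  structure grown and then pruned.

## What the synthetic study does and does not show

The generator emulates the *structure* of the original study's target
family — nested silhouettes (legged → small-legged → legless), a pure
recolouring, and an unrelated compact shape — not its artwork. Passing tests
show the mechanisms behave as designed on clean, binary-alpha, centred
targets at desk scale; they do not establish behaviour on photographic
targets, large canvases, or the exact numeric values a full-scale training
run would give (cell-count peaks, absolute conserved-unit counts and loss
magnitudes all depend on canvas size, training length and the specific
attractor reached).

## Numerical and degenerate-input choices

- float32 everywhere in training; analyses accumulate in float64.
- Strict inequalities at both thresholds (alpha > 0.1, uniform < fire_rate),
  so fire_rate 0 is exactly the identity and an alpha of exactly 0.1 does
  not sustain life.
- Grids smaller than 3×3, non-square or alpha-less PNG targets, organizers
  falling off-grid, out-of-range unit indices, overlapping phase windows and
  empty analysis windows are rejected with explicit errors.
- ReLU subgradient at 0 is taken as 0; clamp hooks contribute no gradient
  (training never uses hooks; they exist for analysis rollouts).
- Checkpoints store weights plus the complete model (and optionally
  training) configuration in one `.npz` archive.

## Known limitations

- No GPU path; full-scale training is supported but slow in pure NumPy.
- Activity summed over *all* pixels includes an environment- and bias-driven
  background at empty pixels. In desk-scale models this background can
  dominate the early-window ranking, so the "early active" set leans toward
  globally environment-responsive units; one consequence we observe is that
  knocking out the 20 late-active units can disrupt the morphology *more*
  than knocking out the 20 early-active ones (runaway overgrowth rather than
  arrested growth), inverting the ordering a fully converged model shows.
  Classifying from alive-pixel-restricted activity restores that ordering,
  but the all-pixels convention is the analysis definition and is kept.
- Desk-scale stochastic properties (knockout ordering, conservation margins,
  vestigial dips) are properties of particular trained fixtures; a different
  master seed changes the magnitudes, and occasionally the margins, though
  not the designed directions.
- The environment is static; cells cannot modify it, and time-varying or
  learned environments are out of scope.
- 2-D grids with exactly 16 model channels and fixed perception kernels;
  channel counts are configurable but learned perception is not.
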