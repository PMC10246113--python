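# Methods

## Model

`dirdiff` is a continuous-time score-based diffusion model for discrete
sequence data. A k-category symbol is embedded as a vertex of the
probability simplex and diffused forward in time by a multivariate
process built from k−1 *independent* Jacobi diffusions through the
stick-breaking construction:

    x₁ = v₁,  x₂ = (1−v₁)v₂, …,  x_k = ∏ᵢ(1−vᵢ),

where each stick coordinate vⱼ ∈ [0,1] solves

    dv = (s/2)[a(1−v) − b v] dt + √(s v(1−v)) dw .

The diffusion coefficient vanishes at the boundary while the drift
points inward, so sticks stay in [0,1]; the stationary law of each
stick is Beta(a,b), and choosing (a,b) = (1,k−1), (1,k−2), …, (1,1)
makes the stationary law of x the flat Dirichlet Dir(1,…,1). Generation
reverses the diffusion: a score network s_θ(x,t) estimates the v-space
score ∇_v log p_t, the reverse SDE is integrated from the horizon T
down to a small cutoff, and the terminal simplex point is discretized
to a category (argmax by default; a categorical draw treats x as the
parameter of an emission distribution).

### Transition density and training targets

The univariate transition density has the classical spectral expansion

    p(x_t|x₀) = B_{a,b}(x_t) · Σₙ e^{λₙt} dₙ Rₙ(x₀) Rₙ(x_t),
    λₙ = −(s/2) n (n−1+a+b),

with Rₙ(x) = Pₙ^{(b−1,a−1)}(2x−1) (classical Jacobi polynomials, exact
eigenfunctions of the generator — verified by a finite-difference
generator oracle in the tests) and dₙ = 1/⟨Rₙ,Rₙ⟩_{Beta(a,b)} in closed
form via gamma functions. The training target for a diffused sample is
the analytic derivative ∂/∂x_t log p(x_t|x₀) of this expansion; it is
cross-checked against central finite differences to 1e-4.

Truncation: one expansion per parameter set is built at the floor time
t_min = 0.01 with terms kept while e^{λₙt}dₙ·max|Rₙ|² ≥ 1e-8 (cap 200);
at larger times fewer terms are used by the same rule. The series is
unreliable below t_min, so all density/score evaluations refuse t <
t_min. Truncated densities are floored at 1e-40 before logs; material
negativity raises a warning.

Training uses denoising score matching with the G Gᵀ-weighted loss:
per stick dimension the squared score residual is weighted by
s·v(1−v), the diffusion coefficient squared. This weighting makes the
loss invariant under smooth changes of variables (checked numerically
between v-space and the simplex to 1e-6) and reduces to the familiar
λ(t) = g(t)² likelihood weighting when g does not depend on the state.

### Forward-sample dictionary

One-hot data start every determined stick at 0 or 1, so forward
diffusion only ever starts from two points per process. We pre-sample
Euler–Maruyama trajectories from both starting points, snapshot them on
a log-spaced grid of 100 times in [0.01, 4] (unit speed; the slowest
spectral mode e^{−t} is ≈0.018 at T=4), score the snapshots
analytically, and draw training minibatches from this dictionary
(uniform without replacement within a cell). Undetermined stick
dimensions (those past the one-hot's 1) remain stationary for all time
and are drawn fresh from their Beta law with the stationary score.

Stored samples are projected to the 1e-3-interior before scoring: the
integrator can park a sample essentially on the boundary at small t,
where the score behaves like 1/(1−v) and a single clamped point would
dominate entire training batches. The projection caps target magnitudes
near 2·10³ at a negligible density distortion.

## Score-model parameterization at CPU scale

Raw networks regressing v-space scores face targets whose magnitude
grows like 1/t (≈200 at t=0.01). Two devices make desk-scale training
work; both are exact reparameterizations, not approximations of the
objective:

1. **Per-time output scaling** (`TimeScaledScore`): the network
   predicts the score in units of the dictionary's median |score| at
   each (time, dimension), keeping its output O(1). Used for the
   convolutional sequence net.

2. **Factorized mixture baseline + gated residual**
   (`FactorizedMixtureScore`, `ResidualScoreModel`): for one-hot data
   the forward marginal of a *single position* is an exact mixture over
   its possible categories of products of spectral transition /
   stationary Beta densities, so its score is available in closed form
   (tabulated over time × value grids, interpolated at run time). This
   baseline is exact whenever positions are independent, and exact in
   the small-t and large-t limits for any data distribution, because a
   position's own coordinates determine its category as t→0 and
   everything is stationary as t→∞. The network therefore only learns
   the cross-position correction, added through a smooth log-time gate
   (cosine ramps, plateau [0.12, 3.0] by default) that is closed where
   the baseline is provably sufficient. Training times are restricted
   to the gate's support. The category prior of the baseline is the
   empirical marginal of the training data (uniform for Sudoku).

   Empirically this decomposition is what turns the 4×4 Sudoku task
   from ~4% valid samples (raw network, same budget) into >80%: the
   constraint structure lives at intermediate diffusion times and is
   learnable there, while the large-magnitude small-t regime needs no
   learning at all.

### Architectures

* `MLPScoreNet` — tokenwise two-hidden-layer MLP (GELU); for
  i.i.d.-position toys.
* `SequenceScoreNet` — same-padded dilated residual 1-D conv stack
  (ReLU, dilation 1,2,4,8 cycle); an optional per-position condition
  track (e.g. a transcription-initiation signal profile) joins the
  input channels.
* `SudokuScoreNet` — pre-LN transformer over the N² cells; a binary
  relative positional encoding (cell pairs sharing a row / column /
  box; 81×81×27 for 9×9) is projected by a linear layer to one bias
  per attention head and added to the attention logits before the
  softmax. Head count and width are free parameters (defaults 4 heads,
  d=96 at full size; 3 blocks, d=48 for the 4×4 study).

Time enters all networks through sinusoidal features of log t (the
small-t regime is where scores change fastest). All layers are plain
numpy with hand-written backward passes and an Adam optimizer
(`dirdiff.nn`); training is bit-reproducible from a seed.

## Sampling

Reverse-time Euler–Maruyama per stick dimension with the model score,
states clamped to the 1e-6 interior. Initialization is an exact
stationary Dirichlet draw via stick-breaking, so there is no burn-in.
The default schedule is log-spaced in time: step sizes shrink ∝ t,
matching the 1/t growth of scores (a linear schedule is available; it
is markedly less stable at the end of sampling).

**Time dilation** (factor c ≥ 1) runs the reverse SDE on a stretched
clock: c times as many full-size integration steps per unit of model
time, i.e. the SDE clock advances c× faster than the score's time
argument. Quasi-statically this lets the state equilibrate toward each
intermediate density before it sharpens further, so terminal samples
concentrate near modes. With a flat stationary law this biases samples
toward high-density regions without retraining; c=1 recovers unbiased
sampling. This stretched-clock construction is one concrete reading of
the technique; we validate it by its qualitative effect (4×4 Sudoku
validity is non-decreasing in c over {1,2,4}), not by a formula.

**Inpainting** (conditional generation): clamped positions are
overwritten at every reverse step with forward-diffused versions of
their fixed one-hot values at the current model time. The forward
states are pre-simulated once as consistent EM trajectories snapshotted
at the reverse schedule's times. After discretization the clamped
positions are set to the clamp values exactly. Solving Sudoku is
inpainting with the clues clamped; no additional training is involved.

## Likelihood

The probability-flow ODE per stick dimension,

    dv = { (s/2)[a(1−v) − bv] − (s/2)(1−2v) − (s/2)v(1−v) s_θ(v,t) } dt,

shares the reverse SDE's marginals. Integrating state plus the
accumulated Jacobian trace from t̃₀ to T (adaptive RK45, rtol = atol =
1e-5) and evaluating the terminal state under the stationary
product-Beta law gives the continuous v-space log-density; the
stick-breaking log-Jacobian converts to simplex densities on request.
The trace is computed exactly via dense central finite differences for
systems of dimension ≤ 32 (noise-free, and no more expensive than
probing at these sizes) and by Hutchinson's estimator with standard
normal probes beyond; probes are fixed per solve and the two agree
within Monte-Carlo error in the tests.

For discrete data y the ELBO

    log p(y) ≥ E_{q(x|y)} [ −log q(x|y) + log pCat(y|x) + log pODE(x) ]

is estimated by forward-diffusing the one-hot datum to t̃₀ (EM with
20 000 steps per unit time — at these short horizons the discretization
must be fine for the sampled law to match the spectral density used for
log q), scoring q with the same spectral densities used in training,
and evaluating pODE from t̃₀. Both q and pODE are taken in v-space so
the change-of-variable terms cancel. The bound tightens as t̃₀
decreases; t̃₀ is floored at the spectral cutoff 0.01. When a ladder of
t̃₀ values is requested, one forward trajectory per Monte-Carlo draw is
snapshotted at every ladder time (common random numbers), which is what
makes the monotone-tightening property testable at small sample sizes.
Per-symbol values in bits divide by L·ln 2.

## Synthetic data

* **Sudoku** (4×4 and 9×9): randomized-backtracking generator —
  correct by construction; the 288-element 4×4 support is small enough
  for exhaustive enumeration, which the tests use as an oracle. Puzzle
  creation removes cells, optionally verifying uniqueness with an
  exhaustive solver. Validity is all-or-nothing.
* **i.i.d. categorical toys**: exact known likelihoods; the
  2-category p=0.7 toy is the reference recovery benchmark.
* **Promoter-like records**: uniform background DNA, one sharp
  TATA-like PWM instance planted ~28 bp upstream of the central "TSS",
  and a per-position initiation-signal profile (Gaussian bump at the
  TSS scaled to a configured expression level, multiplicative noise).
  This reproduces the *shape* of a TSS-centered promoter dataset —
  sequence + aligned signal track — not real promoter biology: there
  is one motif class, no chromatin context, no strand, no genome
  coordinates. Passing the conditional-design test shows the model can
  route per-position conditioning into sequence content; it says
  nothing about performance on real CAGE-derived data.

## Study sizes and defaults

The shipped study configurations are sized for a single CPU:
Bernoulli toy (L=8, MLP, 2500 DSM steps, ~20 s), conditional
sequence toy (L=24, conv width 32, 1800 steps, ~2 min), and 4×4
Sudoku (3-block d=48 transformer residual, 8000 steps at batch 96,
~8 min; sampling with 160 base steps). The full-scale 9×9 Sudoku and
1024-bp promoter configurations (20-block d=96 transformer; width-128
conv) are shipped in `configs/` and run through the same code path;
reaching the literature-scale accuracy regime with them requires
GPU-scale compute and is out of scope for the test suite.

Key defaults: speed factor s=1 (an `inv-sum` preset s = 2/(a+b) is
exposed; the choice only rescales time per process); T=4; t_min =
t̃₀ = 0.01; EM 1000 steps per unit time (400 for cache building, where
the KS agreement with the spectral density was verified); truncation
tolerance 1e-8, cap 200 terms; interior clamps 1e-6 (integration) and
1e-3 (stored training samples / baseline tables); Adam with cosine
learning-rate decay.

## Known limitations

* The spectral series is not evaluated below t=0.01; likelihood bounds
  cannot be tightened past that cutoff.
* Far tails of the transition density at small t (states far from
  every plausible starting point) are dominated by truncation noise;
  scores there are meaningless. Training samples never live there, but
  oracle-style mixture scores evaluated in that regime are unstable —
  relevant when using exact-score references, not the trained models.
* The stretched-clock time dilation is an interpretation; its
  quantitative relation to annealed target densities is not derived
  here.
* Numpy networks are single-threaded and CPU-bound; the architecture
  sizes that fit this budget are far below those needed for 9×9 Sudoku
  or real promoter modeling.
* `draw_minibatch` draws without replacement within a cache cell, so a
  single cell cannot serve more samples than it stores per batch.
* Replacement inpainting samples the conditional distribution only
  approximately: even with an exact score field, single-sample solve
  rates of a unique-solution 8-clue 4x4 puzzle are ~50-80% (rising with
  time dilation and step count), not 100%. Multiple samples plus the
  exact-match validator recover reliability, mirroring how hard puzzles
  are handled at full scale.
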