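# dirdiff — Dirichlet diffusion score models for discrete sequences

`dirdiff` is a generative modeling toolkit for discrete sequence data —
DNA sequences, Sudoku grids, categorical toys — built on continuous-time
score-based diffusion *on the probability simplex*. It is aimed at
researchers in regulatory genomics and generative modeling who want a
diffusion model whose noising process is natural for categorical data:
no bit encodings, no quantization, and a stationary law (the Dirichlet
distribution) that is exactly uniform over the simplex.

## The model

A k-category symbol is a vertex of the (k−1)-simplex. Stick-breaking
coordinates v ∈ [0,1]^{k−1} represent a simplex point via
x₁ = v₁, x₂ = (1−v₁)v₂, …, x_k = ∏ᵢ(1−vᵢ), and each stick runs an
independent Jacobi diffusion

    dv = (s/2)[a(1−v) − bv] dt + √(s v(1−v)) dw ,

whose stationary law is Beta(a, b). With (a,b) = (1,k−1), …, (1,1) the
induced law of x converges to Dir(1,…,1). The transition density has a
spectral expansion in Jacobi polynomials,

    p(v_t | v₀) = B_{a,b}(v_t) Σₙ e^{λₙ t} dₙ Rₙ(v₀) Rₙ(v_t),
    λₙ = −(s/2) n(n−1+a+b),

so the denoising score-matching targets ∂ log p(v_t|v₀)/∂v_t are
analytic. A score network s_θ(x, t) is trained with the
GGᵀ-weighted loss (weight s·v(1−v) per stick; invariant under change of
variables), sampling integrates the reverse-time SDE from the Dirichlet
stationary law, *time dilation* biases samples toward high-density
regions without retraining, *inpainting* clamps observed positions for
conditional generation (e.g. solving Sudoku from clues), and the
probability-flow ODE yields likelihoods plus a discrete-data ELBO.

See `docs/methods.md` for the full model description, the numerical
choices, and the CPU-scale score parameterizations (per-time output
scaling and the factorized-mixture baseline with a gated residual).

## Worked example

Train the two-category toy (i.i.d. positions, P(category 1) = 0.7),
sample from it, and bound the likelihood of a sequence:

```python
import numpy as np
from dirdiff import DirichletDiffusion
from dirdiff.sampler import SamplerConfig
from dirdiff.likelihood import LikelihoodConfig
from dirdiff.tasks import iid_categorical_batches

data = iid_categorical_batches([0.3, 0.7], length=8, batch_size=64,
                               rng=np.random.default_rng(0))
model = DirichletDiffusion(data, k=2, length=8, seed=0)
res = model.fit(n_steps=2500, lr=2e-3)
print(res.summary())

x, cats = res.sample(2000, SamplerConfig(n_steps=100), seed=1)
print(f"category-1 frequency: {np.mean(cats == 1):.4f}")

y = np.array([1, 1, 0, 1, 1, 1, 0, 1])
elbo_bits = res.elbo(y, LikelihoodConfig(t0=0.01), n_mc=8,
                     per_symbol_bits=True, seed=2)
print(f"ELBO: {elbo_bits:.3f} bits/symbol")
```

Output (~40 s on one CPU core):

```
Dirichlet diffusion score model
==================================
categories (k):        2
sequence length:       8
stick processes:       [(1.0, 1.0)]
score model:           MLPScoreNet
trainable parameters:  5441
training steps:        2500  (batch 64, lr 0.002)
final loss (last-50 mean): 0.3848
time grid:             100 points in [0.01, 4]
category-1 frequency: 0.7114
ELBO: -0.962 bits/symbol
```

The sampler recovers the generating frequency (0.711 vs 0.70), and the
ELBO is a valid lower bound: −0.962 bits/symbol against the exact
per-symbol log-likelihood −0.820 bits of this particular sequence.

The same interface drives the structured tasks: the 4×4 Sudoku pipeline
(`configs/mini_sudoku.yaml`; relational-transformer residual around the
analytic factorized baseline, ~10 min CPU) reaches ≳80% fully-valid
grids with time dilation and solves clue-constrained puzzles by
inpainting. From the shell:

```sh
dirdiff train  --config configs/mini_sudoku.yaml
dirdiff sample --config configs/mini_sudoku.yaml --n 100 --dilation 4
dirdiff solve  --config configs/mini_sudoku.yaml --puzzle-file puzzles.txt
```

Full-scale configurations for 9×9 Sudoku and 1024-bp conditional
promoter design (`configs/sudoku9.yaml`, `configs/promoter.yaml`) run
through the same code path but need GPU-scale compute budgets to reach
literature-level accuracy.

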