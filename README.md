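# rnmf — regularized NMF with exact scale control

`rnmf` decomposes a non-negative expression matrix **X** (genes × samples)
into a small number of additive components,

```
X ≈ W Aᵀ,    W ≥ 0 (genes × k),    A ≥ 0 (samples × k),
```

while minimizing the regularized objective

```
min  ‖X − W Aᵀ‖_F² + λ·J(W)     subject to   W ≥ 0,  A ≥ 0,  1ᵀaₗ = α  for every column aₗ of A.
```

Because penalties such as the ℓ1 norm are scale-dependent, an unconstrained
mixing matrix would simply inflate to absorb the shrinkage of **W**. Here
every column of **A** is constrained *exactly* to the α-simplex (non-negative,
summing to α), which locks the scale of the solution and makes standard
regularizers safe to use. Three interchangeable penalties J(W) are provided:

- **l1** — entrywise ℓ1 norm of W: sparse base vectors with exact zeros;
- **tikhonov** — ‖L W‖_F² with a filter matrix L (identity ridge or
  difference operators for smoothing);
- **related** — Σ ‖wᵢ − wⱼ‖² over designated component pairs, pulling base
  vectors of related components (e.g. related cell types) together.

The solver is block-coordinate descent with exact block minimizers and
proximal-point safeguards: each mixing column is a diagonal quadratic over
the α-simplex solved by an exact sort-and-scan Euclidean projection; the
component blocks are solved in closed form (l1 soft threshold) or by
active-set non-negative least squares on normal equations (FNNLS). The
proximal terms keep every subproblem strictly convex, so the objective is
monotone non-increasing and limit points are critical points — the package
reports first-order (KKT) optimality residuals for both factors so that
"converged" has a checkable numerical meaning.

Intended users: computational biologists decomposing bulk or single-cell
expression matrices into sparse metagene-like components, and anyone who
needs regularized NMF with certificates of optimality rather than a
stopped-iteration heuristic.

## Worked example

All testing and the example run on synthetic matrices with planted factor
structure — no external data required.

```python
import numpy as np
from rnmf import (SolverConfig, generate, lambda_for_sparsity,
                  match_components, sparsity_fraction)

# a planted instance: 60 genes, 40 samples, 4 components, 50% zeros in W
inst = generate(n=60, m=40, k=4, alpha=1.0, planted_sparsity=0.5,
                noise_sd=0.05, seed=0)
config = SolverConfig(k=4, alpha=1.0, seed=0)

# choose the l1 weight that yields 50% exact zeros, refit at that weight
lam, model, trace = lambda_for_sparsity(inst.X, target=0.5, config=config)
print(f"lambda            : {lam:.4f}")
print(f"zero fraction of W: {sparsity_fraction(model.W):.3f}")
print(f"sweeps            : {trace.sweeps}")
print(f"final objective   : {trace.objective[-1]:.4f}")
print(f"KKT residuals     : W {trace.kkt_w[-1]:.2e}, A {trace.kkt_a[-1]:.2e}")

perm, sims = match_components(model.W, inst.W_true)
print(f"matched cosine sim: {np.round(sims, 3)}")
```

prints

```
lambda            : 0.0624
zero fraction of W: 0.500
sweeps            : 46
final objective   : 8.4166
KKT residuals     : W 1.59e-03, A 9.09e-03
matched cosine sim: [0.906 0.956 0.937 0.921]
```

The bisection search found the weight λ ≈ 0.062 at which exactly half the
entries of the converged **W** are exact zeros; the fitted base vectors
align with the planted ones at cosine similarity ≈ 0.91–0.96 despite the
noise. Tightening `config.tol` drives the KKT residuals toward zero
(runs at `tol=1e-13` reach ~1e-7; see the diagnostics trace).

## Command line

```sh
rnmf simulate --n 60 --m 40 --k 4 --sparsity 0.5 --noise-sd 0.05 --seed 0 --out sim/
rnmf fit --input sim/X.tsv --k 4 --reg l1 --lam 0.06 --seed 0 --out run/
rnmf sparsity-search --input sim/X.tsv --k 4 --target 0.5 --seed 0 --out search/
rnmf diagnose --model-dir run/ --input sim/X.tsv
```

`fit` writes `W.tsv`, `A.tsv` (components ordered by strength, ‖wₗ‖),
`trace.tsv` (per-sweep objective, KKT residuals, sparsity) and `run.json`
(full configuration). Inputs may be TSV, CSV or GCT 1.2. Exit codes:
0 success, 2 input-contract violation, 3 budget exhausted before
convergence (model still written).

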