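# Methods

## Model

`multisbm` infers modular structure shared by `T` undirected, simple, binary
networks `A^(1)…A^(T)` on one vertex set of size `N`.  The generative model
is a hierarchical stochastic block model:

* a latent *root* assignment `z_i ∈ {1…K}` per vertex, drawn from a
  multinomial with weights `π`;
* per-network *instantaneous* assignments `z_i^(t)` drawn from row `z_i` of
  a row-stochastic transition matrix `P^(t)`;
* edges drawn independently per unordered pair: probability `θ_c` when the
  two endpoints share an instantaneous module, `θ_d` otherwise, with the
  same `(θ_c, θ_d)` for every network.

The root partition is the quantity of scientific interest: it is the
modular structure all observations are noisy snapshots of.  Edges recurring
across networks accumulate evidence through the shared root, which is what
lets multiple noisy observations outperform any single one.

Conjugate priors keep every update closed-form: `π ~ Dirichlet(n₀)`,
`θ_c ~ Beta(α_c0, β_c0)`, `θ_d ~ Beta(α_d0, β_d0)`, and each row of each
`P^(t) ~ Dirichlet(η₀ row)`.

## Inference

The posterior is approximated by a fully factorized (mean-field)
distribution; minimizing the variational free energy `F` (the negative
ELBO, an upper bound on `−ln p(A^(1:T)|K)`) gives digamma-based
expectations of all log-parameters and multiplicative updates for the soft
assignment matrices `Q` (root, `N×K`) and `Q^(t)` (instantaneous), plus
count-based updates for the Beta/Dirichlet posterior hyperparameters.

The loop alternates two stages:

1. **Assignment stage.**  With parameter posteriors fixed, the coupled
   `Q`/`Q^(t)` updates are iterated to their fixed point (tolerance 1e-8 on
   the max entry change, cap 200 sweeps).  This matters: a single sweep
   from a random start produces an essentially random partition whose
   expected within-module edge density equals the global density, the two
   Beta posteriors then coincide, and the coupling signal dies before any
   structure can form.  Running the stage to convergence lets the
   edge-driven attraction amplify incipient structure while the parameter
   posteriors still carry the prior's within > between bias.
2. **Parameter stage.**  `ñ`, `η̃^(t)`, and the four Beta parameters are
   refreshed from the converged assignments, and `F` is recorded.

Updates are whole-matrix (synchronous) for vectorizability.  The raw
synchronous map can oscillate — the non-edge repulsion term acts on all
vertices at once, so every vertex simultaneously chases the currently
smallest module in a period-2 cycle.  The fixed-point step is therefore
damped adaptively: full steps initially, with the convex mixing weight
halved (floor 0.05) whenever the residual stops contracting.  Damping
preserves the fixed points.  With it, the recorded free energy is
non-increasing across outer iterations on every instance we test, which is
asserted (relative tolerance 1e-8) throughout the suite.

Convergence is declared when the relative free-energy change drops below
`rel_tol` (default 1e-6, cap 500 outer iterations).  The objective is
multi-modal, so `fit` runs `n_restarts` random initializations (rows drawn
from a symmetric Dirichlet(1)) and keeps the state with the lowest final
`F`.  `0·ln 0 := 0` in entropy terms; row normalization subtracts the row
maximum in log space.  All randomness flows from one top-level seed through
named substreams (`init`, `rewire`, `holdout`, …).

`exact_log_evidence` enumerates all `K^(N(T+1))` assignment configurations
with `θ`, `π`, `P` integrated out analytically (Beta/Dirichlet normalizer
ratios); it is refused above 10^6 configurations and serves as the
independent oracle behind the bound check `F ≥ −ln p(A|K)`.

`select_K` fits each candidate and returns the `K` with minimal best
free energy, the variational stand-in for maximum evidence.

### Single-network baseline

The baseline is the classical single-network variational SBM, realized
inside the same fitter by structurally tying `Q ≡ Q^(1)`: the one
assignment update combines the pair coupling with the root prior, the
transition machinery drops out, and the free energy counts one assignment
entropy and no transition terms.  Sharing the code path guarantees that
multi-versus-single comparisons isolate the effect of the cross-network
coupling.  (A clamp that forces `E[ln P]` to ±large-constant identity was
considered and rejected: a large coupling constant hardens every row to
one-hot in a single step, collapsing the algorithm to a hard ICM-style
iteration that is not the single-network VB.)  The suite checks the tied
fit against an independently coded single-network VB oracle.

## Default hyperparameters

| parameter | default | role |
| --- | --- | --- |
| `n₀` | all ones | uninformative module weights |
| `(α_c0, β_c0)` | (2, 1) | prior mean θ_c = 2/3: within-module edges denser |
| `(α_d0, β_d0)` | (1, 2) | prior mean θ_d = 1/3 |
| `η₀` | 5 on-diagonal, 1 off | instantaneous assignments tend to follow the root |

The two biases (within > between edge density; diagonal-dominant
transitions) are structural requirements of the model; the magnitudes are
mild engineering defaults — a few pseudo-counts against `O(N²)` pair counts
— and everything is configurable.  Inference is insensitive to the Beta
magnitudes provided the within > between direction holds.

## Synthetic benchmark

The generator reproduces the planted-partition benchmark: `N=128` vertices,
`K=4` modules of 32, expected vertex degree 16 of which 6 between-module,
giving `θ_c = (16−6)/31 ≈ 0.3226` and `θ_d = 6/96 = 0.0625`.  Module sizes
are exact by default (multinomial sampling is available).  Noisy
observations apply Maslov–Sneppen rewiring: pick two distinct edges
uniformly from the current edge set, orient each uniformly, cross them as
`(i,j),(k,l) → (i,l),(j,k)`, reject (uncounted) any proposal creating a
self-loop or duplicate edge, and stop after `round(fraction·|E|)` accepted
swaps.  Degree sequences are preserved exactly.  Experiment one produces
`T=10` networks at fractions 5%…50%; experiment two produces `T=10`
networks at a constant 25%.

What the generator does *not* emulate about real interaction data:
degree heterogeneity (hubs), overlapping complexes, assortativity beyond
the block structure, and systematic (non-exchangeable) measurement bias —
rewiring noise is degree-preserving and unbiased.  Passing the synthetic
suite therefore demonstrates correct inference under the block-model
assumptions, not robustness to every artefact of real protein-interaction
screens.

### Noise-accounting sensitivity

The rewiring quota counts *accepted swaps*, and each swap displaces two
edges, so a fraction-0.25 quota on 1024 edges performs 256 swaps and
displaces roughly 40% of edges (collisions discounted).  An alternative
reading — 25% of *edges displaced*, i.e. half the swaps — produces a much
milder perturbation.  The multi-versus-single NMI gap in the constant-noise
experiment is very sensitive to this choice: with the swap-count quota the
measured gap is ≈0.35–0.37 (single-network NMI ≈0.45); with the
edges-displaced quota it is ≈0.12 (single-network NMI ≈0.8).  We verified
that the low single-network scores are not an optimization artefact:
refining from a truth-initialized state yields *higher* free energy than
the best random restart, so the weak solutions are genuinely optimal under
the single-network model at that noise level.  The package keeps the
swap-count quota throughout.

Scaled-down study sizes used by the suite and the acceptance script (chosen
as the package's own test protocol): 20 repeats × 10 restarts for the
constant-noise experiment; 200 replicates for generator calibration;
20 seeds × 2 restarts for the edge-prediction comparison.

## Edge prediction

Held-out edges are removed from the likelihood (missing-at-random), not set
to zero: every pair sum in the assignment and Beta updates is restricted to
observed pairs via a per-network boolean mask.  Pair `(i,j)` of network `t`
is scored by `p(A_ij=1) = (m_c − m_d)·Σ_k Q^(t)_ik Q^(t)_jk + m_d` with
`m_c, m_d` the posterior means of `θ_c, θ_d`.  Test negatives default to a
*balanced* sample of non-edges (equal to the held-out edge count), keeping
PR baselines comparable across training ratios; an *all-non-edges* mode is
provided for sensitivity analysis.  Ranking quality uses trapezoidal ROC
AUC and average precision.  In our paired runs the two-network fit beats
the single-network fit at every training ratio 0.2–0.8; the measured margin
is largest at low training ratios (≈+0.08 ROC AUC) and flat-to-smaller at
high ones (≈+0.03–0.06), in both negatives modes.

## Evaluation metrics

* **NMI** (partitions): `MI / max(H, H')`, natural logs, `0·ln 0 := 0`;
  defined as 0 when both partitions are single-cluster.  The
  max-normalization (not mean) is deliberate.
* **Overlap score** `ω = |V1∩V2|² / (|V1||V2|)`; the conventional match
  threshold 0.25 is attained by two equal-size sets sharing half their
  members.  `Frac` counts the fraction of *reference* complexes with at
  least one prediction at `ω` strictly greater than 0.25 (the reference-side
  convention; the prediction-side variant is obtainable by swapping
  arguments).
* **Sn / PPV / Acc** from the reference-by-prediction contingency table;
  `Acc = √(Sn·PPV)` since Sn alone is gamed by one giant module and PPV by
  singletons.
* **Sep**: products of row- and column-wise relative frequencies of the
  table, aggregated per prediction (`Sep_ref`) and per reference
  (`Sep_inf`), combined geometrically.  Rows/columns with zero sum
  contribute 0 rather than NaN.

## Numerical and degenerate-input conventions

Argmax ties in hard readout break to the lowest module index.  Empty
modules are allowed to persist (`K` is an upper bound).  Vertices isolated
in one network are retained — their observed non-edges are information.
Probabilities `θ ∈ {0, 1}` are rejected in the exact joint evaluator;
zero entries of `π`/`P` contribute `−inf` only when selected.  Rewiring
aborts if 1000× the quota of proposals fails to complete it (pathological
inputs such as near-complete graphs).

## Known limitations

Binary undirected graphs only; one shared `(θ_c, θ_d)` across networks; no
degree correction, so hub-dominated real networks are fitted only as well
as the plain SBM allows; hard module readout (the posterior `Q` matrices
are written out for anyone wanting overlapping structures); the free-energy
comparison across `K` is a variational approximation to evidence, not the
exact marginal likelihood.
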