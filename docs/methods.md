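# Methods

## The estimation problem

Multiplexed single-cell measurements (mass cytometry and similar) are
destructive: each cell is observed at exactly one time, so a dataset is
a collection of *snapshots* — an initial-condition matrix `X` (cells ×
species) and, for each observed time `t`, a matrix `Y_t` of different
cells.  No cell-to-cell correspondence exists across times.  What the
population does carry, at every time, are sample moments: per-species
means, variances and pairwise covariances.  `snapgmm` estimates the
rate constants θ of a mass-action reaction network by matching those
moments.

Given a network with species abundances x and reactions r with net
stoichiometry S and mass-action propensities
v_r(x; θ) = θ_r · ∏_i x_i^{c_ri} (total order ≤ 2), each cell evolves
independently as dx/dt = S v(x; θ) (deterministic mode) or as a
continuous-time Markov jump process with the same propensities
(stochastic mode, Gillespie direct method).  Every row of `X` is
integrated to each observed time, the predicted moment vector
m(θ, t) is formed from the evolved population, and the estimate
minimizes the generalized-method-of-moments (GMM) cost

    J(θ) = Σ_t g_t(θ)ᵀ W_t g_t(θ),      g_t(θ) = m(θ, t) − m̂_t,

where m̂_t are the observed moments of `Y_t` and W_t is a
data-driven weight block (below).  Because cells at different times are
disjoint sets, cross-time moment covariances vanish and the weighting
is block-diagonal across times.

## Moment vectors

Three nested levels are supported (config key `moments = 1|2|3`): means
only (p entries); means and variances (2p); means, variances and the
p(p−1)/2 pairwise covariances (p(p+3)/2 entries — 27 for six species,
20 for five, 14 for four).  Order is fixed: means in species order,
then variances, then covariances in lexicographic pair order.
Variances and covariances use the unbiased 1/(n−1) normalization; at
least two cells per snapshot are required.

## Weights

Each cell c contributes a vector u_c whose entries are its abundances
(mean slots), squared deviations from the snapshot mean (variance
slots) and cross-deviations (covariance slots).  The sample covariance
of {u_c} divided by n estimates the sampling covariance of the moment
vector itself; the weight block is its ridge-regularized inverse
(`inverse_cov`, the default), its diagonal inverse (`diagonal`), or the
identity (`identity`, for debugging).  The ridge defaults to
10⁻⁶·trace/dim, enough to invert the near-singular covariances produced
by strongly correlated species.  When a snapshot has fewer cells than
moment entries + 1, the full covariance is unestimable and the method
falls back to `diagonal` with a logged warning.  Weights are computed
once from the observed data and held fixed during optimization
(one-step GMM): the objective stays deterministic and the scheme is the
simplest standard choice; iterated GMM is deliberately not implemented.

## Simulation routes

`evolve_cells` integrates every cell independently (no cross-cell
coupling — the well-mixed single-cell interpretation).  Three routes
give the same answer within tolerance:

- `exact`: for networks whose reactions all have order ≤ 1 the
  population dynamics are affine, dx/dt = A(θ)x + b(θ), and every cell
  is propagated by the matrix exponential of the augmented (p+1)
  system.  This is the exact solution and the default for such
  networks; it is also what makes fitting first-order models fast
  (one 7×7 `expm` plus a matrix product per cost evaluation).
- `rk45`: an adaptive Dormand–Prince 4(5) integrator compiled with
  numba, looping over cells with per-cell step control
  (rtol 10⁻⁶, atol 10⁻⁹ by default, both configurable).  This is the
  default for nonlinear networks and the route exercised by all
  integrator-versus-closed-form tests.
- `lsoda`: scipy's stiff-capable LSODA applied to chunks of 64 cells,
  for stiff parameter regions.

Numerical guards: a trajectory entry falling below
−10⁻⁶·max(1, max|x₀|) aborts the integration with the cell index
reported; smaller negative excursions (solver noise around zero) are
clipped to 0 on output.  An absolute guard at the atol scale would
spuriously abort ordinary decays to zero, since local truncation error
near the origin is O(tolerance · step), not O(atol).

During optimization the objective uses a two-stage integration policy:
candidate evaluations run at rtol 10⁻⁴ / atol 10⁻⁷ with a 500-step
per-cell budget, and any evaluation exceeding the budget scores +∞.
This changes the cost in well-behaved regions by less than 10⁻³
relative, while pruning absurd rate regions (say, 1000× the data's
time scale) whose ultra-fast dynamics would otherwise consume ~10⁵
steps per cell without ever fitting the data.  All *reported*
predictions, forecasts and contour grids use the tight default
tolerance.

The stochastic route (`evolve_cells_ssa`) is a per-cell Gillespie
direct method with falling-factorial propensities for multiplicity-2
reactants.  Cell i draws from substream i of `SeedSequence(seed)`, so
results are bit-reproducible and independent of iteration order; states
are recorded piecewise-constantly at the requested times.

## Optimization

The GMM cost is minimized by global-best particle swarm optimization:
v ← ωv + c₁r₁(pbest−x) + c₂r₂(gbest−x), with uniform r₁, r₂ per
dimension, reflecting bounds (position folded back, velocity sign
flipped), and non-finite objective values mapped to +∞ so a failed
integration never kills a run.  Defaults ω = 0.7, c₁ = c₂ = 1.5 are
standard constriction-like values; the search runs in log₁₀-transformed
coordinates by default because rate constants span orders of magnitude
(bounds must then be positive).  Parameter boxes default to three
decades either side of the model-file value.

A fit runs `n_replicates` independent swarms with seeds derived
deterministically from (master seed, replicate index); replicate r
always receives the same derived seed regardless of how many replicates
run.  The point estimate is the lowest-cost replicate (not the
replicate mean), and per-parameter 95% confidence intervals are
empirical percentiles over the replicate estimates with linear
interpolation.  The reported interval is widened, if necessary, to
contain the point estimate — the best replicate can otherwise sit
outside the interpolated 2.5th/97.5th percentiles of a small replicate
set.  These intervals measure optimizer scatter given the data, not
sampling variability; with few replicates they should be read
qualitatively.

## Diagnostics

`fit_report` tabulates every observed moment against its predicted
value and `fit_slopes` summarizes each moment class by the
least-squares slope through the origin of observed on predicted —
slopes near 1 mean the model reproduces the population statistics even
where individual rates are poorly determined.  `cost_contour` evaluates
log₁₀ J on an n×n lattice of one parameter pair (log-spaced axes by
default) with all other parameters held fixed; broad or striped regions
within ~1 log-unit of the minimum flag parameter combinations the data
cannot distinguish.  Exact zeros are floored at 10⁻³⁰⁰ before taking
the logarithm.

## Synthetic data

The generator emulates the structure of cytometry snapshot data:
per-species lognormal initial abundances (log-location μ, log-scale
σ = 0.4 by default); an observed `X` cohort that is never evolved; one
fresh, disjoint cohort per observed time, evolved under the
ground-truth parameters, of which only the evolved states are kept; and
optional additive Gaussian noise on the observed matrices
(`negative_artifact_sd`) that produces the negative entries real
preprocessing pipelines introduce, exercising the load-time row filter.
Cohorts draw from independent children of `SeedSequence(seed)`, so any
single cohort is reproducible in isolation.

Four fixture models ship with frozen ground-truth rates (drawn once,
log-uniformly in [0.05, 1.0]) and default study conditions:

| fixture    | species | parameters (free)   | times      | cells/snapshot |
|------------|---------|---------------------|------------|----------------|
| linear6    | 6       | 6 (6)               | 1.5        | 10,000         |
| msn2       | 5       | 6 (4; pb, pd fixed) | 1, 5       | 10,000         |
| vav1       | 6       | 6 (6)               | 0.5, 2     | 5,000          |
| cd8_chain  | 4       | 5 (5; shared decay) | 1, 2       | 719 / 653      |

The fixture topologies are small reconstructions of commonly studied
motifs — a first-order conversion chain, a transcription-factor/
promoter gene-expression motif, a phosphorylation–dephosphorylation
cycle, and a four-protein signal relay with constant input and one
shared decay rate.  The Vav1 cycle's initial conditions deliberately
place it in the Goldbeter–Koshland zero-order ultrasensitivity regime —
substrate pools (Vav1 ≈ 40, pVav1 ≈ 10 median copies) much larger than
enzyme pools (Syk, SHP1 ≈ 2; complexes ≈ 1) — because that saturated
regime is what makes its k₂ × k₅ cost landscape flat along a valley and
the individual rates unidentifiable while moment fits stay excellent.

What the generator does *not* emulate: measurement spillover,
arcsinh/bead normalization, cell-size and batch effects, or dropout.
Tests passing on these synthetic datasets therefore demonstrate the
estimator's statistical behaviour under the stated model, not
robustness to real-world cytometry artifacts.

## Problem sizes in the shipped checks

The bundled end-to-end checks scale the study conditions to sizes a
single CPU handles comfortably: parameter-recovery runs use 2,000-cell
snapshots with a 200-particle × 60-step swarm and 10 replicates;
contour diagnostics use 41×41 grids on 400-cell datasets; the PSO
budget comparison uses 150-cell datasets with 300×50 versus 75×12
swarms over 5 seeds.  These sizes are the package's own defaults for
its self-checks; the full-size conditions in the table above remain the
generator defaults.

## Known limitations

- Reaction order is capped at 2 and species are plain names — no
  structured molecules, compartments or rule-generated networks.
- One-step GMM weights ignore the (small) correlation between weight
  estimation and moment estimation on the same cells.
- Replicate-percentile confidence intervals quantify optimizer
  variability, not full sampling uncertainty; they can under-cover when
  the swarm always converges to the same basin.
- The SSA route is pure Python per event and is intended for modest
  populations and event counts, not for production stochastic fitting.
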