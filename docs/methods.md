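# Methods

## Model and scope

`alchemsmc` implements adaptive alchemical sequential importance
resampling (SIR) over Boltzmann-family distributions
π(λ, x) ∝ exp(−u(λ, x)) on purely configurational systems. Energies
are dimensionless throughout (u = U/k_BT); no velocities, masses or
thermostat state exist, so the sampler within each λ is Metropolis
Monte Carlo rather than Langevin dynamics — any π-invariant local
sampler is admissible in the SIR framework, and for momentum-free toy
systems Metropolis is the natural choice. Velocity re-randomization
consequently has no analogue here. The free-energy normalizer f(λ) is
never evaluated; only energy differences enter, through the importance
weights, and the accumulated ln Ẑ represents it implicitly.

The engine is asymptotically exact (infinite walkers, exhaustive λ=0
sampling) but two known finite-size caveats apply and are inherited
deliberately rather than corrected:

* **Adaptive-schedule reweighting bias.** Because the λ strides depend
  on the sampled weights, the cross-replicate Ẑ-weighted estimator is
  not strictly unbiased for adaptive runs. We apply the Ẑ reweighting
  during analysis regardless and verify on the toy systems that the
  residual bias is far below statistical noise; a fixed-schedule replay
  mode (`reuse_schedule`) is available for users who want to adapt once
  and replicate with a frozen protocol.
* **Jensen bias of ln Ẑ.** ln of an unbiased ratio estimator is biased
  low by ≈ Var(Ẑ)/2Ẑ²; on the validation systems this is far inside
  one standard error at the default population sizes (verified by the
  Gaussian-ladder recovery test).

## Weights, overlap metrics, and λ placement

Step weights use the annealed-importance form
w̃_j = exp(−[u(λ_{i+1}, x_j) − u(λ_i, x_j)]), whose expectation over
π(λ_i) is exactly Z(λ_{i+1})/Z(λ_i) (Zwanzig identity); the
per-step mean unnormalized weight therefore feeds the free-energy
ledger, and the run invariant ln Ẑ = Σ ln(mean w̃) is enforced as exact
bookkeeping.

Overlap is monitored on the normalized weights with
R_ESS = 1/(N Σ w̄²) and the conservative max-weight bound
R_min = 1/(N max w̄) ≤ R_ESS. R_min is the default control metric: it
is the stricter guard against a single walker dominating the
resampling. The next λ is found by bisection on (λ_i, 1], exploiting
that the metric is 1 at λ' = λ_i and (for the potential families here)
monotone decreasing in λ'; candidates cost only energy re-evaluations.
Iteration stops when the metric is within `bisection_tolerance`
(default 0.01, on the metric scale) of `overlap_target` (default 0.5),
with a final-step rule returning λ' = 1 outright whenever the metric at
1 already meets the target. Should a non-monotone metric break the
bracket (never observed on the shipped systems, and not addressable
within plain bisection), the search falls back to the smallest tested
λ' meeting the target and warns.

A useful consequence of constant-overlap placement: each non-final
step's partition ratio is pinned near the target, so the schedule
length tracks the total dimensionless free energy — harder problems
automatically receive more intermediate distributions with unchanged
hyperparameters. The torsional-barrier scaling test checks exactly
this.

## Decorrelation control

Sampling at each λ runs in blocks of `propagation_block` Metropolis
sweeps (default 100); after each block the Pearson correlation r_τ
between the block-0 walker energies and the current ones is evaluated,
and propagation stops at |r_τ| ≤ 0.1 (configurable). Energies stand in
for configurations because the equilibrium probability of a
configuration depends on them alone. Two degenerate regimes are
resolved pragmatically: constant-energy landscapes (e.g. any system at
λ = 0 over its decoupled DOFs) make r undefined and are declared
decorrelated with a logged warning, and a hard cap of
`max_propagation_blocks` (default 100) bounds every propagation phase,
again with a warning rather than an error, so flat or stiff landscapes
can never hang the run.

## Resampling

Systematic resampling is the default: a single uniform offset
u ∈ [0, 1) and selection points (u + k)/M against the cumulative
profile guarantee counts within floor/ceil of M·w̄_j with exact totals.
Walker order is kept as stored — the floor/ceil guarantee is
order-independent, but the joint count distribution is not, so runs are
reproducible only under a fixed seed, which the counter-based seeding
scheme provides. Multinomial resampling is retained as the
higher-variance baseline and for the paired diversity comparisons;
resampling happens every iteration (an optional `skip_resample_when_uniform`
flag exists, off by default). Lineage tags (`ancestor_id`) propagate
through copies so the irreversible diversity loss of SIR can be
quantified (`diversity_report`).

## λ = 0 generators

Scalar degrees of freedom are drawn from shifted grids — n equally
spaced points plus a single uniform offset — giving max gap = min gap
(O(1/n) star discrepancy); distinct DOFs are shuffled independently so
their grids do not align. Torsions use the grid on [0, 2π); rigid-body
rotations sample an axis direction uniformly on the sphere via
θ = arccos(2X − 1) together with uniform φ and spin ψ; translations
use per-axis grids on [−1, 1) scaled to a cuboid, or uniform-in-ball
sampling with r = R·X^{1/3}. One composition subtlety: a literal
axis–angle rotation with uniform ψ does *not* induce the rotation
group's invariant measure (the identity-heavy angle distribution biases
a rotated vector toward its original direction; the mean rotation
matrix is I/3). The package therefore composes the triples as
R = T(θ, φ)·R_z(ψ) — spin about the body axis, then tilt that axis onto
the sampled direction — which is the ZYZ factorization under which
uniform direction × uniform spin is exactly the Haar measure; the
Rayleigh-style uniformity test in the suite passes only with this
composition. Joint (multidimensional) low-discrepancy sequences are
out of scope; per-DOF independence is the designed behaviour.

The initial population is oversampled (`oversample_factor`, default
100 conformers per walker): the full pool enters the first reweighting
step, and the first systematic resampling reduces it to `n_walkers`.
This is the interpretation under which the extra conformers actually
inform the target distribution rather than being discarded unseen.
Systems whose λ = 0 marginal is not uniform but still exactly
sampleable (the Gaussian ladder) plug in through the `direct` move
kind; systems with neither a uniform decoupled DOF nor an exact sampler
are rejected.

## Toy systems

* **Torsional toy**: u = λ·[a(1 + cos φ) + b(1 + cos 2φ)], a, b ≥ 0.
  The a-term gives a cis/trans asymmetry with barrier 2a·λ; the b-term
  a two-fold symmetric well pattern. λ = 0 is exactly uniform.
* **Gaussian ladder**: u = x²/(2s(λ)²) with s(λ) = s0 + λ(s1 − s0);
  −ln Z(1)/Z(0) = ln(s0/s1) in closed form. This is the calibration
  system for the free-energy ledger (defaults s0 = 2, s1 = 1, so the
  exact answer is ln 2).
* **Soft-core pair**: one mobile particle about a fixed partner in a
  periodic cube (default L = 5σ), with a λ-coupled Lennard-Jones term
  evaluated at the Beutler-style effective distance
  r_eff = (ασ⁶(1 − λ_st) + r⁶)^{1/6} (α = 0.5) and a screened-Coulomb
  toy term q₁q₂/r. The split protocol ramps sterics over
  λ ∈ [0, 0.8] (soft-core) and then electrostatics linearly on the
  bare distance over [0.8, 1]; the unified protocol ramps both
  concurrently with the electrostatics on the soft-core distance. The
  interaction is truncated and shifted to zero at r_cut = L/2, which
  (a) keeps the Metropolis energy continuous in r and λ and (b) makes
  the partition function exactly one-dimensional for the oracle, since
  beyond the cutoff the Boltzmann factor is 1 everywhere, box corners
  included. Electrostatics are deliberately a bare 1/r toy form — the
  package validates the sampler, not an electrostatics model — and the
  "annihilation versus decoupling" distinction collapses for a system
  with no intramolecular environment. Default charges (1, −3) give a
  ≈3.7 k_BT attractive well and a non-trivial bound/unbound split at
  λ = 1; the documented unified-protocol pathology (soft-core
  electrostatics rewarding sub-σ particle overlap at intermediate λ)
  is reproduced in-toy with stronger opposite charges (product −30)
  and asserted as a property test.

## Validation oracle

`oracle_partition_and_populations` integrates exp(−u(λ, ·)) by
adaptive quadrature (relative tolerance 1e−10) over the circle, the
line, or radially with the 4πr² Jacobian plus the exact field-free
outer volume, and is the independent ground truth for free energies
and state populations. It is restricted to systems with a declared
one-dimensional reduction and raises "oracle intractable" otherwise.
Cross-checks pin it to closed forms where they exist: s(λ)/s0 for the
Gaussian ladder and e^{−λa}I₀(λa) for the one-fold torsional toy.

## Estimators and uncertainties

Cross-replicate observables use Ẑ-weighted means with Ẑ applied in
shifted form exp(ln Ẑ_k − max ln Ẑ) for overflow safety. The weighted
sample standard deviation uses frequency-type weights with the
(Σw)²/((Σw)² − Σw²) small-sample correction (the convention choice is
ours; only the quantity itself is prescribed), and the reported
weighted SE divides by √K_eff with K_eff = (ΣẐ)²/ΣẐ². Because a
weighted std can understate a large spread when replicate weights are
lopsided, per-replicate unweighted values are always reported alongside
(the `analyze` command emits one column per run). Dimensionless free
energies are combined as unweighted means ± unweighted std across
replicates.

## Problem sizes and numerical choices

The validation suite runs at the reference operating point — 500
walkers (1000 for the Gaussian-ladder recovery), 100× oversampling,
overlap target 0.5 on R_min, |r_τ| ≤ 0.1, 6 replicates for population
estimates and 20 for the free-energy recovery — sizes at which every
toy-system check resolves its target within 3 SE in about a minute of
CPU. Goodness-of-fit tests on the λ = 0 generators use n = 10⁵ samples
at the 1% level; note the shifted-grid samples are super-uniform, so
iid-based p-values are conservative there. Periodic coordinates are
wrapped by the owning system; bisection runs at most 50 iterations;
weight degeneracies (all-zero, NaN or +∞ weights) abort the run with a
diagnostic rather than silently continuing.

## What the toys do and do not show

The analytic systems exercise every algorithmic component — adaptive
schedule placement, decorrelation control, resampling, the ledger, and
cross-replicate reweighting — against exact references, with one to
three degrees of freedom. They do not emulate the features that make
real molecular applications hard: high-dimensional environment
relaxation orthogonal to the alchemical DOFs, rugged coupled
landscapes, force-field energetics, or long-timescale conformational
gating. Passing here demonstrates correctness of the machinery and the
qualitative phenomena that are machinery-driven (effort scaling with
barrier height, diversity loss, the unified-protocol overlap
pathology), not quantitative performance on proteins.
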