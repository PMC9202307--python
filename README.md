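# alchemsmc

Adaptive alchemical sequential Monte Carlo (sequential importance
resampling) for exploring targeted degrees of freedom, implemented and
validated on analytic potential systems.

## The problem

Sampling multimodal Boltzmann distributions — torsional rotamers,
ligand binding modes, side-chain states — is hard because the modes are
separated by kinetic barriers that ordinary dynamics crosses
exponentially rarely. The alchemical route sidesteps the barriers:
switch off the interactions governing the interesting degrees of
freedom so that, at coupling parameter λ = 0, those coordinates are
*uniform* and trivially sampleable, then anneal a population of
configurations ("walkers") back to the physical distribution at λ = 1
through a sequence of intermediate distributions

$$\pi(\lambda, \vec x) \propto e^{-u(\lambda, \vec x)},$$

where $u = U/k_BT$ is the dimensionless potential. Each iteration of
the sequential importance resampling (SIR) loop has three stages:

1. **Sampling** — Metropolis Monte Carlo decorrelates the walkers at
   the current λ, terminated adaptively when the Pearson correlation
   $r_\tau$ between initial and current walker energies satisfies
   $|r_\tau| \le 0.1$.
2. **Reweighting** — importance weights toward the next distribution,
   $\tilde w_j = e^{-[u(\lambda_{i+1},\vec x_j) - u(\lambda_i,\vec x_j)]}$.
   The next λ is *not* fixed a priori: a bisection search places it so
   that a configurational-overlap metric of the normalized weights hits
   a constant target (default 0.5). Two metrics are available: the
   effective-sample-size ratio
   $R_\mathrm{ESS} = 1/(N\sum_j \bar w_j^2)$ and the conservative
   lower bound $R_\mathrm{min} = 1/(N\max_j \bar w_j)$ (the default).
3. **Resampling** — systematic resampling with a single uniform offset
   copies high-weight walkers and annihilates low-weight ones, with
   every count guaranteed to lie within floor/ceil of the fractional
   allocation $M\bar w_j$.

The mean unnormalized weight of each step is an unbiased estimate of
the partition-function ratio $Z(\lambda_{i+1})/Z(\lambda_i)$ (Zwanzig
identity); the running product yields the run's collective weight
$\hat Z \approx Z(1)/Z(0)$, whose negative logarithm is the
*dimensionless free energy*. Independent replicates are combined by
weighting each run's final samples with its $\hat Z$:

$$\langle O \rangle = \frac{\sum_k \hat Z_k \bar O_k}{\sum_k \hat Z_k}.$$

Because more dissimilar endpoint distributions automatically receive
more intermediate λ values at the same overlap target, the same
hyperparameters transfer across problems of very different difficulty.

The package provides the full engine (walker bookkeeping, overlap and
decorrelation diagnostics, systematic/multinomial resamplers,
low-discrepancy λ = 0 generators for torsions, rigid-body rotations
and translations, the adaptive run loop, cross-replicate estimators and
a brute-force quadrature oracle), together with analytic toy systems —
a cosine-series torsional potential, a Gaussian ladder with closed-form
free energy, and a soft-core Lennard-Jones/Coulomb pair in a periodic
box supporting both split and unified coupling protocols — so every
claim is checkable against exact results.

## Worked example

A torsional toy with both one-fold and two-fold cosine terms
(`a = 2, b = 0` would be butene-like; here `a = 2, b = 2` adds a
metastable cis well). `run.yaml`:

```yaml
system:
  name: torsional_toy
  params: {a: 2.0, b: 2.0}
move:
  kind: torsion
smc:
  n_walkers: 100
  oversample_factor: 2
  propagation_block: 10
  max_propagation_blocks: 10
```

```text
$ smc run --config run.yaml --seed 7 --out run7.h5
steps=2 log_Z_ratio=-2.931214 dimensionless_free_energy=2.931214
step=0 lambda=0.4375 r_ess=0.741 r_min=0.504 tau=10 ln_mean_weight=-1.4501
step=1 lambda=1.0000 r_ess=0.797 r_min=0.609 tau=30 ln_mean_weight=-1.4812
```

The adaptive schedule needed one intermediate distribution
(λ = 0.4375), placed so the achieved overlap metric `r_min = 0.504`
sits at the 0.5 target within the bisection tolerance; the final step
only has to clear the target. `tau` is the number of Metropolis sweeps
spent decorrelating at each λ, and the summed `ln_mean_weight` column
is the free-energy ledger.

Analysis against a second replicate, with states defined by angle
intervals in `states.yaml` (trans: φ ∈ [π/2, 3π/2), cis: the
complementary arc):

```text
$ smc analyze --runs run7.h5 --runs run8.h5 --states states.yaml
state,weighted_mean,weighted_std,run0,run1
trans,0.803615686398,0.0353553390593,0.83,0.78
cis,0.196384313602,0.0353553390593,0.17,0.22
dimensionless_free_energy=2.875785 +- 0.078389 (unweighted)

$ smc oracle --config run.yaml --states states.yaml
Z(1)/Z(0)=0.0563022056 minus_ln_ratio=2.877021569
population[trans]=0.7810908501
population[cis]=0.2189091499
```

The Ẑ-weighted trans population (80.4 ± 3.5%) and the dimensionless
free energy (2.88 ± 0.08) from two 100-walker replicates agree with the
exact quadrature values (78.1% and 2.877) within their uncertainties.
`smc schedule --from run7.h5` exports the adapted λ schedule as CSV for
reuse by other methods, and `smc fixtures` writes three tiny seeded
reference runs.

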