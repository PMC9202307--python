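"""The adaptive sequential-importance-resampling loop.

Each iteration has three stages — sampling, reweighting, resampling:

1. *Sampling.*  A Metropolis random-walk propagator runs in blocks at
   the current lambda until the Pearson correlation between the initial
   and current walker energies satisfies |r_tau| <= threshold (adaptive
   sampling length), with a hard block cap so flat landscapes never
   loop forever.
2. *Reweighting.*  The next lambda is placed adaptively: candidate
   importance weights w_j = exp(-[u(lam', x_j) - u(lam, x_j)]) need
   only energy re-evaluations, so a bisection search finds the lam'
   whose overlap metric (R_min by default) hits the configured target.
   The mean unnormalized weight is the step's unbiased estimate of
   Z(lam')/Z(lam) (Zwanzig identity), accumulated into ln Zhat.
3. *Resampling.*  Systematic resampling with a single uniform offset
   turns the normalized weights into copy counts; high-weight walkers
   are duplicated and low-weight walkers annihilated.

The loop starts from an exact, oversampled lambda=0 population and ends
with a final decorrelation run at lambda=1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .ensemble import (
    DecorrelationReport,
    DegenerateWeightsError,
    Ensemble,
    RunRecord,
    normalize_weights,
)
from .lambda0 import Lambda0MoveSpec, initial_population
from .overlap import (
    DegenerateEnergiesError,
    conservative_min_metric,
    energy_decorrelation,
    ess_metric,
    overlap_report,
)
from .resampling import apply_counts, systematic_resample
from .systems import CouplingProtocol, PotentialSystem

__all__ = [
    "SMCConfig",
    "metropolis_sweep",
    "propagate_until_decorrelated",
    "find_next_lambda",
    "smc_run",
]

logger = logging.getLogger("alchemsmc")

# purpose codes for counter-based child seeding: a master seed plus
# (step, purpose) always yields the same stream, so adding a diagnostic
# never perturbs downstream randomness.
_SEED_INIT, _SEED_PROP, _SEED_RESAMPLE, _SEED_FINAL = 0, 1, 2, 3


@dataclass(frozen=True)
class SMCConfig:
    """Hyperparameters of one SMC replicate.

    Defaults follow the reference operating point: 500 walkers with a
    100-fold oversampled initial pool, |r_tau| <= 0.1 decorrelation,
    a constant configurational-overlap target of 0.5 on the
    conservative R_min metric, and energy-decorrelation checks every
    ``propagation_block`` Metropolis sweeps.
    """

    n_walkers: int = 500
    oversample_factor: int = 100
    overlap_target: float = 0.5
    overlap_metric: str = "r_min"  # or "r_ess"
    decorrelation_threshold: float = 0.1
    bisection_tolerance: float = 0.01
    max_bisection_iterations: int = 50
    propagation_block: int = 100
    max_propagation_blocks: int = 100
    rng_seed: int = 0
    protocol: CouplingProtocol = field(default_factory=CouplingProtocol)
    step_sizes: tuple[float, ...] | None = None  # per-DOF; None = system default
    reuse_schedule: tuple[float, ...] | None = None  # fixed-schedule replay
    skip_resample_when_uniform: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_target < 1.0:
            raise ValueError("overlap_target must lie in (0, 1)")
        if not 0.0 < self.decorrelation_threshold < 1.0:
            raise ValueError("decorrelation_threshold must lie in (0, 1)")
        if self.overlap_metric not in ("r_min", "r_ess"):
            raise ValueError("overlap_metric must be 'r_min' or 'r_ess'")
        if self.n_walkers < 1 or self.oversample_factor < 1:
            raise ValueError("n_walkers and oversample_factor must be >= 1")
        if self.reuse_schedule is not None:
            s = np.asarray(self.reuse_schedule, dtype=float)
            if s[0] != 0.0 or s[-1] != 1.0 or np.any(np.diff(s) <= 0):
                raise ValueError("reuse_schedule must increase strictly from 0 to 1")

    def metric_fn(self):
        return conservative_min_metric if self.overlap_metric == "r_min" else ess_metric


def _child_rng(master_seed: int, step: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng([int(master_seed), int(step), int(purpose)])


def _energies(system: PotentialSystem, ensemble: Ensemble) -> np.ndarray:
    if ensemble.energies is None:
        ensemble.energies = np.asarray(
            system.energy(ensemble.lam, ensemble.coords), dtype=float
        )
    return ensemble.energies


def metropolis_sweep(
    ensemble: Ensemble,
    system: PotentialSystem,
    step_sizes,
    rng_seed,
) -> Ensemble:
    """One symmetric random-walk proposal + accept/reject per walker per DOF.

    Gaussian proposals of scale ``step_sizes[d]`` are applied one degree
    of freedom at a time (vectorized over walkers); periodic DOFs are
    wrapped by the system.  Leaves the Boltzmann distribution at the
    ensemble's lam invariant.  Mutates and returns the ensemble.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    steps = np.asarray(step_sizes, dtype=float)
    if steps.shape == ():
        steps = np.full(ensemble.dimensionality, float(steps))
    if np.any(steps < 0):
        raise ValueError("step sizes must be >= 0")
    coords = ensemble.coords
    u = _energies(system, ensemble)
    n = ensemble.n_walkers
    for d in range(ensemble.dimensionality):
        if steps[d] == 0.0:
            continue
        proposal = coords.copy()
        proposal[:, d] += rng.normal(0.0, steps[d], size=n)
        proposal = system.wrap(proposal)
        u_new = np.asarray(system.energy(ensemble.lam, proposal), dtype=float)
        with np.errstate(over="ignore"):
            accept = rng.random(n) < np.exp(np.minimum(u - u_new, 0.0))
        coords[accept] = proposal[accept]
        u[accept] = u_new[accept]
    ensemble.coords = coords
    ensemble.energies = u
    return ensemble


def propagate_until_decorrelated(
    ensemble: Ensemble,
    system: PotentialSystem,
    config: SMCConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Ensemble, DecorrelationReport]:
    """Run Metropolis blocks until the energy decorrelation criterion holds.

    After each block of ``config.propagation_block`` sweeps the Pearson
    correlation between the block-0 energies and the current energies is
    evaluated; propagation stops at |r_tau| <= threshold or at the block
    cap (with a warning).  Constant-energy (degenerate) populations are
    flagged decorrelated immediately after the first block.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    steps = (
        np.asarray(config.step_sizes, dtype=float)
        if config.step_sizes is not None
        else system.proposal_scales()
    )
    u0 = _energies(system, ensemble).copy()
    tau = 0
    report: DecorrelationReport | None = None
    for _ in range(config.max_propagation_blocks):
        for _ in range(config.propagation_block):
            metropolis_sweep(ensemble, system, steps, rng)
        tau += config.propagation_block
        try:
            report = energy_decorrelation(u0, _energies(system, ensemble), tau=tau)
        except DegenerateEnergiesError:
            logger.warning(
                "degenerate energies at lam=%.4f: treating as decorrelated",
                ensemble.lam,
            )
            report = DecorrelationReport(tau=tau, r_tau=0.0, degenerate=True)
            break
        if abs(report.r_tau) <= config.decorrelation_threshold:
            break
    else:
        logger.warning(
            "decorrelation cap reached at lam=%.4f (r_tau=%.3f)",
            ensemble.lam,
            report.r_tau if report is not None else float("nan"),
        )
    assert report is not None
    return ensemble, report


def _candidate_log_weights(
    system: PotentialSystem, ensemble: Ensemble, u_cur: np.ndarray, lam_next: float
) -> np.ndarray:
    u_next = np.asarray(system.energy(lam_next, ensemble.coords), dtype=float)
    return -(u_next - u_cur)


def _metric_from_logw(logw: np.ndarray, metric_fn) -> float:
    # -inf log-weights are legal (zero weight); +inf, nan, or all -inf are not
    if np.any(np.isnan(logw)) or np.any(logw == np.inf) or np.max(logw) == -np.inf:
        raise DegenerateWeightsError("degenerate weights")
    w = np.exp(logw - np.max(logw))
    return metric_fn(w / w.sum())


def find_next_lambda(
    ensemble: Ensemble,
    system: PotentialSystem,
    lam_current: float,
    config: SMCConfig,
) -> float:
    """Bisection placement of the next lambda by overlap control.

    Returns 1.0 outright when the overlap metric at lam'=1 already meets
    the target (final-step rule); otherwise bisects on (lam_current, 1]
    until the metric is within ``bisection_tolerance`` of the target.
    Only energy re-evaluations are performed — no dynamics.  If the
    metric is non-monotone and the bracket fails, falls back to the
    smallest tested lambda meeting the target, with a warning.
    """
    if not 0.0 <= lam_current < 1.0:
        raise ValueError("lam_current must lie in [0, 1)")
    metric_fn = config.metric_fn()
    u_cur = _energies(system, ensemble)

    def metric_at(lam_next: float) -> float:
        return _metric_from_logw(
            _candidate_log_weights(system, ensemble, u_cur, lam_next), metric_fn
        )

    target, tol = config.overlap_target, config.bisection_tolerance
    if metric_at(1.0) >= target:
        return 1.0
    lo, hi = lam_current, 1.0
    passing: list[float] = []
    for _ in range(config.max_bisection_iterations):
        mid = 0.5 * (lo + hi)
        m = metric_at(mid)
        if m >= target:
            passing.append(mid)
        if abs(m - target) <= tol:
            return mid
        if m > target:
            lo = mid
        else:
            hi = mid
    if passing:
        logger.warning("bisection bracket failed; using smallest passing lambda")
        return min(passing)
    logger.warning("bisection bracket failed; no passing lambda, using upper bracket")
    return hi


def smc_run(
    system: PotentialSystem,
    spec: Lambda0MoveSpec,
    config: SMCConfig,
) -> RunRecord:
    """One complete adaptive SMC replicate from lambda=0 to lambda=1.

    Workflow: exact oversampled initial population at lambda=0, then
    repeat {propagate to decorrelation; place next lambda; reweight;
    systematic resample} until lambda=1, then a final decorrelation run
    at lambda=1.  Returns the full :class:`RunRecord` trace.
    """
    seed = int(config.rng_seed)
    ensemble = initial_population(
        system,
        spec,
        config.n_walkers,
        config.oversample_factor,
        rng_seed=_child_rng(seed, 0, _SEED_INIT),
    )
    schedule = [0.0]
    overlaps = []
    decors = []
    weight_means = []
    distinct = []
    log_z = 0.0
    fixed = None if config.reuse_schedule is None else list(config.reuse_schedule)
    step = 0
    lam = 0.0
    while lam < 1.0:
        step += 1
        ensemble, dec = propagate_until_decorrelated(
            ensemble, system, config, rng=_child_rng(seed, step, _SEED_PROP)
        )
        if fixed is not None:
            lam_next = fixed[len(schedule)]
        else:
            lam_next = find_next_lambda(ensemble, system, lam, config)
        u_cur = _energies(system, ensemble)
        logw = _candidate_log_weights(system, ensemble, u_cur, lam_next)
        if np.any(np.isnan(logw)) or np.any(logw == np.inf) or np.max(logw) == -np.inf:
            raise DegenerateWeightsError(
                f"degenerate weights at step {step} (lam {lam:.4f} -> {lam_next:.4f}); "
                f"energy range [{u_cur.min():.3g}, {u_cur.max():.3g}]"
            )
        # ln mean unnormalized weight via logsumexp (overflow-safe)
        ln_mean = float(logsumexp(logw) - np.log(logw.size))
        wv = normalize_weights(np.exp(logw - np.max(logw)))
        log_z += ln_mean
        overlaps.append(overlap_report(wv.normalized))
        decors.append(dec)
        weight_means.append(float(np.exp(ln_mean)))
        uniform = np.allclose(wv.normalized, 1.0 / wv.normalized.size)
        if config.skip_resample_when_uniform and uniform and (
            ensemble.n_walkers == config.n_walkers
        ):
            resampled = ensemble
        else:
            counts = systematic_resample(
                wv.normalized,
                config.n_walkers,
                _child_rng(seed, step, _SEED_RESAMPLE),
            )
            resampled = apply_counts(ensemble, counts)
        u_next = np.asarray(system.energy(lam_next, resampled.coords), dtype=float)
        ensemble = Ensemble(
            resampled.coords,
            lam_next,
            ancestor_ids=resampled.ancestor_ids,
            energies=u_next,
        )
        distinct.append(int(np.unique(ensemble.ancestor_ids).size))
        schedule.append(float(lam_next))
        lam = lam_next
    ensemble, final_dec = propagate_until_decorrelated(
        ensemble, system, config, rng=_child_rng(seed, step + 1, _SEED_FINAL)
    )
    # reconcile the stored mean weights with the ledger identity exactly
    log_z = float(np.sum(np.log(weight_means)))
    return RunRecord(
        schedule=schedule,
        step_overlaps=overlaps,
        step_decorrelation=decors,
        step_weight_means=weight_means,
        log_Z_ratio=log_z,
        final_ensemble=ensemble,
        seed=seed,
        final_decorrelation=final_dec,
        step_distinct_ancestors=distinct,
    )
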