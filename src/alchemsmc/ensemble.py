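"""Domain types shared across the sampler.

A *walker* is one configuration of the system; an *ensemble* is the
population of N walkers at a common coupling parameter ``lam``
(:math:`\\lambda \\in [0, 1]`).  All energies are dimensionless
(:math:`u = U/k_BT`); temperature never appears explicitly.

The per-step importance weights, overlap diagnostics, decorrelation
diagnostics and the full run trace each get a small record type so that
every quantity the engine logs has a single well-defined home.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Walker",
    "Ensemble",
    "WeightVector",
    "OverlapReport",
    "DecorrelationReport",
    "RunRecord",
    "ObservableEstimate",
    "make_ensemble",
    "normalize_weights",
    "DegenerateWeightsError",
]

_WEIGHT_SUM_TOL = 1e-12


class DegenerateWeightsError(ValueError):
    """All importance weights vanished: catastrophic overlap failure."""


@dataclass
class Walker:
    """One configuration plus bookkeeping.

    Parameters
    ----------
    coordinates : ndarray, shape (D,)
        One value per degree of freedom (radians for angles, lengths in
        the system's units otherwise).
    energy_cache : float or None
        Dimensionless potential at the owning ensemble's current lam,
        or None when stale.
    ancestor_id : int
        Lineage tag tracing back to the initial population; preserved
        through resampling copies so diversity loss can be measured.
    """

    coordinates: np.ndarray
    energy_cache: float | None = None
    ancestor_id: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_1d(np.asarray(self.coordinates, dtype=float))


class Ensemble:
    """Population of N walkers at a common coupling parameter.

    Internally the coordinates are stored as a dense ``(N, D)`` array so
    that toy-system energies vectorize; the ``walkers`` property exposes
    the per-walker view.
    """

    def __init__(
        self,
        coords: np.ndarray,
        lam: float,
        ancestor_ids: np.ndarray | None = None,
        weights: np.ndarray | None = None,
        energies: np.ndarray | None = None,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 1:
            coords = coords[:, None]
        if coords.shape[0] == 0:
            raise ValueError("empty ensemble")
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda out of range")
        self.coords = coords
        self.lam = float(lam)
        n = coords.shape[0]
        if ancestor_ids is None:
            ancestor_ids = np.arange(n, dtype=np.int64)
        self.ancestor_ids = np.asarray(ancestor_ids, dtype=np.int64)
        if self.ancestor_ids.shape != (n,):
            raise ValueError("ancestor_ids length mismatch")
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            if weights.shape != (n,):
                raise ValueError("weights length mismatch")
            if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
                raise ValueError("weights must be normalized and non-negative")
        self.weights = weights
        self.energies = None if energies is None else np.asarray(energies, dtype=float)

    @property
    def n_walkers(self) -> int:
        return self.coords.shape[0]

    @property
    def dimensionality(self) -> int:
        return self.coords.shape[1]

    @property
    def walkers(self) -> list[Walker]:
        e = self.energies
        return [
            Walker(
                coordinates=self.coords[j].copy(),
                energy_cache=None if e is None else float(e[j]),
                ancestor_id=int(self.ancestor_ids[j]),
            )
            for j in range(self.n_walkers)
        ]

    def invalidate_energies(self) -> None:
        self.energies = None

    def copy(self) -> "Ensemble":
        return Ensemble(
            self.coords.copy(),
            self.lam,
            self.ancestor_ids.copy(),
            None if self.weights is None else self.weights.copy(),
            None if self.energies is None else self.energies.copy(),
        )


def make_ensemble(walkers: list[Walker], lam: float) -> Ensemble:
    """Build an :class:`Ensemble` from walkers with uniform implicit weights.

    Energy caches are invalidated (the ensemble's lam need not match the
    lam at which the caches were filled).
    """
    if len(walkers) == 0:
        raise ValueError("empty ensemble")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda out of range")
    dims = {np.atleast_1d(w.coordinates).shape[0] for w in walkers}
    if len(dims) != 1:
        raise ValueError("walkers are not dimensionally consistent")
    coords = np.stack([np.atleast_1d(np.asarray(w.coordinates, float)) for w in walkers])
    ancestors = np.array([w.ancestor_id for w in walkers], dtype=np.int64)
    return Ensemble(coords, lam, ancestor_ids=ancestors)


@dataclass(frozen=True)
class WeightVector:
    """Importance weights for one annealing step.

    ``unnormalized`` holds the relative transition probabilities
    :math:`\\tilde w_j = e^{-[u(\\lambda_{i+1},x_j) - u(\\lambda_i,x_j)]}`;
    their arithmetic mean is the step's partition-function-ratio
    estimate (Zwanzig identity), and ``normalized`` feeds resampling.
    """

    unnormalized: np.ndarray
    normalized: np.ndarray
    mean_unnormalized: float

    def __post_init__(self) -> None:
        s = float(self.normalized.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError("normalized weights do not sum to 1")


def normalize_weights(unnormalized: np.ndarray) -> WeightVector:
    """Normalize raw transition probabilities into importance weights.

    Raises
    ------
    ValueError
        ``"invalid weight"`` for negative or non-finite entries,
        :class:`DegenerateWeightsError` (``"degenerate weights"``) when
        every entry is zero — the signature of a catastrophic overlap
        failure between consecutive distributions.
    """
    w = np.asarray(unnormalized, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("invalid weight")
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("invalid weight")
    total = w.sum()
    if total == 0.0:
        raise DegenerateWeightsError("degenerate weights")
    return WeightVector(
        unnormalized=w.copy(),
        normalized=w / total,
        mean_unnormalized=float(w.mean()),
    )


@dataclass(frozen=True)
class OverlapReport:
    """Configurational-overlap diagnostics for one annealing step.

    ``r_min <= r_ess`` always (the max-weight bound is the conservative
    one); both equal 1 exactly at uniform weights.
    """

    r_ess: float
    r_min: float


@dataclass(frozen=True)
class DecorrelationReport:
    """Outcome of the adaptive sampling-length loop at one lam value.

    ``tau`` counts elapsed propagation sweeps; ``r_tau`` is the Pearson
    correlation between the walker energies at sweep 0 and at sweep tau.
    ``degenerate`` marks the constant-energy case where the correlation
    is undefined and the engine declares decorrelation by fiat.
    """

    tau: int
    r_tau: float
    degenerate: bool = False


@dataclass
class RunRecord:
    """Complete trace of one SMC replicate.

    ``log_Z_ratio`` is ln(Zhat) where Zhat estimates Z(1)/Z(0); the
    ledger identity ``log_Z_ratio == sum(ln step_weight_means)`` is
    bookkeeping, not statistics, and is enforced on construction.
    """

    schedule: list[float]
    step_overlaps: list[OverlapReport]
    step_decorrelation: list[DecorrelationReport]
    step_weight_means: list[float]
    log_Z_ratio: float
    final_ensemble: Ensemble
    seed: int
    final_decorrelation: DecorrelationReport | None = None
    step_distinct_ancestors: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        sched = np.asarray(self.schedule, dtype=float)
        if sched[0] != 0.0 or sched[-1] != 1.0 or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must increase strictly from 0 to 1")
        ledger = float(np.sum(np.log(self.step_weight_means)))
        if abs(ledger - self.log_Z_ratio) > 1e-9 * max(1.0, abs(ledger)):
            raise ValueError("log_Z_ratio does not match the step ledger")

    @property
    def n_steps(self) -> int:
        return len(self.step_weight_means)

    def summary_frame(self) -> pd.DataFrame:
        """Flat per-step summary: step, lambda, r_ess, r_min, tau, ln_mean_weight.

        ``lambda`` is the value reached by the step; ``tau`` the number of
        propagation sweeps spent decorrelating before reweighting.
        """
        return pd.DataFrame(
            {
                "step": np.arange(self.n_steps, dtype=int),
                "lambda": np.asarray(self.schedule[1:], dtype=float),
                "r_ess": [o.r_ess for o in self.step_overlaps],
                "r_min": [o.r_min for o in self.step_overlaps],
                "tau": [d.tau for d in self.step_decorrelation],
                "ln_mean_weight": np.log(np.asarray(self.step_weight_means)),
            }
        )


@dataclass
class ObservableEstimate:
    """Cross-replicate weighted estimate of one observable.

    ``value`` is the collective-weight (Zhat) weighted mean of the
    per-run means; ``weighted_std`` uses the same weights with the
    frequency-type small-sample correction.
    """

    value: float
    weighted_std: float
    per_run_means: np.ndarray
    per_run_Z: np.ndarray

    @property
    def n_runs(self) -> int:
        return self.per_run_means.size

    @property
    def weighted_se(self) -> float:
        """Standard error of ``value``: weighted_std / sqrt(K_eff).

        K_eff = (sum Z)^2 / sum Z^2 is the effective number of replicates
        under the Zhat weights.
        """
        z = self.per_run_Z
        k_eff = z.sum() ** 2 / np.sum(z**2)
        return self.weighted_std / np.sqrt(k_eff)
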