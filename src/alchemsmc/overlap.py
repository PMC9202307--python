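"""Configurational-overlap and decorrelation diagnostics.

Two normalized-weight diagnostics drive the adaptive lambda schedule:
the relative effective sample size

    R_ESS = 1 / (N * sum_j w_j^2),

and the conservative max-weight lower bound

    R_min = 1 / (N * max_j w_j),

both in (0, 1], equal to 1 exactly at uniform weights and to 1/N at
full degeneracy, with R_min <= R_ESS always.  The adaptive sampling
length at each lambda is controlled by the Pearson correlation r_tau
between the initial and current walker energies: once |r_tau| drops
below a threshold the population is declared locally decorrelated.
"""

from __future__ import annotations

import numpy as np

from .ensemble import DecorrelationReport, OverlapReport

__all__ = [
    "ess_metric",
    "conservative_min_metric",
    "overlap_report",
    "energy_decorrelation",
    "DegenerateEnergiesError",
]

_NORM_TOL = 1e-8


class DegenerateEnergiesError(ValueError):
    """Zero-variance energies: the decorrelation coefficient is undefined."""


def _check_normalized(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights not normalized")
    if np.any(w < 0) or abs(w.sum() - 1.0) > _NORM_TOL:
        raise ValueError("weights not normalized")
    return w


def ess_metric(normalized_weights: np.ndarray) -> float:
    """Relative effective sample size R_ESS = 1 / (N * sum w^2)."""
    w = _check_normalized(normalized_weights)
    return float(1.0 / (w.size * np.sum(w**2)))


def conservative_min_metric(normalized_weights: np.ndarray) -> float:
    """Max-weight lower bound R_min = 1 / (N * max w); R_min <= R_ESS."""
    w = _check_normalized(normalized_weights)
    return float(1.0 / (w.size * np.max(w)))


def overlap_report(normalized_weights: np.ndarray) -> OverlapReport:
    """Both overlap diagnostics for one weight vector."""
    return OverlapReport(
        r_ess=ess_metric(normalized_weights),
        r_min=conservative_min_metric(normalized_weights),
    )


def energy_decorrelation(
    initial_energies: np.ndarray,
    current_energies: np.ndarray,
    tau: int = 0,
) -> DecorrelationReport:
    """Pearson correlation between initial and current walker energies.

    Raises :class:`DegenerateEnergiesError` when either vector has zero
    variance (flat landscape); the engine treats that case as
    decorrelated with a logged warning, never as an infinite loop.
    """
    u0 = np.asarray(initial_energies, dtype=float)
    u1 = np.asarray(current_energies, dtype=float)
    if u0.shape != u1.shape or u0.ndim != 1 or u0.size < 3:
        raise ValueError("energy vectors must share a length >= 3")
    if np.var(u0) == 0.0 or np.var(u1) == 0.0:
        raise DegenerateEnergiesError("degenerate energies: decorrelation undefined")
    r = float(np.corrcoef(u0, u1)[0, 1])
    return DecorrelationReport(tau=int(tau), r_tau=r)
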