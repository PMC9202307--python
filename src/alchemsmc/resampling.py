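"""Weighted resampling with replacement.

Systematic resampling (the default) draws a single uniform offset
u ~ U[0,1) and places M equally spaced selection points (u + k)/M over
the cumulative weight profile.  It guarantees each walker receives
between floor(M*w_j) and ceil(M*w_j) copies — the most deterministic of
the standard schemes, chosen to minimize irreversible diversity loss.
Multinomial resampling (M independent categorical draws) is kept as the
higher-variance baseline.
"""

from __future__ import annotations

import numpy as np

from .ensemble import Ensemble

__all__ = ["systematic_resample", "multinomial_resample", "apply_counts"]


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _check_inputs(normalized_weights, M: int) -> np.ndarray:
    w = np.asarray(normalized_weights, dtype=float)
    if w.ndim != 1 or w.size == 0 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights not normalized")
    if M < 1:
        raise ValueError("invalid target count")
    return w


def systematic_resample(normalized_weights, M: int, rng_seed) -> np.ndarray:
    """Systematic resampling: counts_j in {floor(M*w_j), ceil(M*w_j)}.

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``;
    the scheme consumes exactly one uniform variate.
    """
    w = _check_inputs(normalized_weights, M)
    rng = _as_rng(rng_seed)
    u = rng.random()
    points = (u + np.arange(M)) / M
    cum = np.cumsum(w)
    cum[-1] = 1.0  # guard rounding so every point lands in a bin
    idx = np.searchsorted(cum, points, side="right")
    return np.bincount(idx, minlength=w.size).astype(np.int64)


def multinomial_resample(normalized_weights, M: int, rng_seed) -> np.ndarray:
    """Multinomial resampling: counts ~ Multinomial(M, w)."""
    w = _check_inputs(normalized_weights, M)
    rng = _as_rng(rng_seed)
    return rng.multinomial(M, w / w.sum()).astype(np.int64)


def apply_counts(ensemble: Ensemble, counts) -> Ensemble:
    """Materialize resampling counts into a new equally weighted ensemble.

    High-count walkers are copied (independent coordinate copies, not
    aliases), zero-count walkers are annihilated.  Lineage tags and
    energy caches (still valid: lam and coordinates are unchanged)
    propagate through the copies.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (ensemble.n_walkers,):
        raise ValueError("count/ensemble mismatch")
    if counts.sum() < 1:
        raise ValueError("invalid target count")
    coords = np.repeat(ensemble.coords, counts, axis=0).copy()
    ancestors = np.repeat(ensemble.ancestor_ids, counts)
    energies = (
        None
        if ensemble.energies is None
        else np.repeat(ensemble.energies, counts).copy()
    )
    return Ensemble(coords, ensemble.lam, ancestor_ids=ancestors, energies=energies)
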