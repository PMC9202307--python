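"""Exact low-discrepancy generation of the uniform lambda=0 distribution.

At full decoupling the targeted degrees of freedom are exactly uniform
over simple supports (a circle for torsions, the unit sphere plus a
spin for rigid-body rotations, a cube or ball for translations), so
they are sampled directly rather than by dynamics.  Each scalar degree
of freedom uses a shifted grid — n equally spaced points with a single
pseudo-random offset — whose one-dimensional star discrepancy is O(1/n)
(max gap equals min gap); different degrees of freedom are shuffled
independently so their grids do not align.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import Ensemble
from .systems import TWO_PI, PotentialSystem

__all__ = [
    "Lambda0MoveSpec",
    "torsion_samples",
    "rotation_samples",
    "rotation_matrices",
    "translation_samples_cube",
    "translation_samples_sphere",
    "initial_population",
]

MOVE_KINDS = (
    "torsion",
    "com_rotation",
    "com_translation_cube",
    "com_translation_sphere",
    "direct",
)


@dataclass
class Lambda0MoveSpec:
    """Declaration of the lambda=0 move generating the decoupled DOFs.

    ``kind="direct"`` delegates to the system's own exact lambda=0
    sampler (used by systems whose decoupled marginal is not uniform,
    e.g. the Gaussian ladder).  ``radius`` applies to spherical
    translations, ``half_widths`` to cubic ones.
    """

    kind: str = "torsion"
    radius: float = 1.0
    half_widths: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind not in MOVE_KINDS:
            raise ValueError(f"unknown move kind '{self.kind}'")
        if self.radius <= 0 or any(h <= 0 for h in self.half_widths):
            raise ValueError("move region must have positive extent")


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _offset_grid(n: int, rng: np.random.Generator, shuffle: bool) -> np.ndarray:
    """Shifted grid on [0, 1): (k + delta)/n with one uniform offset."""
    if n < 1:
        raise ValueError("n must be >= 1")
    x = (np.arange(n) + rng.random()) / n
    if shuffle:
        rng.shuffle(x)
    return x


def torsion_samples(n: int, rng_seed) -> np.ndarray:
    """Equally spaced angles on [0, 2pi) with a pseudo-random offset.

    phi_k = (2pi*k/n + delta) mod 2pi, delta ~ U[0, 2pi); marginally
    uniform with pairwise minimum circular gap exactly 2pi/n.
    """
    rng = _as_rng(rng_seed)
    return TWO_PI * _offset_grid(n, rng, shuffle=False)


def rotation_samples(n: int, rng_seed) -> np.ndarray:
    """Uniform rigid-body rotation variables as (theta, phi, psi) triples.

    phi (azimuth of the new axis direction) and psi (spin) come from
    independently shuffled offset grids on [0, 2pi); theta comes from an
    offset grid X on [0, 1) through theta = arccos(2X - 1), which makes
    cos(theta) uniform on [-1, 1] and hence the axis direction uniform
    on the unit sphere.
    """
    rng = _as_rng(rng_seed)
    x = _offset_grid(n, rng, shuffle=True)
    theta = np.arccos(2.0 * x - 1.0)
    phi = TWO_PI * _offset_grid(n, rng, shuffle=True)
    psi = TWO_PI * _offset_grid(n, rng, shuffle=True)
    return np.column_stack([theta, phi, psi])


def rotation_matrices(triples: np.ndarray) -> np.ndarray:
    """Compose (theta, phi, psi) triples into rotation matrices.

    The rotation first spins by psi about the body z-axis and then tilts
    that axis onto the sampled direction (theta, phi).  With the axis
    direction uniform on the sphere and psi uniform on [0, 2pi), this
    factorization carries the product of the three per-DOF uniform
    measures onto the invariant (Haar) measure of SO(3), so a rotated
    fixed vector is exactly uniform on the sphere.
    """
    t = np.atleast_2d(np.asarray(triples, dtype=float))
    theta, phi, psi = t[:, 0], t[:, 1], t[:, 2]
    ct, st = np.cos(theta), np.sin(theta)
    cf, sf = np.cos(phi), np.sin(phi)
    cp, sp = np.cos(psi), np.sin(psi)
    n = t.shape[0]
    rz = np.zeros((n, 3, 3))
    rz[:, 0, 0], rz[:, 0, 1] = cp, -sp
    rz[:, 1, 0], rz[:, 1, 1] = sp, cp
    rz[:, 2, 2] = 1.0
    # tilt: R_z(phi) @ R_y(theta) maps zhat to (st*cf, st*sf, ct)
    tilt = np.zeros((n, 3, 3))
    tilt[:, 0, 0] = cf * ct
    tilt[:, 0, 1] = -sf
    tilt[:, 0, 2] = cf * st
    tilt[:, 1, 0] = sf * ct
    tilt[:, 1, 1] = cf
    tilt[:, 1, 2] = sf * st
    tilt[:, 2, 0] = -st
    tilt[:, 2, 2] = ct
    return tilt @ rz


def translation_samples_cube(n: int, half_widths, rng_seed) -> np.ndarray:
    """Uniform positions in a cuboid centered at the origin.

    Reduced coordinates come from independently shuffled offset grids on
    [-1, 1) per axis, scaled by the half-widths.
    """
    rng = _as_rng(rng_seed)
    hw = np.asarray(half_widths, dtype=float)
    if np.any(hw <= 0):
        raise ValueError("half_widths must be positive")
    reduced = np.column_stack(
        [2.0 * _offset_grid(n, rng, shuffle=True) - 1.0 for _ in range(hw.size)]
    )
    return reduced * hw


def translation_samples_sphere(n: int, R: float, rng_seed) -> np.ndarray:
    """Uniform positions inside a sphere of radius R.

    Direction via (theta, phi) as in :func:`rotation_samples`; radius
    r = R * X**(1/3) for a grid-based X on [0, 1), the unique map whose
    radial CDF is (r/R)^3 — uniform density in the ball.
    """
    if R <= 0:
        raise ValueError("radius must be positive")
    rng = _as_rng(rng_seed)
    x_dir = _offset_grid(n, rng, shuffle=True)
    cos_theta = 2.0 * x_dir - 1.0
    sin_theta = np.sqrt(np.maximum(0.0, 1.0 - cos_theta**2))
    phi = TWO_PI * _offset_grid(n, rng, shuffle=True)
    r = R * _offset_grid(n, rng, shuffle=True) ** (1.0 / 3.0)
    return np.column_stack(
        [r * sin_theta * np.cos(phi), r * sin_theta * np.sin(phi), r * cos_theta]
    )


def _generate(spec: Lambda0MoveSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "torsion":
        return torsion_samples(n, rng)[:, None]
    if spec.kind == "com_rotation":
        return rotation_samples(n, rng)
    if spec.kind == "com_translation_cube":
        return translation_samples_cube(n, spec.half_widths, rng)
    if spec.kind == "com_translation_sphere":
        return translation_samples_sphere(n, spec.radius, rng)
    raise ValueError(f"unknown move kind '{spec.kind}'")


def initial_population(
    system: PotentialSystem,
    spec: Lambda0MoveSpec,
    n_walkers: int,
    oversample_factor: int = 1,
    rng_seed=0,
) -> Ensemble:
    """Oversampled lambda=0 population over the decoupled DOFs.

    Generates ``n_walkers * oversample_factor`` exact lambda=0 samples
    (all equally weighted by construction: u(0, .) is flat over the
    decoupled DOFs).  The full oversampled pool is returned; the first
    adaptive reweighting step operates on the pool and its resampling
    reduces the population to ``n_walkers``.
    """
    if n_walkers < 1 or oversample_factor < 1:
        raise ValueError("n_walkers and oversample_factor must be >= 1")
    rng = _as_rng(rng_seed)
    n_total = n_walkers * oversample_factor
    if spec.kind == "direct":
        try:
            coords = system.sample_lambda0(n_total, rng)
        except NotImplementedError as exc:
            raise ValueError("move incompatible with system") from exc
    else:
        if spec.kind not in system.decoupled_move_kinds:
            raise ValueError("move incompatible with system")
        coords = _generate(spec, n_total, rng)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape != (n_total, system.dimensionality):
        raise ValueError("move incompatible with system")
    return Ensemble(system.wrap(coords), lam=0.0)
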