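"""Analytic lambda-coupled potential systems.

Each system implements the contract ``energy(lam, x) -> u`` mapping the
coupling parameter :math:`\\lambda \\in [0,1]` and configurational
coordinates to a dimensionless potential :math:`u = U/k_BT`.  At
``lam=0`` the targeted degrees of freedom are decoupled (their marginal
is uniform over a declared support, or exactly sampleable); at
``lam=1`` the physical target distribution is recovered.

The soft-core effective distance (Beutler form, alpha = 0.5 by default)
removes the singularity of pair potentials at particle overlap for
partial coupling, which is what makes high-energy insertions cheap for
the sampler.  The split/unified coupling protocols mirror the two
standard ways of switching on sterics and electrostatics: consecutively
(sterics fully on at the switch point, electrostatics after) or
concurrently under soft-core forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SoftCoreParams",
    "CouplingProtocol",
    "softcore_effective_distance",
    "PotentialSystem",
    "ConstantPotential",
    "TorsionalToy",
    "GaussianLadder",
    "SoftCorePair",
    "SYSTEM_REGISTRY",
    "build_system",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SoftCoreParams:
    """Soft-core parameters: ``alpha`` (dimensionless) and the LJ
    particle-size parameter ``sigma_ij`` (length units)."""

    alpha: float = 0.5
    sigma_ij: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.sigma_ij <= 0:
            raise ValueError("sigma_ij must be > 0")


@dataclass(frozen=True)
class CouplingProtocol:
    """How sterics and electrostatics are switched on along lambda.

    mode="split": soft-core sterics ramp over [0, switch_point], then
    linear electrostatics on the bare distance over [switch_point, 1].
    mode="unified": both terms ramp concurrently, electrostatics on the
    soft-core effective distance.
    """

    mode: str = "split"
    switch_point: float = 0.8

    def __post_init__(self) -> None:
        if self.mode not in ("split", "unified"):
            raise ValueError("invalid protocol")
        if self.mode == "split" and not 0.0 < self.switch_point < 1.0:
            raise ValueError("switch_point must lie in (0, 1)")

    def sub_lambdas(self, lam):
        """Map global lam to (steric, electrostatic) sub-couplings."""
        lam = np.asarray(lam, dtype=float)
        if self.mode == "unified":
            return lam, lam
        s = self.switch_point
        return np.minimum(lam / s, 1.0), np.maximum((lam - s) / (1.0 - s), 0.0)


def softcore_effective_distance(r, lam, params: SoftCoreParams):
    """Soft-core effective distance r_eff = (alpha*sigma^6*(1-lam) + r^6)^(1/6).

    Equals ``r`` exactly at ``lam=1`` and stays strictly positive at
    ``r=0`` for ``lam<1`` and ``alpha>0``, removing the pair-potential
    singularity at particle overlap.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("invalid distance")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda out of range")
    if lam == 1.0:
        return r + 0.0
    return (params.alpha * params.sigma_ij**6 * (1.0 - lam) + r**6) ** (1.0 / 6.0)


class PotentialSystem:
    """Contract for lambda-coupled configurational systems.

    Subclasses define ``dimensionality``, ``energy(lam, x)`` (vectorized
    over a leading walker axis), the decoupled-DOF declaration consumed
    by the lambda=0 generators, per-DOF Metropolis proposal scales, and
    optionally a periodic wrap and a quadrature description for the
    brute-force oracle.
    """

    dimensionality: int = 1
    #: which lambda=0 move kinds generate this system's decoupled DOFs,
    #: e.g. ("torsion",) or ("com_translation_cube", "com_translation_sphere");
    #: empty tuple means no uniform decoupled DOFs.
    decoupled_move_kinds: tuple[str, ...] = ()

    def energy(self, lam: float, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def wrap(self, x: np.ndarray) -> np.ndarray:
        """Map coordinates back into the support (identity by default)."""
        return x

    def proposal_scales(self) -> np.ndarray:
        """Default per-DOF random-walk step sizes for the Metropolis mover."""
        return np.ones(self.dimensionality)

    def sample_lambda0(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Exact sampler of the lambda=0 distribution, if available."""
        raise NotImplementedError("system has no exact lambda=0 sampler")

    # --- oracle support -------------------------------------------------
    def quadrature_kind(self) -> str | None:
        """One of "circle", "line", "radial", or None if intractable."""
        return None


class ConstantPotential(PotentialSystem):
    """u == 0 everywhere: every lambda distribution is identical.

    The degenerate end-to-end check: the sampler must finish in a single
    step with log Z-ratio exactly 0.
    """

    dimensionality = 1
    decoupled_move_kinds = ("torsion",)

    def energy(self, lam, x):
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda out of range")
        x = np.asarray(x, dtype=float)
        return np.zeros(x.shape[0] if x.ndim > 1 else x.shape[:1] or (1,))

    def wrap(self, x):
        return np.mod(x, TWO_PI)

    def proposal_scales(self):
        return np.array([1.0])

    def quadrature_kind(self):
        return "circle"


class TorsionalToy(PotentialSystem):
    """Single dihedral angle with a cosine-series barrier.

    u(lam, phi) = lam * V(phi),  V(phi) = a*(1+cos phi) + b*(1+cos 2phi),
    a, b >= 0.  At lam=0 the angle is exactly uniform on [0, 2pi) (the
    alchemically decoupled state); ``a`` controls the cis/trans-style
    asymmetry and barrier height, ``b`` adds a two-fold term producing a
    symmetric double well on its own.
    """

    dimensionality = 1
    decoupled_move_kinds = ("torsion",)

    def __init__(self, a: float = 3.0, b: float = 0.0):
        if a < 0 or b < 0:
            raise ValueError("a and b must be >= 0")
        self.a = float(a)
        self.b = float(b)

    def barrier(self, phi):
        phi = np.asarray(phi, dtype=float)
        return self.a * (1.0 + np.cos(phi)) + self.b * (1.0 + np.cos(2.0 * phi))

    def energy(self, lam, x):
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda out of range")
        x = np.asarray(x, dtype=float)
        phi = x[..., 0] if x.ndim > 1 else x
        return lam * self.barrier(phi)

    def wrap(self, x):
        return np.mod(x, TWO_PI)

    def proposal_scales(self):
        return np.array([0.8])

    def quadrature_kind(self):
        return "circle"


class GaussianLadder(PotentialSystem):
    """Closed-form validation system: a Gaussian whose width interpolates
    linearly from s0 (lam=0) to s1 (lam=1).

    u(lam, x) = x^2 / (2 s(lam)^2), s(lam) = s0 + lam*(s1 - s0), so the
    exact dimensionless free energy is -ln Z(1)/Z(0) = ln(s0/s1).  The
    lam=0 marginal is N(0, s0^2), sampled exactly (move kind "direct").
    """

    dimensionality = 1
    decoupled_move_kinds = ()

    def __init__(self, s0: float = 2.0, s1: float = 1.0):
        if s0 <= 0 or s1 <= 0:
            raise ValueError("invalid width")
        self.s0 = float(s0)
        self.s1 = float(s1)

    def width(self, lam):
        return self.s0 + np.asarray(lam, dtype=float) * (self.s1 - self.s0)

    def energy(self, lam, x):
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda out of range")
        x = np.asarray(x, dtype=float)
        v = x[..., 0] if x.ndim > 1 else x
        s = self.width(lam)
        return v**2 / (2.0 * s**2)

    def proposal_scales(self):
        return np.array([min(self.s0, self.s1)])

    def sample_lambda0(self, n, rng):
        return rng.normal(0.0, self.s0, size=(n, 1))

    def exact_free_energy(self) -> float:
        """Exact -ln Z(1)/Z(0) = ln(s0/s1)."""
        return float(np.log(self.s0 / self.s1))

    def quadrature_kind(self):
        return "line"


class SoftCorePair(PotentialSystem):
    """One mobile particle around a fixed partner in a periodic cubic box.

    Coordinates are the mobile particle's displacement from the fixed
    particle, wrapped into [-L/2, L/2)^3 (minimum image).  The pair
    energy combines a lambda-coupled Lennard-Jones term evaluated at the
    soft-core effective distance with a screened-Coulomb toy term
    q1*q2/r; the coupling protocol decides whether electrostatics ramp
    after sterics on the bare distance (split) or concurrently on the
    soft-core distance (unified).  The interaction is truncated and
    shifted to zero at r_cut = L/2, which keeps the partition function
    exactly one-dimensional for the quadrature oracle (beyond r_cut the
    Boltzmann factor is 1 everywhere, corners included).

    At lam=0 both terms vanish, so the mobile particle is uniform in the
    box — the alchemically annihilated state.
    """

    dimensionality = 3
    decoupled_move_kinds = ("com_translation_cube", "com_translation_sphere")

    def __init__(
        self,
        protocol: CouplingProtocol | None = None,
        params: SoftCoreParams | None = None,
        charges: tuple[float, float] = (1.0, -3.0),
        epsilon: float = 1.0,
        box_length: float = 5.0,
    ):
        self.params = params if params is not None else SoftCoreParams()
        if box_length <= 2.0 * self.params.sigma_ij:
            raise ValueError("box length must exceed 2 sigma")
        self.protocol = protocol if protocol is not None else CouplingProtocol()
        self.charges = (float(charges[0]), float(charges[1]))
        self.epsilon = float(epsilon)
        self.box_length = float(box_length)
        self.r_cut = self.box_length / 2.0

    # smallest bare distance used in the split-protocol Coulomb term;
    # the fully-coupled LJ wall makes such configurations unreachable,
    # the floor only guards float overflow in exp(-u).
    _R_FLOOR = 1e-6

    def wrap(self, x):
        L = self.box_length
        return (np.asarray(x, dtype=float) + L / 2.0) % L - L / 2.0

    def min_image_distance(self, x):
        d = self.wrap(x)
        return np.sqrt(np.sum(np.atleast_2d(d) ** 2, axis=-1))

    def _pair_energy_radial(self, lam, r):
        """Untruncated pair energy as a function of separation r."""
        lam_st, lam_el = self.protocol.sub_lambdas(lam)
        r = np.asarray(r, dtype=float)
        sig = self.params.sigma_ij
        # steric term: lambda-scaled LJ at the soft-core distance
        r_eff = softcore_effective_distance(r, float(lam_st), self.params)
        x6 = (sig / r_eff) ** 6
        u = lam_st * 4.0 * self.epsilon * (x6**2 - x6)
        # electrostatic toy term q1 q2 / r
        q = self.charges[0] * self.charges[1]
        if self.protocol.mode == "split":
            u = u + lam_el * q / np.maximum(r, self._R_FLOOR)
        else:
            u = u + lam_el * q / r_eff
        return u

    def pair_energy(self, lam, r):
        """Truncated-and-shifted pair energy u(lam, r); zero for r >= r_cut."""
        r = np.asarray(r, dtype=float)
        shift = self._pair_energy_radial(lam, np.asarray(self.r_cut))
        u = self._pair_energy_radial(lam, r) - shift
        return np.where(r < self.r_cut, u, 0.0)

    def energy(self, lam, x):
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda out of range")
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        r = self.min_image_distance(np.atleast_2d(x))
        u = self.pair_energy(lam, r)
        return u[0] if single else u

    def proposal_scales(self):
        return np.full(3, 0.3 * self.params.sigma_ij)

    def quadrature_kind(self):
        return "radial"

    @property
    def box_volume(self) -> float:
        return self.box_length**3

    @property
    def r_support_max(self) -> float:
        """Largest attainable minimum-image distance (box corner)."""
        return np.sqrt(3.0) * self.box_length / 2.0


SYSTEM_REGISTRY: dict[str, type[PotentialSystem]] = {
    "constant": ConstantPotential,
    "torsional_toy": TorsionalToy,
    "gaussian_ladder": GaussianLadder,
    "softcore_pair": SoftCorePair,
}


def build_system(name: str, params: dict | None = None) -> PotentialSystem:
    """Instantiate a registered system from a name + parameter block.

    The ``softcore_pair`` block accepts ``protocol`` (mode/switch_point),
    ``alpha``/``sigma`` soft-core keys, ``charges``, ``epsilon`` and
    ``box_length``; other systems take their constructor keywords
    directly.  User systems can be plugged in by inserting a constructor
    into :data:`SYSTEM_REGISTRY`.
    """
    if name not in SYSTEM_REGISTRY:
        raise KeyError(f"unknown system '{name}'")
    params = dict(params or {})
    if name == "softcore_pair":
        proto = params.pop("protocol", None)
        if isinstance(proto, dict):
            proto = CouplingProtocol(**proto)
        sc = SoftCoreParams(
            alpha=params.pop("alpha", 0.5), sigma_ij=params.pop("sigma", 1.0)
        )
        charges = tuple(params.pop("charges", (1.0, -3.0)))
        return SoftCorePair(protocol=proto, params=sc, charges=charges, **params)
    return SYSTEM_REGISTRY[name](**params)
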