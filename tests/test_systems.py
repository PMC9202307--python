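import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alchemsmc import (
    ConstantPotential,
    CouplingProtocol,
    GaussianLadder,
    SoftCorePair,
    SoftCoreParams,
    TorsionalToy,
    build_system,
    softcore_effective_distance,
)


class TestSoftCoreDistance:
    def test_full_coupling_restores_bare_distance(self):
        params = SoftCoreParams(alpha=0.5, sigma_ij=1.7)
        assert softcore_effective_distance(1.3, 1.0, params) == pytest.approx(1.3)
        assert softcore_effective_distance(0.0, 1.0, params) == 0.0

    def test_overlap_is_regularized_at_partial_coupling(self):
        params = SoftCoreParams(alpha=0.5, sigma_ij=1.0)
        r_eff = softcore_effective_distance(0.0, 0.0, params)
        assert r_eff == pytest.approx(0.5 ** (1 / 6))  # ~0.8909: no singularity

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="invalid distance"):
            softcore_effective_distance(-0.1, 0.5, SoftCoreParams())

    @given(
        r=st.floats(min_value=0.0, max_value=10.0),
        sigma=st.floats(min_value=0.1, max_value=3.0),
        alpha=st.floats(min_value=0.0, max_value=2.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_monotone_recovery_in_lambda(self, r, sigma, alpha):
        """r_eff is non-increasing in lambda and equals r at lambda=1."""
        params = SoftCoreParams(alpha=alpha, sigma_ij=sigma)
        lams = np.linspace(0.0, 1.0, 21)
        r_effs = np.array(
            [softcore_effective_distance(r, lam, params) for lam in lams]
        )
        assert np.all(np.diff(r_effs) <= 1e-12)
        assert r_effs[-1] == pytest.approx(r, abs=1e-12)
        assert np.all(r_effs >= r - 1e-12)


class TestTorsionalToy:
    @pytest.mark.parametrize(
        "lam,phi,a,b,expected",
        [
            (0.0, 1.234, 3.0, 1.0, 0.0),  # decoupled
            (1.0, np.pi, 3.0, 0.0, 0.0),  # cos(pi) = -1
            (0.5, 0.0, 3.0, 1.0, 4.0),  # 0.5 * (6 + 2)
        ],
    )
    def test_energy_examples(self, lam, phi, a, b, expected):
        sys_ = TorsionalToy(a=a, b=b)
        assert sys_.energy(lam, np.array([[phi]]))[0] == pytest.approx(expected)

    def test_two_pi_periodic(self, rng):
        sys_ = TorsionalToy(a=2.0, b=1.5)
        phi = rng.uniform(0, 2 * np.pi, size=(50, 1))
        np.testing.assert_allclose(
            sys_.energy(0.7, phi), sys_.energy(0.7, phi + 2 * np.pi), atol=1e-12
        )

    def test_lambda0_marginal_flat_over_decoupled_dof(self, rng):
        sys_ = TorsionalToy(a=5.0, b=2.0)
        phi = rng.uniform(0, 2 * np.pi, size=(100, 1))
        assert np.all(sys_.energy(0.0, phi) == 0.0)


class TestGaussianLadder:
    def test_energy_examples(self, ladder):
        assert ladder.energy(0.0, np.array([[0.0]]))[0] == 0.0
        assert ladder.energy(1.0, np.array([[1.0]]))[0] == pytest.approx(0.5)

    def test_closed_form_free_energy(self, ladder):
        assert ladder.exact_free_energy() == pytest.approx(np.log(2.0))

    @pytest.mark.parametrize("s0,s1", [(0.0, 1.0), (1.0, -2.0)])
    def test_invalid_width_rejected(self, s0, s1):
        with pytest.raises(ValueError, match="invalid width"):
            GaussianLadder(s0=s0, s1=s1)


class TestSoftCorePair:
    def test_fully_decoupled_particle_has_zero_energy(self, rng):
        sys_ = SoftCorePair()
        coords = rng.uniform(-2.5, 2.5, size=(20, 3))
        np.testing.assert_allclose(sys_.energy(0.0, coords), 0.0, atol=1e-12)

    def test_split_boundary_has_no_electrostatics(self):
        """At lambda = switch_point the electrostatic term is exactly zero."""
        proto = CouplingProtocol(mode="split", switch_point=0.8)
        charged = SoftCorePair(protocol=proto, charges=(2.0, -2.0))
        neutral = SoftCorePair(protocol=proto, charges=(0.0, 0.0))
        r = np.linspace(0.05, 2.4, 100)
        np.testing.assert_allclose(
            charged.pair_energy(0.8, r), neutral.pair_energy(0.8, r), atol=1e-12
        )
        # just above the switch point electrostatics contribute
        assert not np.allclose(
            charged.pair_energy(0.9, r), neutral.pair_energy(0.9, r)
        )

    def test_overlapping_particles_finite_at_partial_coupling(self):
        for mode in ("split", "unified"):
            sys_ = SoftCorePair(protocol=CouplingProtocol(mode=mode))
            u = sys_.energy(0.5, np.zeros((1, 3)))[0]
            assert np.isfinite(u)

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError, match="invalid protocol"):
            CouplingProtocol(mode="staged")

    def test_box_must_exceed_two_sigma(self):
        with pytest.raises(ValueError, match="box length"):
            SoftCorePair(box_length=1.5)

    def test_unified_pathology_favours_particle_overlap(self):
        """With strongly opposite charges under the unified protocol, the
        minimum-energy separation at intermediate lambda drops below sigma
        (soft-core electrostatics reward unphysical overlap)."""
        sys_ = SoftCorePair(
            protocol=CouplingProtocol(mode="unified"), charges=(6.0, -5.0)
        )
        r = np.linspace(1e-4, 2.4, 4000)
        argmin_mid = r[np.argmin(sys_.pair_energy(0.3, r))]
        argmin_full = r[np.argmin(sys_.pair_energy(1.0, r))]
        assert argmin_mid < sys_.params.sigma_ij
        assert argmin_mid < argmin_full

    def test_truncation_beyond_cutoff(self):
        sys_ = SoftCorePair()
        r = np.array([sys_.r_cut + 0.01, sys_.r_support_max])
        np.testing.assert_array_equal(sys_.pair_energy(1.0, r), 0.0)


@pytest.mark.parametrize(
    "system",
    [
        ConstantPotential(),
        TorsionalToy(a=4.0, b=1.0),
        GaussianLadder(2.0, 1.0),
        SoftCorePair(protocol=CouplingProtocol(mode="split")),
        SoftCorePair(protocol=CouplingProtocol(mode="unified")),
    ],
    ids=["constant", "torsional", "ladder", "pair-split", "pair-unified"],
)
def test_energy_continuous_in_lambda(system, rng):
    """Needed for the bisection search: no jumps along the coupling path.

    Configurations inside a pair system's repulsive core are excluded:
    the energy there is still continuous in lambda but its slope is set
    by the r^-12 wall, which would swamp a finite-difference check.
    """
    coords = rng.uniform(-1.5, 1.5, size=(200, system.dimensionality))
    coords = system.wrap(coords)
    if hasattr(system, "min_image_distance"):
        coords = coords[system.min_image_distance(coords) > 0.9]
        assert coords.shape[0] > 20
    lams = np.linspace(0.0, 1.0, 401)
    u = np.stack([system.energy(lam, coords) for lam in lams])
    steps = np.abs(np.diff(u, axis=0)).max(axis=1)
    scale = max(1.0, np.abs(u).max())
    assert steps.max() < 0.05 * scale


class TestRegistry:
    def test_build_known_systems(self):
        sys_ = build_system("torsional_toy", {"a": 2.0, "b": 1.0})
        assert isinstance(sys_, TorsionalToy) and sys_.a == 2.0
        pair = build_system(
            "softcore_pair",
            {"protocol": {"mode": "unified"}, "charges": [1.0, -1.0], "alpha": 0.4},
        )
        assert pair.protocol.mode == "unified"
        assert pair.params.alpha == 0.4

    def test_unknown_system_rejected(self):
        with pytest.raises(KeyError, match="unknown system"):
            build_system("lennard_jones_fluid")
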