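import numpy as np
import pytest
from scipy import stats

from alchemsmc import (
    ConstantPotential,
    DegenerateWeightsError,
    Ensemble,
    GaussianLadder,
    Lambda0MoveSpec,
    PotentialSystem,
    SMCConfig,
    TorsionalToy,
    find_next_lambda,
    metropolis_sweep,
    propagate_until_decorrelated,
    smc_run,
)
from alchemsmc.overlap import conservative_min_metric

from conftest import small_config

TWO_PI = 2 * np.pi


def _boltzmann_torsion_sample(system, lam, n, rng):
    """Inverse-CDF draw from the exact torsional Boltzmann marginal."""
    grid = np.linspace(0, TWO_PI, 20_001)
    dens = np.exp(-system.energy(lam, grid[:, None]))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]))])
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)[:, None]


class TestMetropolisSweep:
    def test_flat_potential_accepts_everything(self, rng):
        sys_ = ConstantPotential()
        ens = Ensemble(rng.uniform(0, TWO_PI, (200, 1)), lam=1.0)
        before = ens.coords.copy()
        metropolis_sweep(ens, sys_, np.array([0.5]), rng)
        assert np.all(ens.coords != before)  # every proposal accepted

    def test_zero_step_is_identity(self, rng, torsional):
        ens = Ensemble(rng.uniform(0, TWO_PI, (50, 1)), lam=1.0)
        before = ens.coords.copy()
        metropolis_sweep(ens, torsional, np.array([0.0]), rng)
        np.testing.assert_array_equal(ens.coords, before)

    def test_gaussian_target_variance_recovered(self, ladder, rng):
        """Long-run sample variance at lambda=1 matches s1^2: the sweep
        leaves the Boltzmann distribution invariant."""
        ens = Ensemble(rng.normal(0, ladder.s1, (400, 1)), lam=1.0)
        samples = []
        for _ in range(300):
            metropolis_sweep(ens, ladder, ladder.proposal_scales(), rng)
            samples.append(ens.coords[:, 0].copy())
        pooled = np.concatenate(samples[100:])
        # 3 SE with a generous effective-sample-size discount for
        # autocorrelation between sweeps
        assert pooled.var() == pytest.approx(ladder.s1**2, rel=0.05)

    def test_energy_cache_stays_consistent(self, torsional, rng):
        ens = Ensemble(rng.uniform(0, TWO_PI, (100, 1)), lam=0.7)
        metropolis_sweep(ens, torsional, np.array([0.8]), rng)
        np.testing.assert_allclose(
            ens.energies, torsional.energy(0.7, ens.coords), atol=1e-12
        )


class TestPropagateUntilDecorrelated:
    def test_flat_potential_terminates_after_one_block(self, rng):
        sys_ = ConstantPotential()
        ens = Ensemble(rng.uniform(0, TWO_PI, (50, 1)), lam=0.0)
        cfg = small_config(propagation_block=10)
        _, report = propagate_until_decorrelated(ens, sys_, cfg, rng=rng)
        assert report.degenerate
        assert report.tau == 10

    def test_preserves_boltzmann_marginal(self, torsional):
        """Starting from the exact lambda=1 distribution, decorrelation
        finishes and the propagated histogram still matches the quadrature
        marginal (chi-square over pooled replicates)."""
        cfg = small_config(propagation_block=50)
        pooled = []
        rng0 = np.random.default_rng(8)
        for seed in range(6):
            rng = np.random.default_rng(seed)
            coords = _boltzmann_torsion_sample(torsional, 1.0, 500, rng0)
            ens = Ensemble(coords, lam=1.0)
            ens, report = propagate_until_decorrelated(ens, torsional, cfg, rng=rng)
            assert abs(report.r_tau) <= cfg.decorrelation_threshold
            pooled.append(ens.coords[:, 0])
        phi = np.concatenate(pooled)
        bins = np.linspace(0, TWO_PI, 13)
        hist, _ = np.histogram(phi, bins=bins)
        grid = np.linspace(0, TWO_PI, 10_001)
        dens = np.exp(-torsional.energy(1.0, grid[:, None]))
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]))])
        cdf /= cdf[-1]
        probs = np.diff(np.interp(bins, grid, cdf))
        _, p = stats.chisquare(hist, f_exp=probs * phi.size)
        assert p > 0.01


class TestFindNextLambda:
    def test_constant_potential_jumps_to_one(self, rng):
        ens = Ensemble(rng.uniform(0, TWO_PI, (100, 1)), lam=0.0)
        cfg = small_config()
        assert find_next_lambda(ens, ConstantPotential(), 0.0, cfg) == 1.0

    def test_high_overlap_final_step_rule(self, rng):
        """When the metric at lambda=1 already meets the target the search
        returns exactly 1.0."""
        ladder = GaussianLadder(1.2, 1.0)
        ens = Ensemble(ladder.sample_lambda0(2000, rng), lam=0.0)
        cfg = small_config(overlap_target=0.5)
        assert find_next_lambda(ens, ladder, 0.0, cfg) == 1.0

    def test_bisection_matches_grid_scan(self, rng):
        """The returned lambda' reproduces the dense grid-scan solution of
        metric(lambda') = target within the bisection tolerance."""
        ladder = GaussianLadder(3.0, 1.0)
        ens = Ensemble(ladder.sample_lambda0(10_000, rng), lam=0.0)
        cfg = small_config(overlap_target=0.5, bisection_tolerance=0.01)
        lam_next = find_next_lambda(ens, ladder, 0.0, cfg)
        assert 0.0 < lam_next < 1.0

        u0 = ladder.energy(0.0, ens.coords)

        def metric(lam):
            logw = -(ladder.energy(lam, ens.coords) - u0)
            w = np.exp(logw - logw.max())
            return conservative_min_metric(w / w.sum())

        assert abs(metric(lam_next) - 0.5) <= cfg.bisection_tolerance
        grid = np.linspace(1e-4, 1.0, 2000)
        vals = np.array([metric(l) for l in grid])
        crossing = grid[np.argmin(np.abs(vals - 0.5))]
        assert abs(metric(crossing) - metric(lam_next)) <= 2 * cfg.bisection_tolerance


class _HostileSystem(PotentialSystem):
    """Energy jumps to +inf for lam > 0: zero overlap with any next state."""

    dimensionality = 1
    decoupled_move_kinds = ("torsion",)

    def energy(self, lam, x):
        x = np.asarray(x)
        n = x.shape[0] if x.ndim > 1 else 1
        return np.zeros(n) if lam == 0.0 else np.full(n, np.inf)

    def wrap(self, x):
        return np.mod(x, TWO_PI)


class TestSmcRun:
    def test_constant_potential_trivial_run(self):
        cfg = small_config(n_walkers=50, oversample_factor=2, rng_seed=1)
        rec = smc_run(ConstantPotential(), Lambda0MoveSpec(kind="torsion"), cfg)
        assert rec.schedule == [0.0, 1.0]
        assert rec.log_Z_ratio == 0.0

    def test_gaussian_free_energy_recovered(self, ladder):
        estimates = [
            -smc_run(
                ladder,
                Lambda0MoveSpec(kind="direct"),
                small_config(n_walkers=400, oversample_factor=10, rng_seed=seed),
            ).log_Z_ratio
            for seed in range(5)
        ]
        est = np.array(estimates)
        se = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - np.log(2)) < 3 * max(se, 1e-3)

    def test_schedule_and_ledger_invariants(self, torsional):
        rec = smc_run(torsional, Lambda0MoveSpec(kind="torsion"), small_config(rng_seed=3))
        sched = np.array(rec.schedule)
        assert sched[0] == 0.0 and sched[-1] == 1.0
        assert np.all(np.diff(sched) > 0)
        assert rec.log_Z_ratio == pytest.approx(
            np.sum(np.log(rec.step_weight_means)), abs=1e-12
        )

    def test_overlap_guarantee_each_step(self, torsional):
        cfg = small_config(rng_seed=5)
        rec = smc_run(torsional, Lambda0MoveSpec(kind="torsion"), cfg)
        metrics = [o.r_min for o in rec.step_overlaps]
        for m in metrics[:-1]:
            assert abs(m - cfg.overlap_target) <= cfg.bisection_tolerance
        assert metrics[-1] >= cfg.overlap_target - cfg.bisection_tolerance

    def test_harder_problem_gets_longer_schedule(self):
        """The same hyperparameters allocate more intermediate states to a
        higher torsional barrier."""
        cfg = small_config(n_walkers=300, oversample_factor=10, rng_seed=2)
        low = smc_run(TorsionalToy(a=2.0), Lambda0MoveSpec(kind="torsion"), cfg)
        high = smc_run(TorsionalToy(a=8.0), Lambda0MoveSpec(kind="torsion"), cfg)
        assert high.n_steps > low.n_steps

    def test_fixed_schedule_replay(self, torsional):
        adaptive = smc_run(
            torsional, Lambda0MoveSpec(kind="torsion"), small_config(rng_seed=4)
        )
        replay_cfg = small_config(
            rng_seed=99, reuse_schedule=tuple(adaptive.schedule)
        )
        replay = smc_run(torsional, Lambda0MoveSpec(kind="torsion"), replay_cfg)
        assert replay.schedule == adaptive.schedule

    def test_determinism_under_seed(self, torsional):
        cfg = small_config(rng_seed=17)
        a = smc_run(torsional, Lambda0MoveSpec(kind="torsion"), cfg)
        b = smc_run(torsional, Lambda0MoveSpec(kind="torsion"), cfg)
        assert a.schedule == b.schedule
        np.testing.assert_array_equal(a.final_ensemble.coords, b.final_ensemble.coords)
        assert a.log_Z_ratio == b.log_Z_ratio

    def test_degenerate_weights_abort_with_diagnostics(self):
        cfg = small_config(n_walkers=20, oversample_factor=1, rng_seed=0,
                           max_propagation_blocks=2, propagation_block=5)
        with pytest.raises(DegenerateWeightsError, match="degenerate weights"):
            smc_run(_HostileSystem(), Lambda0MoveSpec(kind="torsion"), cfg)


class TestSMCConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"overlap_target": 0.0},
            {"overlap_target": 1.0},
            {"decorrelation_threshold": 0.0},
            {"overlap_metric": "entropy"},
            {"n_walkers": 0},
            {"reuse_schedule": (0.0, 0.5)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SMCConfig(**kwargs)
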