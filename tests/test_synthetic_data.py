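import numpy as np
import pytest
from scipy.stats import spearmanr

from modlabel import (
    BlockSimConfig,
    PopulationSimConfig,
    SimConfigError,
    corrupt_couplings,
    simulate_ar1_block,
    simulate_downstream_units,
    simulate_iid_population,
    simulate_multiunits,
)
from modlabel.synthetic_data import (
    experiment_population,
    relative_strength_of,
    sigma_m_for_relative_strength,
)
from modlabel.task_statistics import fano_factor

from conftest import make_recording


class TestIidPopulation:
    def test_zero_couplings_are_plain_poisson(self):
        cfg = PopulationSimConfig(
            n_informative=0, n_uninformative=20, n_inactive=0,
            uninformative_log_ratio_sd=0.0, sigma_m=1.0, seed=0,
        )
        rec, m = simulate_iid_population(cfg, 4000)
        lam0, _ = cfg.rates(np.random.default_rng(cfg.seed))
        sums = rec.presentation_sums().astype(float)
        fanos = sums.var(axis=1) / sums.mean(axis=1)
        # Fano ~ 1 for unmodulated Poisson counts
        assert np.abs(fanos - 1.0).mean() < 0.05
        np.testing.assert_allclose(sums.mean(axis=1), lam0, rtol=0.05)

    def test_mean_correction_cancels_modulator_gain(self):
        # E[exp(c m - sigma^2 c^2/2)] = 1, so the empirical mean stays at
        # lambda; checked at c=1, sigma=0.5, lambda=10 over many draws
        cfg = PopulationSimConfig(
            n_informative=0, n_uninformative=1, n_inactive=0,
            lam0=np.array([10.0]), lam1=np.array([10.0]),
            sigma_m=0.5, seed=1,
        )
        rng = np.random.default_rng(2)
        n = 500_000
        m = rng.normal(0, cfg.sigma_m, n)
        c = 1.0
        rate = 10.0 * np.exp(c * m - 0.5 * cfg.sigma_m**2 * c**2)
        counts = rng.poisson(rate)
        assert abs(counts.mean() - 10.0) / 10.0 < 0.01

    def test_nonpositive_rate_rejected(self):
        cfg = PopulationSimConfig(lam0=np.array([0.0]), lam1=np.array([1.0]))
        with pytest.raises(SimConfigError):
            cfg.rates()

    def test_seed_determinism(self):
        cfg = PopulationSimConfig(n_informative=4, n_uninformative=6, seed=7)
        rec1, m1 = simulate_iid_population(cfg, 50)
        rec2, m2 = simulate_iid_population(cfg, 50)
        np.testing.assert_array_equal(rec1.counts, rec2.counts)
        np.testing.assert_array_equal(m1, m2)


class TestCorruptCouplings:
    def test_zero_noise_identity(self):
        c = np.array([0.0, 0.5, 1.0])
        np.testing.assert_array_equal(corrupt_couplings(c, 0.0), c)

    def test_all_zero_clipped_nonnegative(self):
        out = corrupt_couplings(np.zeros(100), 1.0, rng=3)
        assert (out >= 0).all()

    def test_rank_correlation_decreases_with_noise(self):
        rng = np.random.default_rng(4)
        c = rng.uniform(0, 1, 200)
        mean_rho = []
        for sd in (0.1, 0.5, 2.0):
            rhos = [
                spearmanr(c, corrupt_couplings(c, sd, rng=s)).statistic
                for s in range(100)
            ]
            mean_rho.append(np.mean(rhos))
        assert mean_rho[0] > mean_rho[1] > mean_rho[2]


class TestMultiunits:
    def test_total_count_conserved_and_pairs_partition(self):
        counts = np.arange(1, 5)[:, None, None] * np.ones((1, 6, 2), dtype=int)
        rec = make_recording(counts[:, :, 0])
        mu = simulate_multiunits(rec, rng=0)
        assert mu.n_units == 2
        assert mu.counts.sum() == rec.counts.sum()
        # each multiunit is the sum of a disjoint pair from {1,2,3,4}
        per_bin = sorted(mu.counts[:, 0, 0])
        assert sum(per_bin) == 10

    def test_odd_unit_count_drops_one(self):
        rec = make_recording(np.ones((5, 4), dtype=int))
        mu = simulate_multiunits(rec, rng=1)
        assert mu.n_units == 2

    def test_paired_rates_add(self):
        rng = np.random.default_rng(5)
        lam = np.array([3.0, 7.0])
        counts = rng.poisson(lam[:, None], size=(2, 20000))
        rec = make_recording(counts)
        mu = simulate_multiunits(rec, rng=2)
        assert abs(mu.counts.mean() - 10.0) < 0.1


class TestAr1Block:
    def test_zero_dynamics_means_no_modulation(self):
        pop = PopulationSimConfig(
            n_informative=2, n_uninformative=2, sigma_m=0.0,
            modulator_law="ar1", ar_coef=0.0, bins_per_presentation=4, seed=0,
        )
        rec, m = simulate_ar1_block(pop, BlockSimConfig(n_trials=10, seed=0))
        np.testing.assert_array_equal(m, np.zeros_like(m))

    def test_unstable_ar_rejected(self):
        pop = PopulationSimConfig(modulator_law="ar1", ar_coef=1.0)
        with pytest.raises(SimConfigError):
            simulate_ar1_block(pop, BlockSimConfig(n_trials=5))

    def test_latent_autocorrelation_time(self):
        # A = exp(-50/75) with 50 ms bins gives a 75 ms decay constant
        a = np.exp(-50.0 / 75.0)
        pop = experiment_population(5, ar_coef=a, sigma_m=0.6, seed=1)
        blk = BlockSimConfig(n_trials=500, seed=1)
        rec, m = simulate_ar1_block(pop, blk)
        # lag-1 autocorrelation within trials estimates A
        bins_per = rec.n_bins
        m_trials = m.reshape(-1, bins_per) if len(m) % bins_per == 0 else None
        x0 = m[:-1]
        x1 = m[1:]
        a_hat = np.corrcoef(x0, x1)[0, 1]
        tau_hat = -50.0 / np.log(a_hat)
        assert abs(tau_hat - 75.0) / 75.0 < 0.15

    def test_target_terminates_every_trial(self, ar1_block):
        meta = ar1_block["rec"].presentation_meta
        for trial, grp in meta.groupby("trial"):
            assert (grp["stimulus"] == 1).sum() == 1
            assert grp.loc[grp["stimulus"] == 1, "repeat_index"].iloc[0] == grp["repeat_index"].max()

    def test_seed_determinism(self):
        pop = experiment_population(10, seed=9)
        blk = BlockSimConfig(n_trials=20, seed=9)
        r1, m1 = simulate_ar1_block(pop, blk)
        pop2 = experiment_population(10, seed=9)
        r2, m2 = simulate_ar1_block(pop2, blk)
        np.testing.assert_array_equal(r1.counts, r2.counts)
        np.testing.assert_array_equal(m1, m2)

    def test_stationary_variance_matches_config(self):
        pop = experiment_population(5, sigma_m=0.7, seed=3)
        blk = BlockSimConfig(n_trials=400, seed=3)
        _, m = simulate_ar1_block(pop, blk)
        assert abs(m.std() - 0.7) / 0.7 < 0.05


class TestRelativeStrength:
    def test_round_trip(self):
        rng = np.random.default_rng(0)
        lam0 = rng.uniform(0.5, 2.0, 30)
        lam1 = lam0 * np.exp(rng.normal(0, 0.4, 30))
        c = np.abs(np.log(lam1) - np.log(lam0))
        for rel in (0.25, 0.5, 2.0):
            sigma = sigma_m_for_relative_strength(rel, c, lam0, lam1)
            assert relative_strength_of(sigma, c, lam0, lam1) == pytest.approx(rel)

    def test_zero_couplings_cannot_reach_strength(self):
        lam = np.ones(3)
        with pytest.raises(SimConfigError):
            sigma_m_for_relative_strength(0.5, np.zeros(3), lam, lam * 2)


class TestDownstream:
    def test_zero_couplings_give_poisson_fano(self, ar1_block):
        rec = ar1_block["rec"]
        m = ar1_block["m"]
        n_down = 8
        lam = np.full(n_down, 1.0)
        down = simulate_downstream_units(m, rec, lam, lam, np.zeros(n_down), rng=0)
        meta = down.presentation_meta
        cond = (meta["contrast"].astype(str) + meta["stimulus"].astype(str)).to_numpy()
        fanos = [fano_factor(down.presentation_sums()[u], cond) for u in range(n_down)]
        assert abs(np.mean(fanos) - 1.0) < 0.1

    def test_coupled_units_have_higher_fano(self, ar1_block):
        rec, m = ar1_block["rec"], ar1_block["m"]
        lam = np.full(10, 1.5)
        coupl = np.array([1.2] * 5 + [0.0] * 5)
        down = simulate_downstream_units(m, rec, lam, lam, coupl, rng=1)
        meta = down.presentation_meta
        cond = (meta["contrast"].astype(str) + meta["stimulus"].astype(str)).to_numpy()
        fanos = np.array([fano_factor(down.presentation_sums()[u], cond)
                          for u in range(10)])
        assert fanos[:5].mean() > fanos[5:].mean() + 0.3

    def test_excessive_lag_rejected(self, ar1_block):
        rec, m = ar1_block["rec"], ar1_block["m"]
        with pytest.raises(ValueError, match="lag"):
            simulate_downstream_units(m, rec, np.ones(2), np.ones(2),
                                      np.zeros(2), lag_bins=10**6)
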