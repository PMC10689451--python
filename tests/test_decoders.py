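import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from itertools import product
from scipy.stats import poisson, spearmanr

from modlabel import (
    PopulationSimConfig,
    baseline_decoder,
    evaluate_training_curve,
    mg_decoder,
    modulator_strength_sweep,
    optimal_decoder,
    simulate_iid_population,
    so_decoder,
)
from modlabel.decoders import LinearThresholdDecoder, fit_constant_threshold

from conftest import make_recording


class TestOptimalDecoder:
    def test_weights_and_threshold_closed_form(self):
        dec = optimal_decoder(np.array([1.0, 4.0]), np.array([4.0, 1.0]),
                              np.array([0.5, 0.5]), sigma_m=0.5,
                              mean_correction=False)
        np.testing.assert_allclose(dec.weights, [np.log(4), -np.log(4)])
        # at m = 0: q = (4-1) + (1-4) = 0
        assert dec.q_of_m(np.array([0.0]))[0] == pytest.approx(0.0)

    def test_equal_rates_chance(self):
        lam = np.array([2.0, 3.0])
        dec = optimal_decoder(lam, lam, train_counts=np.ones((2, 4)),
                              train_labels=np.array([0, 1, 0, 1]),
                              mode="constant")
        assert np.all(dec.weights == 0.0)

    def test_zero_rate_in_weighted_unit_rejected(self):
        with pytest.raises(ValueError, match="unit 0"):
            optimal_decoder(np.array([0.0]), np.array([1.0]))

    def test_bayes_oracle_equivalence_small(self):
        # spot check of the full acceptance-grade property: the linear-
        # threshold decision equals exhaustive Bayes comparison
        rng = np.random.default_rng(1)
        lam0 = rng.uniform(0.5, 5, 2)
        lam1 = rng.uniform(0.5, 5, 2)
        c = rng.uniform(0, 1, 2)
        for sigma, m in product((0.25, 0.5), (-0.8, 0.0, 0.6)):
            dec = optimal_decoder(lam0, lam1, c, sigma)
            corr = 0.5 * sigma**2 * c**2
            r0 = lam0 * np.exp(c * m - corr)
            r1 = lam1 * np.exp(c * m - corr)
            for k in product(range(8), repeat=2):
                k = np.array(k)
                bayes = int(poisson.logpmf(k, r1).sum() >= poisson.logpmf(k, r0).sum())
                mine = int(dec.decide(k.reshape(2, 1, 1), m=np.array([m]))[0])
                assert bayes == mine


class TestMGDecoder:
    def test_zero_modulator_zero_magnitudes(self):
        counts = np.random.default_rng(0).poisson(2.0, size=(3, 50, 1))
        labels = np.tile([0, 1], 25)
        dec = mg_decoder(counts, np.zeros((50, 1)), labels)
        assert np.all(np.abs(dec.weights) == 0.0)

    def test_magnitude_matches_analytic_expectation(self):
        # E[(1/T) sum m k] = lambda c sigma^2 for a mean-corrected unit
        rng = np.random.default_rng(1)
        n = 200000
        sigma, c, lam = 0.5, 1.0, 10.0
        m = rng.normal(0, sigma, n)
        coupled = rng.poisson(lam * np.exp(c * m - 0.5 * sigma**2 * c**2))
        uncoupled = rng.poisson(lam, n)
        counts = np.stack([coupled, uncoupled])[:, :, None]
        labels = np.tile([0, 1], n // 2)
        dec = mg_decoder(counts, m[:, None], labels)
        expected = lam * c * sigma**2
        se = np.std(m * coupled) / np.sqrt(n)
        assert abs(abs(dec.weights[0]) - expected) < 3 * se
        assert abs(dec.weights[1]) < 3 * np.std(m * uncoupled) / np.sqrt(n)

    def test_signs_from_feedback(self):
        rng = np.random.default_rng(2)
        n = 2000
        labels = np.tile([0, 1], n // 2)
        lam = np.where(labels == 1, 8.0, 2.0)
        counts = rng.poisson(lam)[None, :, None].astype(float)
        m = rng.normal(0, 0.5, n)
        dec = mg_decoder(counts, m[:, None], labels)
        assert dec.weights[0] >= 0

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="both stimuli"):
            mg_decoder(np.ones((1, 4, 1)), np.zeros((4, 1)), np.zeros(4))


class TestSODecoder:
    def test_signs(self):
        dec = so_decoder(np.array([1.0, 5.0, 2.0]), np.array([3.0, 1.0, 2.0]))
        np.testing.assert_array_equal(dec.weights, [1.0, -1.0, 1.0])

    def test_uninformative_population_at_chance(self):
        cfg = PopulationSimConfig(
            n_informative=0, n_uninformative=50, n_inactive=0,
            uninformative_log_ratio_sd=0.0, sigma_m=0.3, seed=3,
        )
        rec, _ = simulate_iid_population(cfg, 1000)
        k = rec.presentation_sums()
        y = rec.presentation_meta["stimulus"].to_numpy()
        tr = slice(0, 1000)
        te = slice(1000, 2000)
        dec = so_decoder(k[:, tr][:, y[tr] == 0].mean(axis=1),
                         k[:, tr][:, y[tr] == 1].mean(axis=1),
                         k[:, tr], y[tr])
        acc = dec.accuracy(k[:, te], y[te])
        assert abs(acc - 0.5) < 0.05


class TestBaselines:
    def test_separable_data_fit_perfectly(self):
        X = np.array([[0.0, 0], [0, 1], [5, 5], [6, 4]]).T
        y = np.array([0, 0, 1, 1])
        for kind in ("logistic", "svm"):
            dec = baseline_decoder(X, y, kind=kind)
            assert dec.accuracy(X, y) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            baseline_decoder(np.ones((2, 4)), np.zeros(4))

    def test_logistic_approaches_optimal_with_data(self, theory_population_cfg):
        cfg = theory_population_cfg
        rec, m = simulate_iid_population(cfg, 5000)
        k = rec.presentation_sums()
        y = rec.presentation_meta["stimulus"].to_numpy()
        lam0, lam1 = cfg.rates(np.random.default_rng(cfg.seed))
        c = cfg.couplings(lam0, lam1)
        tr, te = slice(0, 8000), slice(8000, 10000)
        logit = baseline_decoder(k[:, tr], y[tr])
        opt = optimal_decoder(lam0, lam1, c, cfg.sigma_m)
        acc_l = logit.accuracy(k[:, te], y[te])
        acc_o = np.mean(opt.decide(rec.counts[:, te], m=m[te]) == y[te])
        assert acc_l > acc_o - 0.03


class TestThresholdRule:
    def test_tie_decides_stimulus_one(self):
        dec = LinearThresholdDecoder(weights=np.array([1.0]), kind="SO",
                                     threshold=5.0)
        assert dec.decide(np.array([[5.0]]))[0] == 1

    def test_constant_threshold_midpoint_of_optimal_interval(self):
        scores = np.array([0.0, 1.0, 10.0, 11.0])
        labels = np.array([0, 0, 1, 1])
        q = fit_constant_threshold(scores, labels)
        assert q == pytest.approx(5.5)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance_of_decisions(self, k):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, size=(4, 30))
        w = rng.normal(size=4)
        d1 = LinearThresholdDecoder(weights=w, kind="SO", threshold=1.3)
        d2 = LinearThresholdDecoder(weights=w * k, kind="SO", threshold=1.3 * k)
        np.testing.assert_array_equal(d1.decide(counts), d2.decide(counts))


class TestTrainingCurve:
    def test_perfect_decoder_flat_at_one(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        counts = (10 * y + 1)[None, :] + 0 * y
        rec = make_recording(counts, stimulus=y,
                             contrast=rng.choice(["high", "low"], 200))

        def factory(train_idx):
            return LinearThresholdDecoder(weights=np.array([1.0]), kind="SO",
                                          threshold=5.0)

        curve = evaluate_training_curve(factory, rec, [4, 8, 16],
                                        n_resamples=5, rng=0)
        np.testing.assert_allclose(curve.mean_accuracy, 1.0)
        assert curve.minimal_size_above_chance == 4

    def test_grid_truncated_to_available_data(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 40)
        rec = make_recording(rng.poisson(2.0, size=(2, 40)), stimulus=y,
                             contrast=["high"] * 40)

        def factory(train_idx):
            return LinearThresholdDecoder(weights=np.array([1.0, 0.0]),
                                          kind="SO", threshold=2.0)

        curve = evaluate_training_curve(factory, rec, [4, 8, 10**4],
                                        n_resamples=3, rng=0)
        assert curve.sizes.max() <= 40


@pytest.fixture(scope="module")
def sweep():
    base = PopulationSimConfig(
        n_informative=10, n_uninformative=90, n_inactive=0,
        modulator_law="iid-gaussian", seed=0,
    )
    return modulator_strength_sweep(
        base, [0.0, 0.125, 0.5, 2.0], decoders=("optimal", "MG", "SO"),
        n_train=1000, n_test=600, seeds=range(5),
    )


@pytest.fixture(scope="module")
def curves():
    cfg = PopulationSimConfig(
        n_informative=10, n_uninformative=190, n_inactive=0,
        modulator_law="iid-gaussian", seed=2,
    )
    lam0, lam1 = cfg.rates(np.random.default_rng(2))
    c = cfg.couplings(lam0, lam1)
    from modlabel.synthetic_data import sigma_m_for_relative_strength

    sigma = sigma_m_for_relative_strength(1.0, c, lam0, lam1)
    cfg = PopulationSimConfig(
        **{**cfg.__dict__, "lam0": lam0, "lam1": lam1, "sigma_m": sigma}
    )
    rec, m = simulate_iid_population(cfg, 400)
    counts, sums = rec.counts, rec.presentation_sums()
    labels = rec.presentation_meta["stimulus"].to_numpy()
    m_bins = m[:, None]

    def mg_factory(idx):
        return mg_decoder(counts[:, idx], m_bins[idx], labels[idx])

    def log_factory(idx):
        return baseline_decoder(sums[:, idx], labels[idx], kind="logistic")

    grid = [4, 8, 16, 32, 64]
    return (
        evaluate_training_curve(mg_factory, rec, grid, n_resamples=20, rng=0),
        evaluate_training_curve(log_factory, rec, grid, n_resamples=20, rng=0),
    )


class TestTrainingCurveComparison:
    """MG vs regression on a targeted-modulator population."""

    def test_mg_above_chance_from_minimal_training(self, curves):
        cu_mg, cu_lg = curves
        assert cu_mg.minimal_size_above_chance is not None
        assert cu_mg.minimal_size_above_chance <= cu_lg.minimal_size_above_chance

    def test_mg_weights_more_stable_across_training_sizes(self, curves):
        # minimal-training MG weights resemble the fully trained ones more
        # than the regression weights do
        cu_mg, cu_lg = curves
        assert cu_mg.weight_agreement > cu_lg.weight_agreement


def test_sweep_variants_preserve_mg_label(theory_population_cfg):
    """Corrupted couplings and multiunit pooling degrade but do not destroy
    the modulator label: MG stays above chance at moderate strength and
    below the ideal observer."""
    res = modulator_strength_sweep(
        theory_population_cfg, [0.0, 0.5], decoders=("optimal", "MG"),
        n_train=800, n_test=400, seeds=range(3),
        coupling_noise_sd=0.3, multiunits=True,
    )
    assert res["MG"]["mean"][1] > 0.55
    assert res["optimal"]["mean"][1] >= res["MG"]["mean"][1]


class TestStrengthSweep:

    def test_mg_at_zero_strength_is_chance(self, sweep):
        assert abs(sweep["MG"]["mean"][0] - 0.5) < 0.02

    def test_optimal_maximal_at_zero_strength(self, sweep):
        opt = sweep["optimal"]["mean"]
        assert opt[0] == opt.max()

    def test_optimal_non_increasing(self, sweep):
        rho = spearmanr(sweep["strength_grid"], sweep["optimal"]["mean"]).statistic
        assert rho <= 0

    def test_mg_interior_peak(self, sweep):
        mg = sweep["MG"]["mean"]
        peak = int(np.argmax(mg))
        assert 0 < peak < len(mg) - 1
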