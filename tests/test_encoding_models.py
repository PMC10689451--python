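import numpy as np
import pytest
from scipy.stats import spearmanr

from modlabel import (
    BlockSimConfig,
    build_design_matrix,
    fit_plds_em,
    fit_sr,
    fit_sr_plus_modulator,
    modulator_summaries,
    null_ll,
    poisson_ll,
    pseudo_r2,
    reference_subset,
    saturated_ll,
    select_dimensionality,
    simulate_ar1_block,
    simulate_downstream_units,
)
from modlabel.encoding_models import flatten_counts
from modlabel.synthetic_data import experiment_population

from conftest import make_recording


class TestDesignMatrix:
    def test_one_hot_windows_per_contrast(self):
        rec = make_recording(
            np.ones((2, 4, 6), dtype=int), n_stim_bins=4,
            contrast=["high", "low", "high", "low"],
        )
        des = build_design_matrix(rec)
        # 2 contrasts x 4 windows + after-stimulus + offset
        assert des.n_dims == 10
        X = des.X.reshape(4, 6, 10)
        for p, cl in enumerate(["high", "low", "high", "low"]):
            base = 0 if cl == "high" else 4
            for b in range(4):
                row = X[p, b]
                assert row[base + b] == 1.0
                assert row[:8].sum() == 1.0
                assert row[des.offset_index] == 1.0
        # inter-stimulus bins: only after-stimulus + offset active
        for p in range(4):
            for b in (4, 5):
                row = X[p, b]
                assert row[:8].sum() == 0.0
                assert row[8] == 1.0

    def test_drift_adds_one_column(self):
        rec = make_recording(np.ones((2, 4, 4), dtype=int))
        rec.presentation_meta["drift_direction"] = ["cw", "ccw", "cw", "ccw"]
        plain = build_design_matrix(rec)
        with_drift = build_design_matrix(rec, drift=True)
        assert with_drift.n_dims == plain.n_dims + 1
        assert "drift" in with_drift.columns

    def test_modulator_covariate_is_zscored(self):
        rec = make_recording(np.ones((2, 5, 4), dtype=int))
        m = np.arange(20.0)
        des = build_design_matrix(rec, modulator=m)
        col = des.X[:, des.columns.index("modulator")]
        assert abs(col.mean()) < 1e-12
        assert col.std() == pytest.approx(1.0)


class TestSRFit:
    def test_offset_only_recovers_log_mean(self):
        rng = np.random.default_rng(0)
        K = rng.poisson(4.2, size=(1, 4000))
        X = np.ones((4000, 1))
        fit = fit_sr(K, X, alpha=0.0)
        assert fit.coefficients[0, 0] == pytest.approx(np.log(K.mean()), abs=1e-6)

    def test_parameter_recovery_on_random_design(self):
        rng = np.random.default_rng(1)
        n, p, U = 12000, 4, 6
        X = np.column_stack([rng.normal(0, 0.5, size=(n, p - 1)), np.ones(n)])
        beta = rng.normal(0, 0.4, size=(U, p))
        beta[:, -1] = 0.5
        K = rng.poisson(np.exp(beta @ X.T))
        fit = fit_sr(K, X, alpha=0.0)
        rms = np.sqrt(np.mean((fit.coefficients - beta) ** 2))
        scale = np.sqrt(np.mean(beta**2))
        assert rms / scale < 0.05

    def test_large_ridge_shrinks_stimulus_coefficients(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.integers(0, 2, size=(500, 1)).astype(float),
                             np.ones(500)])
        K = rng.poisson(np.exp(1.0 * X[:, 0] + 0.5), size=(1, 500))
        small = fit_sr(K, X, alpha=0.0)
        # ridge applies to all but the last (offset) column of an SRDesign;
        # with a raw matrix all columns are penalized, so check via design
        rec = make_recording(K.reshape(1, 500, 1), n_stim_bins=1)
        des = build_design_matrix(rec)
        huge = fit_sr(rec, des, alpha=1e7)
        stim_cols = [i for i, c in enumerate(des.columns) if c != "offset"]
        assert np.abs(huge.coefficients[0, stim_cols]).max() < 1e-3
        # offset absorbs the mean rate
        assert huge.coefficients[0, des.offset_index] == pytest.approx(
            np.log(K.mean()), abs=0.01
        )

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        K = rng.poisson(2.0, size=(3, 400))
        X = np.column_stack([rng.normal(size=(400, 2)), np.ones(400)])
        f1 = fit_sr(K, X, alpha=1.0)
        f2 = fit_sr(K, X, alpha=1.0)
        np.testing.assert_array_equal(f1.coefficients, f2.coefficients)


class TestPseudoR2:
    def test_null_is_zero_and_saturated_is_one(self):
        rng = np.random.default_rng(4)
        K = rng.poisson(3.0, size=(2, 200))
        ll_null = null_ll(K)
        ll_sat = saturated_ll(K)
        np.testing.assert_allclose(pseudo_r2(ll_null, ll_null, ll_sat), 0.0)
        np.testing.assert_allclose(pseudo_r2(ll_sat, ll_null, ll_sat), 1.0)

    def test_zero_denominator_marked_undefined(self):
        assert np.isnan(pseudo_r2(1.0, 2.0, 2.0))

    def test_stimulus_driven_unit_improves_over_null(self, ar1_block):
        ref = reference_subset(ar1_block["rec"])
        des = build_design_matrix(ref)
        fit = fit_sr(ref, des, alpha=1.0)
        K = flatten_counts(ref).astype(float)
        r2 = pseudo_r2(poisson_ll(K, fit.log_rates(des.X)), null_ll(K), saturated_ll(K))
        assert np.nanmean(r2) > 0.05


@pytest.fixture(scope="module")
def plds_fit(ar1_block):
    ref = reference_subset(ar1_block["rec"])
    des = build_design_matrix(ref)
    return ref, des, fit_plds_em(ref, des, 1, max_iter=80, seed=0)


class TestPLDS:
    def test_d0_delegates_to_sr(self, ar1_block):
        ref = reference_subset(ar1_block["rec"])
        des = build_design_matrix(ref)
        f0 = fit_plds_em(ref, des, 0)
        fsr = fit_sr(ref, des)
        np.testing.assert_array_equal(f0.coefficients, fsr.coefficients)

    def test_em_objective_nondecreasing(self, plds_fit):
        _, _, fit = plds_fit
        tr = np.array(fit.em_trace)
        rel = np.diff(tr) / np.maximum(np.abs(tr[:-1]), 1.0)
        assert (rel > -1e-6).all()

    def test_determinism(self, ar1_block):
        ref = reference_subset(ar1_block["rec"])
        des = build_design_matrix(ref)
        f1 = fit_plds_em(ref, des, 1, max_iter=20, seed=4)
        f2 = fit_plds_em(ref, des, 1, max_iter=20, seed=4)
        np.testing.assert_array_equal(f1.C, f2.C)
        np.testing.assert_array_equal(f1.A, f2.A)

    def test_scale_convention_and_sign(self, plds_fit):
        _, _, fit = plds_fit
        from scipy.linalg import solve_discrete_lyapunov

        S = solve_discrete_lyapunov(fit.A, fit.Q)
        assert S[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert fit.C.sum() >= 0

    def test_coupling_and_timescale_recovery(self, plds_fit, ar1_block):
        ref, des, fit = plds_fit
        pop = ar1_block["pop"]
        c_true = pop.couplings(*pop.rates())
        # the session fixture is smaller than the full recovery setting
        # (30 units, 60 trials), so the bar here is slightly lower than the
        # full-size check in the acceptance suite
        rho = spearmanr(np.abs(fit.C[:, 0]), c_true).statistic
        assert rho > 0.7
        tau_hat = -1.0 / np.log(fit.A[0, 0])
        tau_true = -1.0 / np.log(pop.ar_coef)
        assert abs(tau_hat - tau_true) / tau_true < 0.3

    def test_modulator_path_tracks_truth(self, plds_fit, ar1_block):
        ref, des, fit = plds_fit
        rec, m = ar1_block["rec"], ar1_block["m"]
        ref_mask = np.repeat(
            (rec.presentation_meta["stimulus"] == 0).to_numpy(), rec.n_bins
        )
        r = np.corrcoef(fit.modulator_trace(), m[ref_mask])[0, 1]
        assert r > 0.6

    def test_null_data_gives_small_strength_and_no_fit_gain(self):
        # on modulator-free data the D=1 fit can only absorb sampling noise:
        # the strength estimate is small and the in-sample pseudo-R2 gain
        # over the SR model is negligible (the stringent null check is the
        # dimensionality selection, which picks D=0)
        pop = experiment_population(30, sigma_m=0.6, seed=21)
        pop.coupling_scale = 0.0
        rec, _ = simulate_ar1_block(pop, BlockSimConfig(n_trials=80, seed=21))
        ref = reference_subset(rec)
        des = build_design_matrix(ref)
        fit = fit_plds_em(ref, des, 1, max_iter=60, seed=0)
        summ = modulator_summaries(fit, des)
        assert summ["relative_strength"] < 0.1
        K = flatten_counts(ref).astype(float)
        sr = fit_sr(ref, des)
        eta = fit.B @ des.X.T + fit.C @ fit.posterior_means.T
        gain = np.nanmean(pseudo_r2(
            poisson_ll(K, eta), poisson_ll(K, sr.log_rates(des.X)), saturated_ll(K)
        ))
        assert gain < 0.02


class TestModulatorSummaries:
    def test_unit_decay_constant(self, plds_fit):
        _, des, fit = plds_fit
        import copy

        f = copy.copy(fit)
        f.A = np.array([[np.exp(-1.0)]])
        summ = modulator_summaries(f, des, bin_width_ms=50.0)
        assert summ["tau_ms"] == pytest.approx(50.0)

    def test_zero_couplings_zero_strength(self, plds_fit):
        _, des, fit = plds_fit
        import copy

        f = copy.copy(fit)
        f.C = np.zeros_like(fit.C)
        summ = modulator_summaries(f, des)
        assert summ["absolute_strength"] == 0.0
        assert summ["relative_strength"] == 0.0

    def test_nonpositive_dynamics_undefined_tau(self, plds_fit):
        _, des, fit = plds_fit
        import copy

        f = copy.copy(fit)
        f.A = np.array([[-0.2]])
        assert np.isnan(modulator_summaries(f, des)["tau_ms"])

    def test_scale_identifiability(self, plds_fit):
        # only the product of coupling magnitude and latent scale is
        # identifiable: scaling C by k and the latent SD by 1/k and then
        # renormalizing to the stationary-variance-1 convention recovers the
        # same parameters and the same strength metric
        from modlabel.encoding_models import _normalize_scale
        _, des, fit = plds_fit
        import copy

        k = 3.0
        A2, Q2, Q02, C2, _, _ = _normalize_scale(
            fit.A, fit.Q / k**2, fit.Q0 / k**2, fit.C * k
        )
        f = copy.copy(fit)
        f.A, f.Q, f.Q0, f.C = A2, Q2, Q02, C2
        np.testing.assert_allclose(C2, fit.C, rtol=1e-8)
        s1 = modulator_summaries(fit, des)["absolute_strength"]
        s2 = modulator_summaries(f, des)["absolute_strength"]
        assert s2 == pytest.approx(s1, rel=1e-8)


class TestSelectDimensionality:
    def test_tie_breaks_to_smaller(self, monkeypatch):
        # force identical scores by stubbing the scoring machinery
        from modlabel import encoding_models as em

        pop = experiment_population(6, seed=31)
        rec, _ = simulate_ar1_block(pop, BlockSimConfig(n_trials=12, seed=31))
        ref = reference_subset(rec)
        monkeypatch.setattr(em, "loo_predictive_ll", lambda *a, **k: -100.0)
        monkeypatch.setattr(
            em, "fit_plds_em",
            lambda rec, des, d, **k: em.fit_sr(rec, des) if d == 0 else object(),
        )
        monkeypatch.setattr(
            em, "poisson_ll", lambda K, lr: np.full(K.shape[0], -100.0 / K.shape[0])
        )
        sel = em.select_dimensionality(ref, D_range=(0, 1, 2), folds=2, seed=0)
        assert sel.selected_D == 0

    def test_reduces_folds_with_warning(self):
        pop = experiment_population(5, seed=32)
        rec, _ = simulate_ar1_block(pop, BlockSimConfig(n_trials=4, seed=32))
        ref = reference_subset(rec)
        with pytest.warns(UserWarning, match="reducing folds"):
            select_dimensionality(ref, D_range=(0,), folds=10, seed=0)


class TestSRPlusModulator:
    def test_uncoupled_downstream_no_improvement(self, ar1_block):
        rec, m = ar1_block["rec"], ar1_block["m"]
        lam = np.full(6, 1.5)
        down = simulate_downstream_units(m, rec, lam, lam, np.zeros(6), rng=0)
        down_ref = reference_subset(down)
        ref_mask = np.repeat(
            (rec.presentation_meta["stimulus"] == 0).to_numpy(), rec.n_bins
        )
        res = fit_sr_plus_modulator(down_ref, m[ref_mask])
        assert abs(np.nanmean(res["pseudo_r2_improvement"])) < 0.01

    def test_shuffled_modulator_collapses_improvement(self, ar1_block):
        rec, m = ar1_block["rec"], ar1_block["m"]
        lam = np.full(6, 1.5)
        coupl = np.full(6, 1.0)
        down = simulate_downstream_units(m, rec, lam, lam, coupl, rng=1)
        down_ref = reference_subset(down)
        ref_mask = np.repeat(
            (rec.presentation_meta["stimulus"] == 0).to_numpy(), rec.n_bins
        )
        m_ref = m[ref_mask]
        real = fit_sr_plus_modulator(down_ref, m_ref)
        rng = np.random.default_rng(0)
        shuf = fit_sr_plus_modulator(down_ref, rng.permutation(m_ref))
        gain_real = np.nanmean(real["pseudo_r2_improvement"])
        gain_shuf = np.nanmean(shuf["pseudo_r2_improvement"])
        assert gain_real > 0.02
        assert gain_shuf < 0.2 * gain_real

    def test_length_mismatch_rejected(self, ar1_block):
        ref = reference_subset(ar1_block["rec"])
        with pytest.raises(ValueError):
            fit_sr_plus_modulator(ref, np.zeros(7))
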