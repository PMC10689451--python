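"""Linear-threshold decoders for binary stimulus discrimination.

All decoders share one functional form: decide stimulus 1 when a weighted
sum of spike counts reaches a threshold,

    sum_n a_n k_n >= q,

with counts summed over the decoding window (200 ms, i.e. the stimulus-on
bins of a presentation). They differ in how weights and threshold are set:

* optimal — the ideal observer for the modulated-Poisson encoding model:
  a_n = log lambda_n(1) - log lambda_n(0); threshold either modulator-
  dependent, q(m_t) = sum_n gain_n(m_t) [lambda_n(1) - lambda_n(0)]
  (exactly Bayes-optimal given the modulator), or a constant fitted on
  training data.
* MG (modulator-guided) — weight magnitudes from modulator/response
  co-fluctuations, |a_n| = (1/T) sum_t m_t k_{n,t} over 50 ms bins, clipped
  at 0; signs from trial feedback (mean response to s=1 vs s=0 on labeled
  training data); constant threshold fitted on training data.
* SO (sign-only) — a_n = sign(lambda_n(1) - lambda_n(0)) in {-1, +1}.
* logistic / svm — regression baselines on per-presentation summed counts
  (L2-penalized logistic regression at strength 1; linear-kernel SVM).

Ties (score exactly at threshold) decide s = 1, fixed for determinism.
When the modulator-dependent threshold is applied to multi-bin windows,
per-bin decisions are combined by majority vote (ties toward s = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .population_data import PopulationRecording
from . import synthetic_data as syn


@dataclass
class LinearThresholdDecoder:
    """Weights, sign structure and threshold rule of a linear readout."""

    weights: np.ndarray
    kind: str  # optimal | MG | SO | logistic | svm
    threshold: float | None = None  # constant threshold
    #: parameters of the modulator-dependent threshold (optimal decoder)
    threshold_params: dict | None = None
    window_ms: float = 200.0

    def scores(self, counts: np.ndarray) -> np.ndarray:
        """Window-summed decision scores; counts is (U, P) or (U, P, T_b)."""
        counts = np.asarray(counts, dtype=float)
        if counts.ndim == 3:
            counts = counts.sum(axis=2)
        return self.weights @ counts

    def q_of_m(self, m: np.ndarray) -> np.ndarray:
        """Modulator-dependent per-bin threshold q(m)."""
        if self.threshold_params is None:
            raise ValueError("decoder has no modulator-dependent threshold")
        lam0 = self.threshold_params["lam0"]
        lam1 = self.threshold_params["lam1"]
        c = self.threshold_params["couplings"]
        corr = self.threshold_params["correction"]  # sigma_m^2 c^2 / 2 or zeros
        m = np.atleast_1d(np.asarray(m, dtype=float))
        gain = np.exp(np.multiply.outer(m, c) - corr[None, :])
        return gain @ (lam1 - lam0)

    def decide(self, counts: np.ndarray, m: np.ndarray | None = None) -> np.ndarray:
        """Binary decisions per presentation.

        With a constant threshold, counts are summed over the window and
        compared against q*. With a modulator-dependent threshold, counts
        must be (U, P, T_b) with ``m`` per bin (P, T_b) or per presentation
        (P,); per-bin decisions are combined by majority vote.
        """
        counts = np.asarray(counts, dtype=float)
        if self.threshold_params is not None and m is not None:
            if counts.ndim == 2:
                counts = counts[:, :, None]
            U, P, T = counts.shape
            m = np.asarray(m, dtype=float)
            if m.ndim == 1:
                m = np.repeat(m[:, None], T, axis=1)
            per_bin_scores = np.einsum("u,upt->pt", self.weights, counts)
            q = self.q_of_m(m.reshape(-1)).reshape(P, T)
            votes = (per_bin_scores >= q).sum(axis=1)
            return (votes >= T / 2.0).astype(int)
        if self.threshold is None:
            raise ValueError("decoder has no constant threshold")
        return (self.scores(counts) >= self.threshold).astype(int)

    def accuracy(self, counts, labels, m=None) -> float:
        pred = self.decide(counts, m=m)
        return float(np.mean(pred == np.asarray(labels)))


# ---------------------------------------------------------------------------
# threshold fitting
# ---------------------------------------------------------------------------

def fit_constant_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive scan over midpoints of sorted training scores.

    Candidates are the midpoints between adjacent sorted scores plus
    sentinels below/above the range; decision is s=1 when score >= q.
    Ties in training accuracy resolve to the midpoint of the optimal
    candidate interval.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    if len(uniq) == 1:
        candidates = np.array([uniq[0] - 1.0, uniq[0], uniq[0] + 1.0])
    else:
        mids = 0.5 * (uniq[:-1] + uniq[1:])
        candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    acc = np.array([np.mean((scores >= q).astype(int) == labels) for q in candidates])
    best = np.flatnonzero(acc == acc.max())
    # midpoint of the (first contiguous) optimal interval
    run_end = best[0]
    while run_end + 1 < len(candidates) and acc[run_end + 1] == acc.max():
        run_end += 1
    return float(0.5 * (candidates[best[0]] + candidates[run_end]))


# ---------------------------------------------------------------------------
# decoder constructors
# ---------------------------------------------------------------------------

def optimal_decoder(
    lam0: np.ndarray,
    lam1: np.ndarray,
    couplings: np.ndarray | None = None,
    sigma_m: float = 0.0,
    *,
    mean_correction: bool = True,
    mode: str = "modulator",
    train_counts: np.ndarray | None = None,
    train_labels: np.ndarray | None = None,
) -> LinearThresholdDecoder:
    """The ideal observer for the modulated-Poisson encoding model.

    ``lam0``/``lam1`` are per-unit rates for the decoding window (or per
    bin, matching the counts the decoder will see). In ``"modulator"`` mode
    the threshold is the modulator-dependent q(m); in ``"constant"`` mode a
    single threshold is fitted on labeled training data.
    """
    lam0 = np.asarray(lam0, dtype=float)
    lam1 = np.asarray(lam1, dtype=float)
    with np.errstate(divide="ignore"):
        a = np.where(lam1 == lam0, 0.0, np.log(lam1) - np.log(lam0))
    bad = np.flatnonzero(((lam0 <= 0) | (lam1 <= 0)) & (a != 0))
    if len(bad):
        raise ValueError(f"zero rate in weighted unit {bad[0]}")
    if couplings is None:
        couplings = np.zeros_like(lam0)
    couplings = np.asarray(couplings, dtype=float)
    correction = (
        0.5 * sigma_m**2 * couplings**2 if mean_correction else np.zeros_like(couplings)
    )
    dec = LinearThresholdDecoder(
        weights=a,
        kind="optimal",
        threshold_params={
            "lam0": lam0,
            "lam1": lam1,
            "couplings": couplings,
            "correction": correction,
        },
    )
    if mode == "constant":
        if train_counts is None or train_labels is None:
            raise ValueError("constant mode requires labeled training data")
        dec.threshold = fit_constant_threshold(dec.scores(train_counts), train_labels)
        dec.threshold_params = None
    elif mode != "modulator":
        raise ValueError(f"unknown mode {mode!r}")
    return dec


def mg_decoder(
    train_counts: np.ndarray,
    modulator: np.ndarray,
    train_labels: np.ndarray,
) -> LinearThresholdDecoder:
    """Modulator-guided decoder learned from training data only.

    ``train_counts``: (U, P) or (U, P, T_b) spike counts at the modulator's
    bin resolution; ``modulator``: matching per-bin trace; ``train_labels``:
    stimulus identity per presentation (trial feedback), used for the signs
    and the constant threshold.
    """
    counts = np.asarray(train_counts, dtype=float)
    if counts.ndim == 2:
        counts = counts[:, :, None]
    U, P, T = counts.shape
    m = np.asarray(modulator, dtype=float).reshape(P, -1)
    if m.shape[1] == 1 and T > 1:
        m = np.repeat(m, T, axis=1)
    if m.shape[1] != T:
        raise ValueError("modulator trace does not align to count bins")
    labels = np.asarray(train_labels)
    if not ((labels == 0).any() and (labels == 1).any()):
        raise ValueError("need labeled examples of both stimuli to set signs")

    magnitude = np.clip(np.einsum("upt,pt->u", counts, m) / (P * T), 0.0, None)
    mean1 = counts[:, labels == 1].sum(axis=2).mean(axis=1)
    mean0 = counts[:, labels == 0].sum(axis=2).mean(axis=1)
    signs = np.where(mean1 >= mean0, 1.0, -1.0)
    weights = signs * magnitude
    dec = LinearThresholdDecoder(weights=weights, kind="MG")
    dec.threshold = fit_constant_threshold(dec.scores(counts), labels)
    return dec


def so_decoder(
    lam0: np.ndarray,
    lam1: np.ndarray,
    train_counts: np.ndarray | None = None,
    train_labels: np.ndarray | None = None,
) -> LinearThresholdDecoder:
    """Sign-only decoder: a_n = sign(lambda(1) - lambda(0)) in {-1, +1}.

    Rates may be true values or training-set mean responses; zero
    differences are assigned +1. The constant threshold is fitted on
    training data when provided, else 0.
    """
    diff = np.asarray(lam1, dtype=float) - np.asarray(lam0, dtype=float)
    weights = np.where(diff >= 0, 1.0, -1.0)
    dec = LinearThresholdDecoder(weights=weights, kind="SO")
    if train_counts is not None and train_labels is not None:
        dec.threshold = fit_constant_threshold(dec.scores(train_counts), train_labels)
    else:
        dec.threshold = 0.0
    return dec


def baseline_decoder(
    train_counts: np.ndarray,
    train_labels: np.ndarray,
    kind: str = "logistic",
) -> LinearThresholdDecoder:
    """Regression baselines on per-presentation window-summed counts.

    ``logistic``: L2-penalized logistic regression at regularization
    strength 1; ``svm``: linear-kernel SVM at default regularization.
    """
    counts = np.asarray(train_counts, dtype=float)
    if counts.ndim == 3:
        counts = counts.sum(axis=2)
    X = counts.T  # (P, U)
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if kind == "logistic":
        # L2 penalty at regularization strength alpha = 1 (C = 1/alpha)
        model = LogisticRegression(C=1.0, max_iter=2000)
    elif kind == "svm":
        model = LinearSVC()
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    model.fit(X, y)
    weights = model.coef_.ravel()
    threshold = -float(model.intercept_[0])
    return LinearThresholdDecoder(weights=weights, kind=kind, threshold=threshold)


# ---------------------------------------------------------------------------
# evaluation protocol
# ---------------------------------------------------------------------------

@dataclass
class TrainingCurve:
    sizes: np.ndarray
    mean_accuracy: np.ndarray
    se_accuracy: np.ndarray
    minimal_training_accuracy: float
    minimal_size_above_chance: int | None
    weight_agreement: float
    accuracies: np.ndarray = field(repr=False, default=None)  # (sizes, resamples)


def _balanced_sample(cells: list[np.ndarray], size: int, rng) -> np.ndarray:
    """Draw ``size`` presentations balanced across stimulus-contrast cells."""
    n_cells = len(cells)
    per = max(size // n_cells, 1)
    chosen = []
    for cell in cells:
        take = min(per, len(cell))
        chosen.append(rng.choice(cell, size=take, replace=False))
    return np.concatenate(chosen)


def evaluate_training_curve(
    decoder_factory,
    rec: PopulationRecording,
    grid: np.ndarray | list[int],
    n_resamples: int = 20,
    rng: np.random.Generator | int | None = None,
    test_fraction: float = 0.3,
) -> TrainingCurve:
    """Held-out accuracy as a function of training-set size.

    ``decoder_factory(train_idx)`` builds a decoder from the given
    presentations. Training subsets are balanced over stimulus x contrast
    cells; the held-out test set is disjoint from every training subset.
    The minimal size whose pooled test decisions beat chance is assessed by
    a one-sided binomial proportion test at 0.05. Weight agreement is the
    mean Pearson correlation between minimal-training weight vectors and
    the weights fitted on the full training pool.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    grid = np.asarray(sorted(grid), dtype=int)
    meta = rec.presentation_meta
    labels = meta["stimulus"].to_numpy()
    counts_window = rec.presentation_sums()

    # stratified train-pool / test split
    cells_all = [
        grp.index.to_numpy()
        for _, grp in meta.groupby(["stimulus", "contrast"], sort=True)
    ]
    test_idx, pool_cells = [], []
    for cell in cells_all:
        cell = rng.permutation(cell)
        n_test = max(int(round(test_fraction * len(cell))), 1)
        test_idx.append(cell[:n_test])
        pool_cells.append(cell[n_test:])
    test_idx = np.concatenate(test_idx)

    max_avail = sum(len(c) for c in pool_cells)
    grid = grid[grid <= max_avail]

    accs = np.full((len(grid), n_resamples), np.nan)
    weights_min: list[np.ndarray] = []
    for si, size in enumerate(grid):
        for ri in range(n_resamples):
            train_idx = _balanced_sample(pool_cells, int(size), rng)
            dec = decoder_factory(train_idx)
            accs[si, ri] = dec.accuracy(counts_window[:, test_idx], labels[test_idx])
            if si == 0:
                weights_min.append(dec.weights.copy())

    mean_acc = accs.mean(axis=1)
    se_acc = accs.std(axis=1, ddof=1) / np.sqrt(n_resamples)

    # minimal size beating chance (pooled binomial test)
    n_test = len(test_idx)
    minimal = None
    for si, size in enumerate(grid):
        k = int(round(mean_acc[si] * n_test * n_resamples))
        res = stats.binomtest(k, n_test * n_resamples, 0.5, alternative="greater")
        if res.pvalue < 0.05:
            minimal = int(size)
            break

    dec_full = decoder_factory(np.concatenate(pool_cells))
    w_full = dec_full.weights
    agreements = []
    for w in weights_min:
        if np.std(w) > 0 and np.std(w_full) > 0:
            agreements.append(np.corrcoef(w, w_full)[0, 1])
    agreement = float(np.mean(agreements)) if agreements else np.nan

    return TrainingCurve(
        sizes=grid,
        mean_accuracy=mean_acc,
        se_accuracy=se_acc,
        minimal_training_accuracy=float(mean_acc[0]),
        minimal_size_above_chance=minimal,
        weight_agreement=agreement,
        accuracies=accs,
    )


# ---------------------------------------------------------------------------
# modulator-strength sweep
# ---------------------------------------------------------------------------

def modulator_strength_sweep(
    base_cfg: syn.PopulationSimConfig,
    strength_grid,
    decoders=("optimal", "MG", "SO"),
    n_train: int = 5000,
    n_test: int = 1000,
    seeds=(0, 1, 2, 3, 4),
    coupling_noise_sd: float = 0.0,
    multiunits: bool = False,
) -> dict:
    """Decoding accuracy vs relative modulator strength, per decoder.

    For each grid point the modulator SD is set so that the population's
    relative modulator strength (modulator- over stimulus-induced variance)
    equals the grid value; fresh training and test populations are
    simulated per seed with mean correction on. Variants: couplings
    corrupted by Gaussian noise before being handed to the generator, or
    multiunit recordings formed by summing random unit pairs.

    Returns a dict with per-decoder mean accuracy and normal-approximation
    95% confidence intervals over seeds.
    """
    strength_grid = np.asarray(strength_grid, dtype=float)
    acc = {d: np.full((len(strength_grid), len(seeds)), np.nan) for d in decoders}

    for gi, rel in enumerate(strength_grid):
        for si, seed in enumerate(seeds):
            rng = np.random.default_rng(seed)
            cfg = syn.PopulationSimConfig(**{**base_cfg.__dict__, "seed": seed})
            lam0, lam1 = cfg.rates(np.random.default_rng(cfg.seed))
            c_clean = cfg.coupling_scale * np.abs(np.log(lam1) - np.log(lam0))
            c = (
                syn.corrupt_couplings(c_clean, coupling_noise_sd, rng)
                if coupling_noise_sd > 0
                else c_clean
            )
            sigma = syn.sigma_m_for_relative_strength(rel, c, lam0, lam1)
            cfg = syn.PopulationSimConfig(
                **{**cfg.__dict__, "lam0": lam0, "lam1": lam1, "sigma_m": sigma,
                   "coupling_noise_sd": 0.0}
            )
            # simulate with the (possibly corrupted) couplings
            rec_tr, m_tr = _simulate_with_couplings(cfg, c, n_train // 2, rng)
            rec_te, m_te = _simulate_with_couplings(cfg, c, n_test // 2, rng)
            k_tr = rec_tr.presentation_sums()
            y_tr = rec_tr.presentation_meta["stimulus"].to_numpy()
            k_te = rec_te.presentation_sums()
            y_te = rec_te.presentation_meta["stimulus"].to_numpy()
            k_tr_bins, k_te_bins = rec_tr.counts, rec_te.counts
            lam0_d, lam1_d, c_d = lam0, lam1, c_clean
            if multiunits:
                pair_rng = np.random.default_rng(seed + 1000)
                rec_tr = syn.simulate_multiunits(rec_tr, pair_rng)
                pair_rng = np.random.default_rng(seed + 1000)
                rec_te = syn.simulate_multiunits(rec_te, pair_rng)
                k_tr = rec_tr.presentation_sums()
                k_te = rec_te.presentation_sums()
                k_tr_bins, k_te_bins = rec_tr.counts, rec_te.counts
                # the ideal observer is specified for single units; for the
                # multiunit variant it sees summed-pair rates and mean couplings
                pair_rng = np.random.default_rng(seed + 1000)
                perm = pair_rng.permutation(len(lam0))
                if len(perm) % 2 == 1:
                    perm = perm[:-1]
                pairs = perm.reshape(-1, 2)
                lam0_d = lam0[pairs].sum(axis=1)
                lam1_d = lam1[pairs].sum(axis=1)
                c_d = c_clean[pairs].mean(axis=1)

            for dname in decoders:
                if dname == "optimal":
                    dec = optimal_decoder(lam0_d, lam1_d, c_d, cfg.sigma_m)
                    acc[dname][gi, si] = np.mean(
                        dec.decide(k_te_bins, m=m_te) == y_te
                    )
                elif dname == "MG":
                    dec = mg_decoder(k_tr_bins, m_tr, y_tr)
                    acc[dname][gi, si] = dec.accuracy(k_te, y_te)
                elif dname == "SO":
                    mean0 = k_tr[:, y_tr == 0].mean(axis=1)
                    mean1 = k_tr[:, y_tr == 1].mean(axis=1)
                    dec = so_decoder(mean0, mean1, k_tr, y_tr)
                    acc[dname][gi, si] = dec.accuracy(k_te, y_te)
                elif dname in ("logistic", "svm"):
                    dec = baseline_decoder(k_tr, y_tr, kind=dname)
                    acc[dname][gi, si] = dec.accuracy(k_te, y_te)
                else:
                    raise ValueError(f"unknown decoder {dname!r}")

    out = {"strength_grid": strength_grid, "accuracy": acc}
    for d in decoders:
        mean = acc[d].mean(axis=1)
        half = 1.96 * acc[d].std(axis=1, ddof=1) / np.sqrt(len(seeds))
        out[d] = {"mean": mean, "ci_low": mean - half, "ci_high": mean + half}
    return out


def _simulate_with_couplings(cfg, couplings, per_stim, rng):
    """i.i.d.-modulator simulation with explicit couplings."""
    lam0, lam1 = cfg.rates(np.random.default_rng(cfg.seed))
    n_p = 2 * per_stim
    stimulus = np.tile([0, 1], per_stim)
    m = rng.normal(0.0, cfg.sigma_m, size=n_p)
    lam = np.where(stimulus[None, :] == 1, lam1[:, None], lam0[:, None])
    gain = np.exp(couplings[:, None] * m[None, :])
    if cfg.mean_correction:
        gain = gain * np.exp(-0.5 * cfg.sigma_m**2 * couplings[:, None] ** 2)
    counts = rng.poisson(lam * gain)[:, :, None]
    meta = pd.DataFrame(
        {
            "block": 0,
            "trial": np.arange(n_p),
            "repeat_index": 1,
            "contrast": "high",
            "stimulus": stimulus,
            "outcome": "hit",
        }
    )
    rec = PopulationRecording(
        counts=counts, presentation_meta=meta,
        bin_width_ms=cfg.bin_width_ms, n_stim_bins=1,
    )
    return rec, m
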