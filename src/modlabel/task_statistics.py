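"""Task statistics for modulated population recordings.

Implements the bespoke statistics used throughout the analysis:

* d-prime informativeness of a unit with a permutation null built from
  random splits of the reference-stimulus responses,
* choice d-prime (hit vs miss trials instead of stimulus identity),
* rank-based partial correlation (covariates regressed out of the target,
  residuals Spearman-correlated with the predictor),
* two-group comparisons (rank-sum U and two-sample t),
* within-trial cross-correlograms between modulator traces,
* within-condition Fano factors.

Undefined results (zero variance, single-outcome blocks, constant residuals,
zero-mean counts) are reported as ``nan`` rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class DPrimeResult:
    value: float
    p_value: float


def dprime(
    responses_0: np.ndarray,
    responses_1: np.ndarray,
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> DPrimeResult:
    """Absolute standardized response difference between the two stimuli.

        d' = |mu_0 - mu_1| / sqrt(0.5 (sigma_0^2 + sigma_1^2))

    The permutation p-value compares the observed d' against a null built by
    splitting the stimulus-0 responses into two random disjoint subsets whose
    sizes match the (0, 1) group-size ratio; it is the (add-one smoothed)
    fraction of null values at or above the observed one.
    """
    r0 = np.asarray(responses_0, dtype=float)
    r1 = np.asarray(responses_1, dtype=float)
    if len(r0) < 2 or len(r1) < 2:
        raise ValueError("need at least 2 presentations per stimulus")
    d = _dprime_value(r0, r1)
    if not np.isfinite(d):
        return DPrimeResult(np.nan, np.nan)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n0, n1 = len(r0), len(r1)
    # match the true group sizes as closely as the n0 samples allow: the
    # second subset gets n1 elements when possible, so the null d' has the
    # same sampling variability as the observed statistic
    n_b = min(max(n1, 2), n0 - 2)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(n0)
        null[i] = _dprime_value(r0[perm[n_b:]], r0[perm[:n_b]])
    null = null[np.isfinite(null)]
    p = (1.0 + np.sum(null >= d)) / (1.0 + len(null))
    return DPrimeResult(float(d), float(p))


def _dprime_value(a: np.ndarray, b: np.ndarray) -> float:
    pooled = 0.5 * (a.var(ddof=1) + b.var(ddof=1))
    if pooled <= 0:
        return np.nan
    return float(abs(a.mean() - b.mean()) / np.sqrt(pooled))


def choice_dprime(hit_responses: np.ndarray, miss_responses: np.ndarray) -> float:
    """d' over behavioral outcomes: target responses on hit vs miss trials."""
    h = np.asarray(hit_responses, dtype=float)
    m = np.asarray(miss_responses, dtype=float)
    if len(h) < 2 or len(m) < 2:
        return np.nan
    return _dprime_value(h, m)


def partial_correlation(
    target: np.ndarray,
    predictor: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Spearman correlation of covariate-residualized target with predictor.

    The covariates (one or two columns, plus an intercept) are linearly
    regressed out of the target; the residuals are then rank-correlated with
    the predictor. With no covariates this reduces to the ordinary Spearman
    correlation. Returns (coefficient, p_value); undefined results are nan.
    """
    y = np.asarray(target, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if covariates is None or (hasattr(covariates, "size") and np.size(covariates) == 0):
        resid = y - y.mean()
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != len(y):
            Z = Z.T
        if len(y) < 5:
            raise ValueError("need at least 5 observations")
        Z1 = np.column_stack([np.ones(len(y)), Z])
        if np.linalg.matrix_rank(Z1) < Z1.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        coef, *_ = np.linalg.lstsq(Z1, y, rcond=None)
        resid = y - Z1 @ coef
    if np.allclose(resid, 0) or np.allclose(x, x[0]):
        return np.nan, np.nan
    rho, p = stats.spearmanr(resid, x)
    return float(rho), float(p)


def compare_groups(
    group_a: np.ndarray,
    group_b: np.ndarray,
    test: str = "ranksum",
) -> tuple[float, float]:
    """Two-sided two-group comparison: rank-sum U or two-sample t.

    Used for relevant-vs-control modulator strength, informative-vs-
    uninformative fit improvement, and coupling-rank comparisons.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if test == "ranksum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "ttest":
        res = stats.ttest_ind(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def coupling_ranks(couplings: np.ndarray) -> np.ndarray:
    """Relative within-block rank (in [0, 1]) of coupling magnitudes."""
    c = np.abs(np.asarray(couplings, dtype=float))
    ranks = stats.rankdata(c)
    return (ranks - 1) / (len(c) - 1) if len(c) > 1 else np.zeros_like(c)


def cross_correlogram(
    trace_a: np.ndarray,
    trace_b: np.ndarray,
    max_lag: int,
    trial_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pearson correlation of two aligned traces at integer lags.

    Correlations are computed only over valid within-trial overlaps (no
    correlation across trial boundaries). Positive lag means trace A leads
    trace B: the reported value at lag L is corr(a_t, b_{t+L}).

    Returns (lags, correlations, peak_lag).
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("traces must have equal length")
    if trial_ids is None:
        trial_ids = np.zeros(len(a), dtype=int)
    trial_ids = np.asarray(trial_ids)
    min_len = min(np.bincount(np.unique(trial_ids, return_inverse=True)[1]))
    if max_lag >= min_len:
        raise ValueError("max lag exceeds the shortest trial")
    lags = np.arange(-max_lag, max_lag + 1)
    corrs = np.empty(len(lags))
    for i, lag in enumerate(lags):
        xs, ys = [], []
        for trial in np.unique(trial_ids):
            idx = np.flatnonzero(trial_ids == trial)
            seg_a, seg_b = a[idx], b[idx]
            if lag >= 0:
                x, y = seg_a[: len(idx) - lag], seg_b[lag:]
            else:
                x, y = seg_a[-lag:], seg_b[: len(idx) + lag]
            if len(x) >= 2:
                xs.append(x)
                ys.append(y)
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        sx, sy = x.std(), y.std()
        corrs[i] = np.nan if sx == 0 or sy == 0 else np.corrcoef(x, y)[0, 1]
    peak = int(lags[np.nanargmax(corrs)])
    return lags, corrs, peak


def fano_factor(
    presentation_counts: np.ndarray,
    conditions: np.ndarray | None = None,
) -> float:
    """Variance/mean of per-presentation summed counts, within condition.

    ``conditions`` assigns each presentation to a matched stimulus condition
    (e.g. contrast x repeat class); the Fano factor is computed within each
    condition with >= 2 presentations and nonzero mean, then averaged.
    """
    x = np.asarray(presentation_counts, dtype=float)
    if conditions is None:
        conditions = np.zeros(len(x), dtype=int)
    conditions = np.asarray(conditions)
    values = []
    for cond in np.unique(conditions):
        xc = x[conditions == cond]
        if len(xc) < 2:
            continue
        mu = xc.mean()
        if mu > 0:
            values.append(xc.var(ddof=1) / mu)
    return float(np.mean(values)) if values else np.nan
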