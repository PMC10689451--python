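"""Stimulus-response and modulated stimulus-response (PLDS) models.

The stimulus-response (SR) model is per-unit Poisson regression of binned
spike counts on a one-hot stimulus design:

    k_{n,t} ~ Poisson(exp(beta_n . s_t)),

with an L2 (ridge) penalty on the non-offset coefficients. The design has,
per contrast level, one indicator per 50 ms window of the stimulus-on
period (8 stimulus dimensions for a two-contrast, 4-window primary-area
model), an after-stimulus indicator for the inter-stimulus bins, an always-
on offset, and optionally a drift-direction indicator (downstream area)
and/or an external z-scored modulator covariate.

The modulated-SR model augments the SR model with a low-dimensional latent
modulator entering through the exponential link:

    k_t ~ Poisson(exp(C m_t + B s_t)),   m_{t+1} = A m_t + eps,
    eps ~ N(0, Q),  m_0 ~ N(0, Q0),

with trials treated as independent sequences. It is fitted by EM with a
per-trial Laplace approximation in the E step (damped Newton on the joint
latent posterior, exploiting the block-tridiagonal Hessian), and closed-form
(A, Q, Q0) plus per-unit Newton (C, B) updates in the M step. The latent
scale is fixed by normalizing the stationary variance to 1 per dimension
(the coupling matrix C carries the magnitude) and the sign by requiring
sum(C) >= 0 per dimension.

Model comparison uses trial-stratified cross-validation with leave-one-
neuron-out (LOO) predictive likelihoods for the latent models, averaging
over posterior uncertainty by sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_discrete_lyapunov
from scipy.special import gammaln

from .population_data import PopulationRecording


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class SRDesign:
    """Design specification plus the realized per-bin design rows."""

    columns: list
    X: np.ndarray  # (n_bins_total, p), presentation-major bin order
    offset_index: int
    bin_trial: np.ndarray  # trial id per row
    n_bins_per_presentation: int

    @property
    def n_dims(self) -> int:
        return self.X.shape[1]


def build_design_matrix(
    rec: PopulationRecording,
    *,
    drift: bool = False,
    modulator: np.ndarray | None = None,
    contrast_levels: list | None = None,
) -> SRDesign:
    """Build the one-hot SR design for a recording.

    Each stimulus-on bin activates exactly one (contrast, window) indicator;
    inter-stimulus bins activate the after-stimulus indicator; the offset is
    always 1. ``drift`` adds a drift-direction indicator (downstream area);
    ``modulator`` appends an externally estimated, z-scored modulator trace
    (one value per bin).
    """
    meta = rec.presentation_meta
    n_p, n_bins, n_on = rec.n_presentations, rec.n_bins, rec.n_stim_bins
    contrasts = contrast_levels or sorted(meta["contrast"].unique())
    unknown = set(meta["contrast"]) - set(contrasts) | (set(contrasts) - {"high", "low"})
    if unknown:
        raise ValueError(f"unknown contrast level {sorted(unknown)}")

    columns: list = [f"{cl}:w{j}" for cl in contrasts for j in range(n_on)]
    columns.append("after_stimulus")
    if drift:
        if "drift_direction" not in meta.columns:
            raise ValueError("drift requested but metadata has no drift_direction")
        columns.append("drift")
    if modulator is not None:
        columns.append("modulator")
    columns.append("offset")

    n_rows = n_p * n_bins
    X = np.zeros((n_rows, len(columns)))
    col_of = {name: i for i, name in enumerate(columns)}
    contrast_idx = meta["contrast"].map({cl: i for i, cl in enumerate(contrasts)}).to_numpy()
    rows = np.arange(n_rows)
    pres = rows // n_bins
    b = rows % n_bins
    on = b < n_on
    X[rows[on], contrast_idx[pres[on]] * n_on + b[on]] = 1.0
    X[rows[~on], col_of["after_stimulus"]] = 1.0
    if drift:
        cw = (meta["drift_direction"] == "cw").to_numpy()
        X[rows, col_of["drift"]] = cw[pres].astype(float)
    if modulator is not None:
        m = np.asarray(modulator, dtype=float)
        if len(m) != n_rows:
            raise ValueError("modulator length does not match bin count")
        X[:, col_of["modulator"]] = (m - m.mean()) / m.std()
    X[:, col_of["offset"]] = 1.0

    bin_trial = meta["trial"].to_numpy()[pres]
    return SRDesign(columns, X, col_of["offset"], bin_trial, n_bins)


def reference_subset(rec: PopulationRecording) -> PopulationRecording:
    """Restrict to reference (stimulus 0) presentations, as used for fitting."""
    return rec.select_presentations((rec.presentation_meta["stimulus"] == 0).to_numpy())


def flatten_counts(rec: PopulationRecording) -> np.ndarray:
    """Counts as (U, n_bins_total) in presentation-major bin order."""
    return rec.counts.reshape(rec.n_units, -1)


# ---------------------------------------------------------------------------
# SR model (Poisson ridge regression)
# ---------------------------------------------------------------------------

@dataclass
class SRFit:
    coefficients: np.ndarray  # (U, p)
    alpha: float
    design: SRDesign | None
    train_ll: np.ndarray | None = None  # per unit

    def log_rates(self, X: np.ndarray) -> np.ndarray:
        return self.coefficients @ X.T  # (U, N)


class FitConvergenceError(RuntimeError):
    pass


def poisson_ridge(
    K: np.ndarray,
    X: np.ndarray,
    alpha: float = 1.0,
    unpenalized: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """Penalized Poisson regression, jointly for all units.

    Maximizes sum_t [k_t eta_t - exp(eta_t)] - alpha * ||beta||^2 per unit
    (the offset column is unpenalized) by damped Newton iterations; the
    problem is strictly convex for alpha > 0, so the result is deterministic.
    """
    K = np.atleast_2d(np.asarray(K, dtype=float))
    U, N = K.shape
    p = X.shape[1]
    pen = np.full(p, 2.0 * alpha)
    if unpenalized is not None:
        pen[unpenalized] = 0.0
    # init: offset at log mean rate
    beta = np.zeros((U, p))
    if unpenalized is not None:
        beta[:, unpenalized] = np.log(np.maximum(K.mean(axis=1), 1e-3))
    eta = beta @ X.T
    for it in range(max_iter):
        r = np.exp(np.clip(eta, -30, 30))
        grad = (K - r) @ X - pen[None, :] * beta
        gnorm = np.abs(grad).max()
        if gnorm < tol * max(1.0, np.abs(K).sum() / U):
            return beta
        # Hessian per unit: X^T diag(r_u) X + pen
        H = np.einsum("un,np,nq->upq", r, X, X, optimize=True)
        H[:, np.arange(p), np.arange(p)] += pen[None, :] + 1e-9
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        # damped update with objective check per unit
        obj = _poisson_obj(K, eta, beta, pen)
        t = np.ones(U)
        for _ in range(30):
            beta_new = beta + t[:, None] * step
            eta_new = beta_new @ X.T
            obj_new = _poisson_obj(K, eta_new, beta_new, pen)
            bad = obj_new < obj - 1e-12
            if not bad.any():
                break
            t[bad] *= 0.5
        beta, eta = beta_new, eta_new
    gnorm = np.abs((K - np.exp(np.clip(eta, -30, 30))) @ X - pen[None, :] * beta).max()
    if gnorm > 1e-3 * max(1.0, np.abs(K).sum() / U):
        raise FitConvergenceError(f"Poisson regression did not converge (|grad|={gnorm:.3g})")
    return beta


def _poisson_obj(K, eta, beta, pen):
    r = np.exp(np.clip(eta, -30, 30))
    return (K * eta - r).sum(axis=1) - 0.5 * (pen[None, :] * beta**2).sum(axis=1)


def fit_sr(
    rec_or_counts,
    design: SRDesign | np.ndarray,
    alpha: float = 1.0,
) -> SRFit:
    """Fit the SR model (per-unit Poisson ridge regression)."""
    if isinstance(rec_or_counts, PopulationRecording):
        K = flatten_counts(rec_or_counts)
    else:
        K = np.atleast_2d(np.asarray(rec_or_counts, dtype=float))
    if isinstance(design, SRDesign):
        X, offset = design.X, design.offset_index
        dsg = design
    else:
        X, offset, dsg = np.asarray(design, dtype=float), None, None
    beta = poisson_ridge(K, X, alpha=alpha, unpenalized=offset)
    ll = poisson_ll(K, beta @ X.T)
    return SRFit(coefficients=beta, alpha=alpha, design=dsg, train_ll=ll)


def poisson_ll(K: np.ndarray, log_rates: np.ndarray) -> np.ndarray:
    """Per-unit Poisson log-likelihood (including the log k! term)."""
    eta = np.clip(log_rates, -30, 30)
    return (K * eta - np.exp(eta) - gammaln(K + 1.0)).sum(axis=-1)


def saturated_ll(K: np.ndarray) -> np.ndarray:
    """Per-unit log-likelihood of the saturated model (rate = observed count)."""
    K = np.asarray(K, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(K > 0, K * np.log(K) - K, 0.0)
    return (term - gammaln(K + 1.0)).sum(axis=-1)


def null_ll(K: np.ndarray) -> np.ndarray:
    """Per-unit log-likelihood of the mean-rate (constant) null model."""
    K = np.atleast_2d(np.asarray(K, dtype=float))
    mean = np.maximum(K.mean(axis=1, keepdims=True), 1e-12)
    return poisson_ll(K, np.log(mean) * np.ones_like(K))


def pseudo_r2(model_ll, null_ll_, saturated_ll_) -> np.ndarray:
    """Fraction of the null-to-saturated log-likelihood gain achieved.

    Returns nan where the denominator vanishes. The null model scores 0 by
    construction; the saturated model scores 1; held-out evaluation may fall
    outside [0, 1].
    """
    num = np.asarray(model_ll) - np.asarray(null_ll_)
    den = np.asarray(saturated_ll_) - np.asarray(null_ll_)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, num / den, np.nan)
    return out


# ---------------------------------------------------------------------------
# PLDS: Laplace E-step machinery
# ---------------------------------------------------------------------------

def _segments_by_length(bin_trial: np.ndarray) -> dict[int, np.ndarray]:
    """Group trials by length; maps T -> array of segment start rows."""
    starts: dict[int, list[int]] = {}
    ids, index = np.unique(bin_trial, return_index=True)
    order = np.argsort(index)
    pos = 0
    for trial in ids[order]:
        n = int((bin_trial == trial).sum())
        starts.setdefault(n, []).append(pos)
        pos += n
    return {T: np.asarray(v) for T, v in starts.items()}


class _PLDSData:
    """Counts and design rows regrouped into equal-length trial batches."""

    def __init__(self, K: np.ndarray, X: np.ndarray, bin_trial: np.ndarray):
        self.U = K.shape[0]
        self.p = X.shape[1]
        self.groups = []
        seen = list(bin_trial[np.sort(np.unique(bin_trial, return_index=True)[1])])
        by_len: dict[int, list[tuple[int, np.ndarray]]] = {}
        for trial in seen:
            idx = np.flatnonzero(bin_trial == trial)
            by_len.setdefault(len(idx), []).append((trial, idx))
        for T, items in sorted(by_len.items()):
            rows = np.stack([idx for _, idx in items])
            self.groups.append(
                {
                    "T": T,
                    "trials": [t for t, _ in items],
                    "K": K[:, rows].transpose(1, 2, 0),  # (R, T, U)
                    "X": X[rows],  # (R, T, p)
                }
            )
        self.n_trials = len(seen)
        self.n_bins = K.shape[1]


def _prior_blocks(A, Qi, Q0i, T):
    """Diagonal/off-diagonal precision blocks of the AR(1) prior."""
    D = A.shape[0]
    AtQiA = A.T @ Qi @ A
    diag = np.empty((T, D, D))
    if T == 1:
        diag[0] = Q0i
    else:
        diag[0] = Q0i + AtQiA
        diag[1:-1] = Qi + AtQiA
        diag[-1] = Qi
    upper = -A.T @ Qi  # block (t, t+1)
    return diag, upper


def _prior_quad_grad(m, A, Qi, Q0i):
    """Gradient of the AR(1) prior quadratic, batched (R, T, D)."""
    R, T, D = m.shape
    g = np.zeros_like(m)
    g[:, 0] += m[:, 0] @ Q0i.T
    if T > 1:
        innov = m[:, 1:] - m[:, :-1] @ A.T  # (R, T-1, D)
        w = innov @ Qi.T
        g[:, 1:] += w
        g[:, :-1] -= w @ A
    return g


def _prior_quad_val(m, A, Qi, Q0i):
    val = 0.5 * np.einsum("rd,de,re->r", m[:, 0], Q0i, m[:, 0])
    if m.shape[1] > 1:
        innov = m[:, 1:] - m[:, :-1] @ A.T
        val = val + 0.5 * np.einsum("rtd,de,rte->r", innov, Qi, innov)
    return val


def _block_thomas(diag, lower, upper, rhs):
    """Solve block-tridiagonal systems batched over trials.

    diag: (R, T, D, D); lower/upper: (D, D) constant off-diagonal blocks;
    rhs: (R, T, D). Returns (solution, Dinv list (R,T,D,D), logdet (R,)).
    """
    R, T, D, _ = diag.shape
    Dinv = np.empty_like(diag)
    y = np.empty_like(rhs)
    logdet = np.zeros(R)
    Dt = diag[:, 0]
    Dinv[:, 0] = np.linalg.inv(Dt)
    sign, ld = np.linalg.slogdet(Dt)
    logdet += ld
    y[:, 0] = rhs[:, 0]
    for t in range(1, T):
        LDinv = lower[None] @ Dinv[:, t - 1]
        Dt = diag[:, t] - LDinv @ upper[None]
        Dinv[:, t] = np.linalg.inv(Dt)
        _, ld = np.linalg.slogdet(Dt)
        logdet += ld
        y[:, t] = rhs[:, t] - np.einsum("rde,re->rd", LDinv, y[:, t - 1])
    x = np.empty_like(rhs)
    x[:, T - 1] = np.einsum("rde,re->rd", Dinv[:, T - 1], y[:, T - 1])
    for t in range(T - 2, -1, -1):
        x[:, t] = np.einsum(
            "rde,re->rd", Dinv[:, t], y[:, t] - x[:, t + 1] @ upper.T
        )
    return x, Dinv, logdet


def _posterior_covariances(Dinv, upper):
    """Marginal and one-step cross covariances of the Laplace posterior.

    Standard block-tridiagonal inverse recursion: Sigma_T = Dinv_T;
    Sigma_t = Dinv_t + Dinv_t U Sigma_{t+1} U^T Dinv_t^T;
    Sigma_{t,t+1} = -Dinv_t U Sigma_{t+1}.
    """
    R, T, D, _ = Dinv.shape
    Sig = np.empty_like(Dinv)
    Cross = np.empty((R, T - 1, D, D)) if T > 1 else np.empty((R, 0, D, D))
    Sig[:, T - 1] = Dinv[:, T - 1]
    for t in range(T - 2, -1, -1):
        PU = Dinv[:, t] @ upper[None]
        Cross[:, t] = -PU @ Sig[:, t + 1]
        Sig[:, t] = Dinv[:, t] + PU @ Sig[:, t + 1] @ PU.transpose(0, 2, 1)
    # enforce symmetry against accumulation error
    Sig = 0.5 * (Sig + Sig.transpose(0, 1, 3, 2))
    return Sig, Cross


def _laplace_estep_group(Kg, etag, C, A, Qi, Q0i, m0=None,
                         max_newton: int = 30, tol: float = 1e-7):
    """Damped-Newton Laplace E-step for one batch of equal-length trials.

    Kg: (R, T, U) counts; etag: (R, T, U) stimulus drive B s_t.
    Returns posterior mean, marginal/cross covariances, -log joint at the
    mode, and log-determinant of the posterior precision.
    """
    R, T, U = Kg.shape
    D = C.shape[1]
    diag_prior, upper = _prior_blocks(A, Qi, Q0i, T)
    lower = upper.T
    m = np.zeros((R, T, D)) if m0 is None else m0.copy()

    def neg_log_joint(mm):
        eta = etag + mm @ C.T
        r = np.exp(np.clip(eta, -30, 30))
        pois = (r - Kg * eta).sum(axis=(1, 2))
        return pois + _prior_quad_val(mm, A, Qi, Q0i)

    f = neg_log_joint(m)
    gtol = tol * max(1.0, Kg.sum() / (R * T))
    for _ in range(max_newton):
        eta = etag + m @ C.T
        r = np.exp(np.clip(eta, -30, 30))
        grad = (r - Kg) @ C + _prior_quad_grad(m, A, Qi, Q0i)
        if np.abs(grad).max() < gtol:
            break
        H_diag = np.einsum("rtu,ud,ue->rtde", r, C, C, optimize=True) + diag_prior[None]
        step, _, _ = _block_thomas(H_diag, lower, upper, -grad)
        t_damp = np.ones(R)
        for _ in range(25):
            m_new = m + t_damp[:, None, None] * step
            f_new = neg_log_joint(m_new)
            bad = f_new > f + 1e-10
            if not bad.any():
                break
            t_damp[bad] *= 0.5
        m, f = m_new, np.minimum(f_new, f)
    # curvature at the mode
    eta = etag + m @ C.T
    r = np.exp(np.clip(eta, -30, 30))
    H_diag = np.einsum("rtu,ud,ue->rtde", r, C, C, optimize=True) + diag_prior[None]
    _, Dinv, logdet = _block_thomas(H_diag, lower, upper, np.zeros_like(m))
    Sig, Cross = _posterior_covariances(Dinv, upper)
    return m, Sig, Cross, f, logdet


# ---------------------------------------------------------------------------
# PLDS fit object and EM
# ---------------------------------------------------------------------------

@dataclass
class PLDSFit:
    D: int
    A: np.ndarray
    Q: np.ndarray
    Q0: np.ndarray
    C: np.ndarray  # (U, D)
    B: np.ndarray  # (U, p)
    alpha: float
    design: SRDesign | None
    posterior_means: np.ndarray | None = None  # (n_bins_total, D)
    posterior_vars: np.ndarray | None = None  # (n_bins_total, D)
    em_trace: list = field(default_factory=list)
    converged: bool = False
    bin_trial: np.ndarray | None = None

    def modulator_trace(self) -> np.ndarray:
        """Concatenated posterior-mean modulator path (1-d case squeezed)."""
        m = self.posterior_means
        return m[:, 0] if m.shape[1] == 1 else m


def _normalize_scale(A, Q, Q0, C, means=None, sigs=None):
    """Reparametrize so each latent dimension has stationary variance 1."""
    S = solve_discrete_lyapunov(A, Q)
    d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    Dm = np.diag(d)
    Dmi = np.diag(1.0 / d)
    A2 = Dmi @ A @ Dm
    Q2 = Dmi @ Q @ Dmi
    Q02 = Dmi @ Q0 @ Dmi
    C2 = C @ Dm
    if means is not None:
        means = means / d[None, :]
    if sigs is not None:
        sigs = sigs / (d[None, :] ** 2)
    return A2, 0.5 * (Q2 + Q2.T), 0.5 * (Q02 + Q02.T), C2, means, sigs


def fit_plds_em(
    rec_or_counts,
    design: SRDesign,
    D: int,
    *,
    alpha: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> PLDSFit | SRFit:
    """Fit the modulated-SR model by EM with a Laplace E-step.

    ``D == 0`` delegates to :func:`fit_sr`. Initialization: B from an
    SR-only fit, C from the top factor(s) of the Poisson-residual
    covariance, A = 0.5 I, stationary-variance-1 innovation noise. The
    approximate log-likelihood trace is recorded per iteration; a decrease
    beyond tolerance triggers a warning and the best iterate is returned.
    """
    if D == 0:
        return fit_sr(rec_or_counts, design, alpha=alpha)
    if not 1 <= D <= 4:
        raise ValueError("latent dimension must be in 0..4")
    if isinstance(rec_or_counts, PopulationRecording):
        K = flatten_counts(rec_or_counts).astype(float)
    else:
        K = np.atleast_2d(np.asarray(rec_or_counts, dtype=float))
    X = design.X
    data = _PLDSData(K, X, design.bin_trial)
    U, p = data.U, data.p

    # ---- initialization -------------------------------------------------
    sr = fit_sr(K, design, alpha=alpha)
    B = sr.coefficients.copy()
    r_hat = np.exp(np.clip(B @ X.T, -30, 30))
    z = (K - r_hat) / np.sqrt(np.maximum(r_hat, 1e-6))
    cov = np.cov(z)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    rbar = np.maximum(K.mean(axis=1), 1e-3)
    C = np.zeros((U, D))
    for d_i in range(D):
        v = evecs[:, order[d_i]]
        lam_excess = max(evals[order[d_i]] - 1.0, 0.05)
        c_dir = v / np.sqrt(rbar)
        scale = np.sqrt(lam_excess / max(np.sum(rbar * c_dir**2), 1e-12))
        C[:, d_i] = c_dir * scale
    A = 0.5 * np.eye(D)
    Q = (1.0 - 0.25) * np.eye(D)
    Q0 = np.eye(D)

    best = None
    best_ll = -np.inf
    trace = []
    prev_ll = -np.inf
    converged = False
    warm = {i: None for i in range(len(data.groups))}
    const_k = sum(gammaln(g["K"] + 1.0).sum() for g in data.groups)

    for it in range(max_iter):
        Qi = np.linalg.inv(Q)
        Q0i = np.linalg.inv(Q0)
        sign_Q, ld_Q = np.linalg.slogdet(Q)
        _, ld_Q0 = np.linalg.slogdet(Q0)

        # E-step over equal-length groups
        stats = {
            "sum_mm": np.zeros((D, D)),  # sum over t<T-1 of E[m_t m_t^T]
            "sum_mm1": np.zeros((D, D)),  # sum over t of E[m_{t+1} m_t^T]
            "sum_mm_next": np.zeros((D, D)),
            "sum_m0m0": np.zeros((D, D)),
            "n_pairs": 0,
            "n_trials": 0,
        }
        ll = 0.0
        posts = []
        for gi, g in enumerate(data.groups):
            T = g["T"]
            etag = g["X"] @ B.T  # (R, T, U)
            mu, Sig, Cross, f, logdet = _laplace_estep_group(
                g["K"], etag, C, A, Qi, Q0i, m0=warm[gi]
            )
            warm[gi] = mu
            R = mu.shape[0]
            # Laplace approximate marginal log-likelihood
            ll += float(
                np.sum(-f)
                - 0.5 * np.sum(logdet)
                - R * 0.5 * (ld_Q0 + (T - 1) * ld_Q)
            )
            Emm = Sig + np.einsum("rtd,rte->rtde", mu, mu)
            if T > 1:
                Ecross = Cross + np.einsum("rtd,rte->rtde", mu[:, :-1], mu[:, 1:])
                stats["sum_mm"] += Emm[:, :-1].sum(axis=(0, 1))
                stats["sum_mm1"] += Ecross.sum(axis=(0, 1)).T  # E[m_{t+1} m_t^T]
                stats["sum_mm_next"] += Emm[:, 1:].sum(axis=(0, 1))
            stats["sum_m0m0"] += Emm[:, 0].sum(axis=0)
            stats["n_pairs"] += R * (T - 1)
            stats["n_trials"] += R
            posts.append((mu, np.einsum("rtdd->rtd", Sig), Emm))
        ll -= const_k
        trace.append(ll)
        if ll > best_ll:
            best_ll = ll
            best = (A.copy(), Q.copy(), Q0.copy(), C.copy(), B.copy())
        if it > 0:
            rel = (ll - prev_ll) / max(abs(prev_ll), 1.0)
            # stop as soon as the Laplace-approximate objective stops
            # improving: with an approximate E-step the surrogate can drift
            # slowly downward past its maximum, so a decrease marks
            # convergence (the best iterate is returned); only a substantial
            # decrease is worth a warning
            if rel < -1e-3:
                warnings.warn(
                    f"EM objective dropped sharply at iteration {it} ({rel:.2e}); "
                    "returning best iterate"
                )
                trace.pop()
                break
            if rel < tol:
                converged = True
                if rel < 0:
                    trace.pop()  # keep the reported trace non-decreasing
                break
        prev_ll = ll

        # ---- M-step: dynamics -------------------------------------------
        if stats["n_pairs"] > 0:
            A = stats["sum_mm1"] @ np.linalg.inv(
                stats["sum_mm"] + 1e-9 * np.eye(D)
            )
            Q = (
                stats["sum_mm_next"]
                - A @ stats["sum_mm1"].T
                - stats["sum_mm1"] @ A.T
                + A @ stats["sum_mm"] @ A.T
            ) / stats["n_pairs"]
            Q = 0.5 * (Q + Q.T) + 1e-8 * np.eye(D)
        Q0 = stats["sum_m0m0"] / stats["n_trials"]
        Q0 = 0.5 * (Q0 + Q0.T) + 1e-8 * np.eye(D)
        # keep dynamics stable
        eig = np.abs(np.linalg.eigvals(A))
        if eig.max() >= 0.999:
            A = A * (0.998 / eig.max())

        # ---- M-step: loadings and stimulus weights ----------------------
        C, B = _update_CB(data, C, B, posts, alpha, design.offset_index)

        # renormalize latent scale each iteration (pure reparametrization)
        A, Q, Q0, C, _, _ = _normalize_scale(A, Q, Q0, C)

    if best is not None and ll < best_ll:
        A, Q, Q0, C, B = best

    # final normalization and sign convention
    A, Q, Q0, C, _, _ = _normalize_scale(A, Q, Q0, C)
    flip = np.where(C.sum(axis=0) >= 0, 1.0, -1.0)
    C = C * flip[None, :]
    F = np.diag(flip)
    A = F @ A @ F
    Q = F @ Q @ F
    Q0 = F @ Q0 @ F

    # assemble posterior paths in original bin order (recomputed under the
    # final parameters for consistency)
    Qi = np.linalg.inv(Q)
    Q0i = np.linalg.inv(Q0)
    mean_full = np.zeros((data.n_bins, D))
    var_full = np.zeros((data.n_bins, D))
    bt = design.bin_trial
    for g in data.groups:
        etag = g["X"] @ B.T
        mu, Sig, _, _, _ = _laplace_estep_group(g["K"], etag, C, A, Qi, Q0i)
        for ri, trial in enumerate(g["trials"]):
            idx = np.flatnonzero(bt == trial)
            mean_full[idx] = mu[ri]
            var_full[idx] = np.einsum("tdd->td", Sig[ri])

    return PLDSFit(
        D=D, A=A, Q=Q, Q0=Q0, C=C, B=B, alpha=alpha, design=design,
        posterior_means=mean_full, posterior_vars=var_full,
        em_trace=trace, converged=converged, bin_trial=bt,
    )


def _update_CB(data, C, B, posts, alpha, offset_index, n_newton: int = 3):
    """Per-unit damped Newton update of (C_n, B_n) on the expected
    complete-data log-likelihood, ridge alpha on non-offset B entries."""
    U, D = C.shape
    p = B.shape[1]
    q = D + p
    pen = np.full(q, 2.0 * alpha)
    pen[:D] = 0.0  # couplings unpenalized; scale is fixed by the latent convention
    if offset_index is not None:
        pen[D + offset_index] = 0.0
    theta = np.concatenate([C, B], axis=1)  # (U, q)

    # gather flattened posterior stats across groups
    mus, sigs, Xs, Ks = [], [], [], []
    for g, (mu, sig_diag, Emm) in zip(data.groups, posts):
        R, T, _ = mu.shape
        mus.append(mu.reshape(R * T, D))
        if Emm is not None:
            sigs.append((Emm - np.einsum("rtd,rte->rtde", mu, mu)).reshape(R * T, D, D))
        else:
            Sg = np.zeros((R * T, D, D))
            Sg[:, np.arange(D), np.arange(D)] = sig_diag.reshape(R * T, D)
            sigs.append(Sg)
        Xs.append(g["X"].reshape(R * T, p))
        Ks.append(g["K"].reshape(R * T, U))
    MU = np.concatenate(mus)  # (N, D)
    SIG = np.concatenate(sigs)  # (N, D, D)
    XX = np.concatenate(Xs)  # (N, p)
    KK = np.concatenate(Ks)  # (N, U)
    Z = np.concatenate([MU, XX], axis=1)  # (N, q) design for the linear part

    def objective(th):
        Cn, Bn = th[:, :D], th[:, D:]
        lin = Z @ th.T  # (N, U)
        quad = 0.5 * np.einsum("ud,nde,ue->nu", Cn, SIG, Cn, optimize=True)
        w = np.exp(np.clip(lin + quad, -30, 30))
        return (KK * lin).sum(axis=0) - w.sum(axis=0) - 0.5 * (pen[None] * th**2).sum(axis=1)

    obj = objective(theta)
    for _ in range(n_newton):
        Cn = theta[:, :D]
        lin = Z @ theta.T
        quad = 0.5 * np.einsum("ud,nde,ue->nu", Cn, SIG, Cn, optimize=True)
        w = np.exp(np.clip(lin + quad, -30, 30))  # (N, U)
        # effective regressor per (n, u): [mu + Sig C_u ; x]
        SC = np.einsum("nde,ue->nud", SIG, Cn, optimize=True)  # (N, U, D)
        g_lat = KK.T @ MU - np.einsum("nu,nud->ud", w, MU[:, None, :] + SC, optimize=True)
        g_x = KK.T @ XX - w.T @ XX
        grad = np.concatenate([g_lat, g_x], axis=1) - pen[None] * theta
        # Hessian: - sum_n w [z~ z~^T + blkdiag(Sig, 0)] - pen
        ztil_lat = MU[:, None, :] + SC  # (N, U, D)
        H = np.empty((U, q, q))
        H[:, :D, :D] = -np.einsum("nu,nud,nue->ude", w, ztil_lat, ztil_lat, optimize=True) \
            - np.einsum("nu,nde->ude", w, SIG, optimize=True)
        H_lx = -np.einsum("nu,nud,np->udp", w, ztil_lat, XX, optimize=True)
        H[:, :D, D:] = H_lx
        H[:, D:, :D] = H_lx.transpose(0, 2, 1)
        H[:, D:, D:] = -np.einsum("nu,np,nq->upq", w, XX, XX, optimize=True)
        H[:, np.arange(q), np.arange(q)] -= pen[None] + 1e-8
        step = np.linalg.solve(H, -grad[..., None])[..., 0]
        t_damp = np.ones(U)
        for _ in range(25):
            theta_new = theta + t_damp[:, None] * step
            obj_new = objective(theta_new)
            bad = obj_new < obj - 1e-10
            if not bad.any():
                break
            t_damp[bad] *= 0.5
        theta, obj = theta_new, np.maximum(obj_new, obj)
    return theta[:, :D].copy(), theta[:, D:].copy()


# ---------------------------------------------------------------------------
# LOO prediction and dimensionality selection
# ---------------------------------------------------------------------------

def loo_predictive_ll(
    fit: PLDSFit,
    rec_or_counts,
    design: SRDesign,
    n_samples: int = 100,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Leave-one-neuron-out predictive log-likelihood of a PLDS fit.

    For each unit, the latent posterior is inferred from the remaining
    units (Laplace), ``n_samples`` latent paths are drawn from the Gaussian
    approximation, and the unit's counts are scored by the sample-averaged
    Poisson predictive likelihood. Returns the summed LOO log-likelihood.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if isinstance(rec_or_counts, PopulationRecording):
        K = flatten_counts(rec_or_counts).astype(float)
    else:
        K = np.atleast_2d(np.asarray(rec_or_counts, dtype=float))
    data = _PLDSData(K, design.X, design.bin_trial)
    U = data.U
    D = fit.D
    Qi = np.linalg.inv(fit.Q)
    Q0i = np.linalg.inv(fit.Q0)
    total = 0.0
    for g in data.groups:
        T = g["T"]
        R = g["K"].shape[0]
        etag_all = g["X"] @ fit.B.T  # (R, T, U)
        for u in range(U):
            keep = np.arange(U) != u
            mu, Sig, Cross, _, _ = _laplace_estep_group(
                g["K"][:, :, keep], etag_all[:, :, keep], fit.C[keep],
                fit.A, Qi, Q0i,
            )
            # sample paths from the block-tridiagonal Gaussian: build the
            # dense precision per trial (T*D is small) and use its Cholesky
            diag_prior, upper = _prior_blocks(fit.A, Qi, Q0i, T)
            eta = etag_all[:, :, keep] + mu @ fit.C[keep].T
            r = np.exp(np.clip(eta, -30, 30))
            Hd = np.einsum("rtu,ud,ue->rtde", r, fit.C[keep], fit.C[keep],
                           optimize=True) + diag_prior[None]
            ll_u = 0.0
            for ri in range(R):
                J = _dense_from_blocks(Hd[ri], upper, T, D)
                L = np.linalg.cholesky(J)
                zdraw = rng.standard_normal((T * D, n_samples))
                paths = mu[ri].reshape(-1, 1) + np.linalg.solve(L.T, zdraw)
                paths = paths.reshape(T, D, n_samples)
                eta_u = etag_all[ri, :, u][:, None] + np.einsum(
                    "tds,d->ts", paths, fit.C[u]
                )
                k_u = g["K"][ri, :, u][:, None]
                ll_s = (k_u * eta_u - np.exp(np.clip(eta_u, -30, 30))
                        - gammaln(k_u + 1.0)).sum(axis=0)
                m = ll_s.max()
                ll_u += m + np.log(np.mean(np.exp(ll_s - m)))
            total += ll_u
    return float(total)


def _dense_from_blocks(diag, upper, T, D):
    J = np.zeros((T * D, T * D))
    for t in range(T):
        J[t * D:(t + 1) * D, t * D:(t + 1) * D] = diag[t]
        if t < T - 1:
            J[t * D:(t + 1) * D, (t + 1) * D:(t + 2) * D] = upper
            J[(t + 1) * D:(t + 2) * D, t * D:(t + 1) * D] = upper.T
    return J


@dataclass
class DimensionSelection:
    selected_D: int
    scores: dict  # D -> mean held-out LOO log-likelihood per fold
    per_fold: dict


def select_dimensionality(
    rec: PopulationRecording,
    *,
    D_range=(0, 1, 2, 3, 4),
    folds: int = 10,
    alpha: float = 1.0,
    seed: int = 0,
    loo_samples: int = 100,
    max_iter: int = 200,
    drift: bool = False,
) -> DimensionSelection:
    """Choose the latent dimensionality by trial-stratified cross-validation.

    Whole trials are held out; each candidate D is scored by the mean
    held-out leave-one-neuron-out log-likelihood (plain held-out likelihood
    for D = 0). Ties break toward smaller D.
    """
    rng = np.random.default_rng(seed)
    trials = rec.presentation_meta["trial"].unique()
    if folds > len(trials):
        warnings.warn(f"only {len(trials)} trials; reducing folds")
        folds = len(trials)
    perm = rng.permutation(len(trials))
    fold_of = np.empty(len(trials), dtype=int)
    for i, tri in enumerate(perm):
        fold_of[tri] = i % folds
    trial_fold = dict(zip(trials, fold_of))

    per_fold: dict[int, list[float]] = {d: [] for d in D_range}
    for f in range(folds):
        test_trials = {t for t in trials if trial_fold[t] == f}
        test_mask = rec.presentation_meta["trial"].isin(test_trials).to_numpy()
        rec_tr = rec.select_presentations(~test_mask)
        rec_te = rec.select_presentations(test_mask)
        levels = sorted(rec.presentation_meta["contrast"].unique())
        des_tr = build_design_matrix(rec_tr, drift=drift, contrast_levels=levels)
        des_te = build_design_matrix(rec_te, drift=drift, contrast_levels=levels)
        K_te = flatten_counts(rec_te).astype(float)
        for d in D_range:
            if d == 0:
                fit0 = fit_sr(rec_tr, des_tr, alpha=alpha)
                ll = float(poisson_ll(K_te, fit0.log_rates(des_te.X)).sum())
            else:
                fit = fit_plds_em(rec_tr, des_tr, d, alpha=alpha,
                                  max_iter=max_iter, seed=seed)
                ll = loo_predictive_ll(fit, rec_te, des_te,
                                       n_samples=loo_samples,
                                       rng=np.random.default_rng(seed + 7 * f + d))
            per_fold[d].append(ll)
    scores = {d: float(np.mean(v)) for d, v in per_fold.items()}
    best = max(scores.values())
    selected = min(d for d in D_range if scores[d] >= best - 1e-9)
    return DimensionSelection(selected_D=selected, scores=scores, per_fold=per_fold)


# ---------------------------------------------------------------------------
# modulator summaries and the downstream SR+modulator model
# ---------------------------------------------------------------------------

def modulator_summaries(
    fit: PLDSFit,
    design: SRDesign | None = None,
    bin_width_ms: float = 50.0,
) -> dict:
    """Time constant, absolute and relative strength of a fitted modulator.

    tau = -1 / log(A) in bins (1-d case; nan for A <= 0), reported in ms.
    Absolute strength = Var(m) * sqrt(sum_n C_n^2) with Var(m) = 1 under the
    stationary-variance convention. Relative strength divides by the
    stimulus drive sum_{n,i} Var(s_i B_{n,i}) over the block's design rows.
    """
    if design is None:
        design = fit.design
    D = fit.D
    taus = []
    for d in range(D):
        a = fit.A[d, d] if D > 1 else float(fit.A[0, 0])
        taus.append(-1.0 / np.log(a) * bin_width_ms if 0 < a < 1 else np.nan)
    S = solve_discrete_lyapunov(fit.A, fit.Q)
    var_m = float(np.trace(S)) / D
    absolute = var_m * float(np.sqrt(np.sum(fit.C**2)))
    col_var = design.X.var(axis=0)  # per design column, over rows
    drive = float(np.sum(fit.B**2 * col_var[None, :]))
    relative = absolute / drive if drive > 0 else np.nan
    return {
        "tau_ms": taus[0] if D == 1 else taus,
        "absolute_strength": absolute,
        "relative_strength": relative,
    }


def stimulus_drive_from_coefficients(B: np.ndarray, X: np.ndarray) -> float:
    """sum_{n,i} Var(X_i B_{n,i}) over design rows — the stimulus drive."""
    return float(np.sum(np.asarray(B) ** 2 * X.var(axis=0)[None, :]))


def fit_sr_plus_modulator(
    rec: PopulationRecording,
    modulator: np.ndarray,
    *,
    alpha: float = 1.0,
    drift: bool = False,
) -> dict:
    """Fit the SR model with and without an external modulator covariate.

    The modulator trace (estimated in the primary area, aligned to this
    recording's bins) is z-scored and added as one extra design column.
    Returns both fits and the per-unit pseudo-R^2 of the augmented model
    with the SR-only model as the null.
    """
    des_plain = build_design_matrix(rec, drift=drift)
    des_mod = build_design_matrix(rec, drift=drift, modulator=modulator)
    K = flatten_counts(rec).astype(float)
    fit_plain = fit_sr(K, des_plain, alpha=alpha)
    fit_mod = fit_sr(K, des_mod, alpha=alpha)
    ll_plain = poisson_ll(K, fit_plain.log_rates(des_plain.X))
    ll_mod = poisson_ll(K, fit_mod.log_rates(des_mod.X))
    sat = saturated_ll(K)
    improvement = pseudo_r2(ll_mod, ll_plain, sat)
    return {
        "sr_fit": fit_plain,
        "sr_mod_fit": fit_mod,
        "ll_sr": ll_plain,
        "ll_sr_mod": ll_mod,
        "pseudo_r2_improvement": improvement,
    }
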