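"""Generators for modulated-Poisson population data.

Three families of synthetic data feed the rest of the package:

* :func:`simulate_iid_population` — the theory setting: static stimulus
  rates, a one-dimensional i.i.d. Gaussian modulator shared across the
  population at the stimulus time scale, spike counts Poisson with
  multiplicatively modulated rates and an optional mean correction,

      k_{n,t} ~ Poisson( lambda_n(s) * exp(c_n m_t - sigma_m^2 c_n^2 / 2) ).

* :func:`simulate_ar1_block` — an experiment-like block: trials made of
  repeated reference presentations ending in a target, two contrast levels,
  an AR(1) latent modulator restarting each trial from its stationary
  distribution, spike counts Poisson(exp(C m_t + B s_t)), and hit/miss
  outcomes drawn from a logistic function of the pooled informative-unit
  target response.

* :func:`simulate_downstream_units` — an MT-like population inheriting the
  primary-area modulator (optionally with a feedforward bin lag) through
  its own couplings.

Population composition follows the theory simulations: a small informative
subpopulation whose two stimulus rates differ, a larger uninformative
active group with equal rates, and a sea of inactive low-rate units. The
modulator coupling of every unit is proportional to the log-rate difference
c_n = |log lambda_n(1) - log lambda_n(0)|, so only informative units are
labeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population_data import PopulationRecording


class SimConfigError(ValueError):
    pass


@dataclass
class PopulationSimConfig:
    """Generative specification of a modulated-Poisson population.

    Rates are in spikes per 50 ms bin unless stated otherwise. Default
    composition and coupling rule follow the theory simulations; the rate
    ranges (inactive ~1 Hz, active 10–40 Hz with stimulus-dependent
    differences for informative units) are package defaults.
    """

    n_informative: int = 12
    n_uninformative: int = 38
    n_inactive: int = 0
    #: explicit per-unit rates (spikes/bin); generated from the ranges below when None
    lam0: np.ndarray | None = None
    lam1: np.ndarray | None = None
    active_rate_range_hz: tuple[float, float] = (10.0, 40.0)
    inactive_rate_hz: float = 1.0
    #: log-rate ratio between preferred and null stimulus for informative units
    informative_log_ratio_range: tuple[float, float] = (0.6, 1.2)
    #: SD of the (small) log-rate difference of uninformative units; they
    #: respond similarly — not identically — to the two stimuli
    uninformative_log_ratio_sd: float = 0.05
    sigma_m: float = 0.5
    coupling_scale: float = 1.0
    coupling_noise_sd: float = 0.0
    modulator_law: str = "iid-gaussian"  # or "ar1"
    ar_coef: float = 0.5
    bins_per_presentation: int = 1
    mean_correction: bool = True
    bin_width_ms: float = 50.0
    seed: int = 0

    @property
    def n_units(self) -> int:
        return self.n_informative + self.n_uninformative + self.n_inactive

    def validate(self) -> None:
        if self.sigma_m < 0:
            raise SimConfigError("sigma_m must be >= 0")
        if self.modulator_law not in ("iid-gaussian", "ar1"):
            raise SimConfigError(f"unknown modulator law {self.modulator_law!r}")
        if self.modulator_law == "ar1" and abs(self.ar_coef) >= 1:
            raise SimConfigError("AR coefficient must satisfy |A| < 1")

    def rates(self, rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-unit rate pairs (lambda(0), lambda(1)) in spikes per bin."""
        self.validate()
        if self.lam0 is not None and self.lam1 is not None:
            lam0 = np.asarray(self.lam0, dtype=float)
            lam1 = np.asarray(self.lam1, dtype=float)
            if (lam0 <= 0).any() or (lam1 <= 0).any():
                raise SimConfigError("rates must be positive")
            return lam0, lam1
        if rng is None:
            rng = np.random.default_rng(self.seed)
        per_bin = self.bin_width_ms / 1000.0
        lo, hi = self.active_rate_range_hz
        n_act = self.n_informative + self.n_uninformative
        base = rng.uniform(lo, hi, size=n_act) * per_bin
        lam0 = np.concatenate([base, np.full(self.n_inactive, self.inactive_rate_hz * per_bin)])
        lam1 = lam0.copy()
        # informative units: stimulus-dependent rates, half preferring each stimulus
        ratios = rng.uniform(*self.informative_log_ratio_range, size=self.n_informative)
        signs = np.where(np.arange(self.n_informative) % 2 == 0, 1.0, -1.0)
        lam1[: self.n_informative] = lam0[: self.n_informative] * np.exp(signs * ratios)
        # uninformative (but active) units respond similarly, not identically
        if self.uninformative_log_ratio_sd > 0 and self.n_uninformative:
            sl = slice(self.n_informative, self.n_informative + self.n_uninformative)
            small = rng.normal(0.0, self.uninformative_log_ratio_sd, size=self.n_uninformative)
            lam1[sl] = lam0[sl] * np.exp(small)
        return lam0, lam1

    def couplings(self, lam0: np.ndarray, lam1: np.ndarray,
                  rng: np.random.Generator | None = None) -> np.ndarray:
        """Coupling rule c_n = scale * |log lambda(1) - log lambda(0)| (+ optional noise)."""
        c = self.coupling_scale * np.abs(np.log(lam1) - np.log(lam0))
        if self.coupling_noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng(self.seed + 1)
            c = corrupt_couplings(c, self.coupling_noise_sd, rng)
        return c


def experiment_population(
    n_units: int = 50,
    *,
    rate_range_hz: tuple[float, float] = (5.0, 40.0),
    log_ratio_sd: float = 0.4,
    sigma_m: float = 0.6,
    ar_coef: float = 0.5,
    bins_per_presentation: int = 4,
    seed: int = 0,
) -> PopulationSimConfig:
    """Population config emulating a recorded block.

    Unlike the theory setting's discrete informative/uninformative split,
    recorded units show a broad, continuous distribution of task
    informativeness; here the per-unit log-rate difference between the two
    stimuli is drawn Normal(0, ``log_ratio_sd``), giving a continuum of
    |d'| values (most units weakly informative, a tail strongly so). The
    coupling rule c_n = |log ratio| then yields graded, targeted couplings.
    """
    rng = np.random.default_rng(seed)
    per_bin = 50.0 / 1000.0
    lam0 = rng.uniform(*rate_range_hz, size=n_units) * per_bin
    delta = rng.normal(0.0, log_ratio_sd, size=n_units)
    lam1 = lam0 * np.exp(delta)
    return PopulationSimConfig(
        n_informative=n_units, n_uninformative=0, n_inactive=0,
        lam0=lam0, lam1=lam1, sigma_m=sigma_m,
        modulator_law="ar1", ar_coef=ar_coef,
        bins_per_presentation=bins_per_presentation, seed=seed,
    )


@dataclass
class BlockSimConfig:
    """Trial/block structure for the experiment-like generator.

    Repeats before the target are geometric(p) truncated to
    [min_repeats, max_repeats]; hit/miss outcomes follow a logistic model of
    the standardized pooled informative-unit target response, giving a base
    hit rate of sigmoid(hit_bias) ~ 0.73 at the mean response.
    """

    n_trials: int = 60
    repeat_p: float = 0.25
    min_repeats: int = 2
    max_repeats: int = 12
    contrast_levels: tuple[str, ...] = ("high", "low")
    contrast_scale: dict = field(default_factory=lambda: {"high": 1.0, "low": 0.5})
    off_bins: int = 4
    off_rate_fraction: float = 0.25  # baseline rate relative to lambda(0)
    hit_gain: float = 1.0
    hit_bias: float = 1.0
    seed: int = 0


# ---------------------------------------------------------------------------
# modulator strength bookkeeping
# ---------------------------------------------------------------------------

def stimulus_drive(lam0: np.ndarray, lam1: np.ndarray) -> float:
    """Summed stimulus-induced log-rate variance for a balanced binary task.

    With design columns (offset, indicator of s=1) and coefficient
    Delta_n = log lambda_n(1) - log lambda_n(0) active on half the
    presentations, the per-unit variance of the stimulus drive is
    Delta_n^2 / 4.
    """
    delta = np.log(lam1) - np.log(lam0)
    return float(np.sum(delta**2) / 4.0)


def relative_strength_of(sigma_m: float, couplings: np.ndarray,
                         lam0: np.ndarray, lam1: np.ndarray) -> float:
    """Relative modulator strength: modulator- over stimulus-induced variance."""
    drive = stimulus_drive(lam0, lam1)
    if drive == 0:
        return np.inf if sigma_m > 0 else 0.0
    return sigma_m**2 * np.sqrt(np.sum(couplings**2)) / drive


def sigma_m_for_relative_strength(rel: float, couplings: np.ndarray,
                                  lam0: np.ndarray, lam1: np.ndarray) -> float:
    """Invert :func:`relative_strength_of` for the modulator SD."""
    norm = np.sqrt(np.sum(couplings**2))
    if norm == 0:
        if rel > 0:
            raise SimConfigError("cannot reach nonzero strength with zero couplings")
        return 0.0
    return float(np.sqrt(rel * stimulus_drive(lam0, lam1) / norm))


# ---------------------------------------------------------------------------
# i.i.d.-modulator population (theory setting)
# ---------------------------------------------------------------------------

def modulated_rates(lam: np.ndarray, c: np.ndarray, m: np.ndarray,
                    sigma_m: float, mean_correction: bool = True) -> np.ndarray:
    """Rates lambda * exp(c m [- sigma^2 c^2 / 2]) for unit-vector c and modulator m."""
    gain = np.exp(np.multiply.outer(c, m))
    if mean_correction:
        gain = gain * np.exp(-0.5 * sigma_m**2 * c[:, None] ** 2)
    return lam[:, None] * gain


def simulate_iid_population(
    cfg: PopulationSimConfig,
    presentations_per_stimulus: int,
    rng: np.random.Generator | None = None,
) -> tuple[PopulationRecording, np.ndarray]:
    """Simulate a population with an i.i.d. Gaussian modulator.

    One modulator draw per presentation (the modulator fluctuates at the
    stimulus time scale); stimulus identities are balanced and interleaved.
    Returns the recording and the realized modulator trace (one value per
    presentation).
    """
    if cfg.modulator_law != "iid-gaussian":
        raise SimConfigError("simulate_iid_population requires the iid-gaussian law")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lam0, lam1 = cfg.rates(rng)
    c = cfg.couplings(lam0, lam1, rng)

    n_p = 2 * presentations_per_stimulus
    stimulus = np.tile([0, 1], presentations_per_stimulus)
    m = rng.normal(0.0, cfg.sigma_m, size=n_p)

    lam = np.where(stimulus[None, :] == 1, lam1[:, None], lam0[:, None])
    gain = np.exp(c[:, None] * m[None, :])
    if cfg.mean_correction:
        gain = gain * np.exp(-0.5 * cfg.sigma_m**2 * c[:, None] ** 2)
    rate = lam * gain
    T = cfg.bins_per_presentation
    counts = rng.poisson(np.repeat(rate[:, :, None], T, axis=2))

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
        counts=counts,
        presentation_meta=meta,
        bin_width_ms=cfg.bin_width_ms,
        n_stim_bins=T,
    )
    return rec, m


def corrupt_couplings(c: np.ndarray, noise_sd: float,
                      rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Add Gaussian noise to coupling magnitudes, clipping at zero.

    Couplings enter the model as gain exponents whose magnitude is the task
    label, so negative corrupted values are clipped to 0.
    """
    if noise_sd < 0:
        raise SimConfigError("noise_sd must be >= 0")
    c = np.asarray(c, dtype=float)
    if noise_sd == 0:
        return c.copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return np.clip(c + rng.normal(0.0, noise_sd, size=c.shape), 0.0, None)


def simulate_multiunits(rec: PopulationRecording,
                        rng: np.random.Generator | int | None = None) -> PopulationRecording:
    """Sum disjoint random pairs of units to emulate multiunit recordings."""
    if rec.n_units < 2:
        raise ValueError("need at least 2 units to form multiunits")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    perm = rng.permutation(rec.n_units)
    if len(perm) % 2 == 1:
        perm = perm[:-1]  # drop one unit at random (permutation is random)
    pairs = perm.reshape(-1, 2)
    counts = rec.counts[pairs[:, 0]] + rec.counts[pairs[:, 1]]
    return PopulationRecording(
        counts=counts,
        presentation_meta=rec.presentation_meta.copy(),
        bin_width_ms=rec.bin_width_ms,
        n_stim_bins=rec.n_stim_bins,
        unit_ids=np.arange(len(pairs)),
        area=rec.area,
    )


# ---------------------------------------------------------------------------
# AR(1)-modulator experiment-like block
# ---------------------------------------------------------------------------

def _ar1_trace(n_bins: int, a: float, sigma_st: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) path with stationary SD sigma_st, started from stationarity."""
    q_sd = sigma_st * np.sqrt(max(1.0 - a**2, 0.0))
    m = np.empty(n_bins)
    m[0] = rng.normal(0.0, sigma_st)
    eps = rng.normal(0.0, q_sd, size=n_bins - 1) if n_bins > 1 else np.empty(0)
    for t in range(1, n_bins):
        m[t] = a * m[t - 1] + eps[t - 1]
    return m


def simulate_ar1_block(
    pop_cfg: PopulationSimConfig,
    block_cfg: BlockSimConfig,
    rng: np.random.Generator | None = None,
    drift_directions: bool = False,
) -> tuple[PopulationRecording, np.ndarray]:
    """Simulate one experiment-like block with an AR(1) latent modulator.

    Each trial is a run of reference presentations (stimulus 0) ending in a
    single target (stimulus 1); each presentation contributes
    ``pop_cfg.bins_per_presentation`` stimulus-on bins (rate
    lambda_n(s) x contrast scale) followed by ``block_cfg.off_bins``
    inter-stimulus bins at the baseline rate. The latent restarts each trial
    from its stationary distribution N(0, sigma_m^2) and multiplies all
    rates through exp(c_n m_t) (mean-corrected with the stationary variance
    when configured). Returns the recording and the concatenated per-bin
    modulator trace.
    """
    if pop_cfg.modulator_law != "ar1":
        raise SimConfigError("simulate_ar1_block requires the ar1 law")
    pop_cfg.validate()
    if rng is None:
        rng = np.random.default_rng(pop_cfg.seed)
    brng = np.random.default_rng(block_cfg.seed)
    lam0, lam1 = pop_cfg.rates(rng)
    c = pop_cfg.couplings(lam0, lam1, rng)

    n_on = pop_cfg.bins_per_presentation
    n_off = block_cfg.off_bins
    bins_per_pres = n_on + n_off
    off_rate = block_cfg.off_rate_fraction * lam0

    # trial layout
    n_repeats = np.clip(
        brng.geometric(block_cfg.repeat_p, size=block_cfg.n_trials),
        block_cfg.min_repeats,
        block_cfg.max_repeats,
    )
    rows = []
    for trial, reps in enumerate(n_repeats):
        contrasts = brng.choice(block_cfg.contrast_levels, size=reps + 1)
        drift = brng.choice(["cw", "ccw"]) if drift_directions else None
        for r in range(reps + 1):
            row = {
                "block": 0,
                "trial": trial,
                "repeat_index": r,
                "contrast": contrasts[r],
                "stimulus": 1 if r == reps else 0,
            }
            if drift_directions:
                row["drift_direction"] = drift
            rows.append(row)
    meta = pd.DataFrame(rows)
    n_p = len(meta)

    # modulator: independent AR(1) path per trial, concatenated over bins
    m_parts = []
    for trial in range(block_cfg.n_trials):
        n_bins_trial = int((meta["trial"] == trial).sum()) * bins_per_pres
        m_parts.append(_ar1_trace(n_bins_trial, pop_cfg.ar_coef, pop_cfg.sigma_m, rng))
    m = np.concatenate(m_parts)

    # per-bin log rates
    scale = np.array([block_cfg.contrast_scale[cl] for cl in meta["contrast"]])
    lam_s = np.where(meta["stimulus"].to_numpy() == 1, lam1[:, None], lam0[:, None])
    log_on = np.log(lam_s * scale[None, :])  # (U, P)
    log_off = np.log(off_rate)[:, None] * np.ones((1, n_p))
    log_rate = np.concatenate(
        [np.repeat(log_on[:, :, None], n_on, axis=2),
         np.repeat(log_off[:, :, None], n_off, axis=2)],
        axis=2,
    )  # (U, P, bins_per_pres)
    m_bins = m.reshape(n_p, bins_per_pres)
    log_rate = log_rate + c[:, None, None] * m_bins[None, :, :]
    if pop_cfg.mean_correction:
        log_rate = log_rate - 0.5 * pop_cfg.sigma_m**2 * c[:, None, None] ** 2
    counts = rng.poisson(np.exp(log_rate))

    # hit/miss outcomes from the pooled informative-unit target response
    informative = np.arange(pop_cfg.n_informative)
    target_rows = meta.index[meta["stimulus"] == 1].to_numpy()
    pooled = counts[informative][:, target_rows, :n_on].sum(axis=(0, 2))
    lam1_scale = np.array([block_cfg.contrast_scale[meta.loc[p, "contrast"]] for p in target_rows])
    expected = np.sum(lam1[informative]) * n_on * lam1_scale
    z = (pooled - expected) / np.sqrt(np.maximum(expected, 1e-12))
    p_hit = 1.0 / (1.0 + np.exp(-(block_cfg.hit_gain * z + block_cfg.hit_bias)))
    hits = brng.random(len(target_rows)) < p_hit
    outcome_by_trial = {
        int(meta.loc[p, "trial"]): ("hit" if h else "miss")
        for p, h in zip(target_rows, hits)
    }
    meta["outcome"] = meta["trial"].map(outcome_by_trial)

    rec = PopulationRecording(
        counts=counts,
        presentation_meta=meta,
        bin_width_ms=pop_cfg.bin_width_ms,
        n_stim_bins=n_on,
    )
    return rec, m


def simulate_downstream_units(
    modulator: np.ndarray,
    primary_rec: PopulationRecording,
    lam0: np.ndarray,
    lam1: np.ndarray,
    couplings: np.ndarray,
    *,
    off_rate_fraction: float = 0.25,
    contrast_scale: dict | None = None,
    drift_gain: np.ndarray | None = None,
    lag_bins: int = 0,
    sigma_m: float | None = None,
    mean_correction: bool = False,
    rng: np.random.Generator | int | None = None,
) -> PopulationRecording:
    """Simulate a downstream (MT-like) population inheriting the modulator.

    Each downstream unit has its own stimulus tuning (``lam0``/``lam1`` in
    spikes per bin, optionally scaled by ``drift_gain`` for presentations
    whose ``drift_direction`` is ``"cw"``) and is multiplicatively gated by
    the primary-area modulator through ``couplings``, with an optional
    feedforward delay of ``lag_bins`` bins (applied within trial).
    """
    if contrast_scale is None:
        contrast_scale = {"high": 1.0, "low": 0.5}
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    meta = primary_rec.presentation_meta
    n_p = primary_rec.n_presentations
    bins_per_pres = primary_rec.n_bins
    n_on = primary_rec.n_stim_bins
    total_bins = n_p * bins_per_pres
    if len(modulator) != total_bins:
        raise ValueError("modulator trace does not align to the presentation/bin grid")
    if lag_bins < 0:
        raise ValueError("lag must be >= 0")

    # lag the modulator within each trial
    m_lag = np.empty_like(modulator)
    pres_trial = meta["trial"].to_numpy()
    bin_trial = np.repeat(pres_trial, bins_per_pres)
    for trial in np.unique(bin_trial):
        idx = np.flatnonzero(bin_trial == trial)
        if lag_bins >= len(idx):
            raise ValueError("lag exceeds trial length")
        seg = modulator[idx]
        m_lag[idx] = np.concatenate([np.full(lag_bins, seg[0]), seg[: len(seg) - lag_bins]])

    lam0 = np.asarray(lam0, dtype=float)
    lam1 = np.asarray(lam1, dtype=float)
    couplings = np.asarray(couplings, dtype=float)
    scale = np.array([contrast_scale[cl] for cl in meta["contrast"]])
    lam_s = np.where(meta["stimulus"].to_numpy() == 1, lam1[:, None], lam0[:, None]) * scale[None, :]
    if drift_gain is not None and "drift_direction" in meta.columns:
        cw = (meta["drift_direction"] == "cw").to_numpy()
        lam_s = lam_s * np.where(cw[None, :], np.asarray(drift_gain)[:, None], 1.0)
    log_on = np.log(lam_s)
    log_off = np.log(off_rate_fraction * lam0)[:, None] * np.ones((1, n_p))
    n_off = bins_per_pres - n_on
    log_rate = np.concatenate(
        [np.repeat(log_on[:, :, None], n_on, axis=2),
         np.repeat(log_off[:, :, None], n_off, axis=2)],
        axis=2,
    )
    m_bins = m_lag.reshape(n_p, bins_per_pres)
    log_rate = log_rate + couplings[:, None, None] * m_bins[None, :, :]
    if mean_correction:
        if sigma_m is None:
            sigma_m = float(np.std(modulator))
        log_rate = log_rate - 0.5 * sigma_m**2 * couplings[:, None, None] ** 2
    counts = rng.poisson(np.exp(log_rate))
    return PopulationRecording(
        counts=counts,
        presentation_meta=meta.copy(),
        bin_width_ms=primary_rec.bin_width_ms,
        n_stim_bins=n_on,
        area="downstream",
    )
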