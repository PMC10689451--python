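# Methods

`modlabel` implements a theory of task-adaptive sensory readout in which a
shared, rapidly fluctuating multiplicative gain signal (the *modulator*)
labels the task-informative units of a neural population, and a downstream
readout uses that label to set its decoding weights. This note documents
the models, the estimators, the synthetic-data conditions, and the
numerical choices, in the package's own terms.

## Encoding model

In the theory setting, spike counts of unit *n* at time step *t* follow a
modulated Poisson model

    k_{n,t}(s) ~ Poisson( λ_n(s) · exp(c_n m_t − σ_m² c_n² / 2) ),

where λ_n(s) is the stimulus-dependent rate (s ∈ {0, 1}), m_t ~ N(0, σ_m²)
is drawn independently per stimulus presentation (the modulator fluctuates
at the stimulus time scale), and c_n ≥ 0 is the unit's modulator coupling.
The subtracted term is the **mean correction**: since
E[exp(c m)] = exp(σ² c² / 2), dividing the rate by that factor makes
modulation change variability without changing mean rate. The coupling rule
is c_n = |log λ_n(1) − log λ_n(0)|, i.e. proportional to the unit's
log-rate discriminability — the "label".

**Relative modulator strength** is the ratio of modulator-induced to
stimulus-induced variance. With design columns (offset, stimulus
indicator) the stimulus drive is Σ_n Δ_n²/4 with Δ_n the log-rate
difference, and the strength is σ_m² √(Σ c_n²) divided by that drive; the
generator exposes the inverse map so populations can be simulated at a
prescribed relative strength.

## Decoders

All decoders are linear-threshold rules on window-summed counts
(Σ_n a_n k_n ≥ q; ties decide s = 1, fixed for determinism).

* **Ideal observer**: a_n = log λ_n(1) − log λ_n(0); the modulator-dependent
  threshold is q(m) = Σ_n exp(c_n m − σ_m² c_n²/2)[λ_n(1) − λ_n(0)] (the
  correction factor appears when the generative model uses it). This is the
  exact log-odds decision; the test suite verifies exact agreement with
  brute-force Bayes comparison over all count vectors (U ≤ 3, counts ≤ 10)
  across σ_m and m grids. The *learned* variant replaces the
  modulator-dependent threshold with a constant fitted on training data
  (exhaustive scan over score midpoints; ties resolve to the midpoint of
  the optimal interval). When the threshold is modulator-dependent and the
  window has several bins, per-bin decisions are combined by majority vote
  (the combination rule is a package choice; ties vote s = 1).
* **Modulator-guided (MG)**: |a_n| = (1/T) Σ_t m_t k_{n,t} over 50 ms bins,
  clipped at 0; for a mean-corrected unit E|a_n| = λ c σ_m², so the weight
  magnitude estimates the label. Signs come from trial feedback (mean
  response to s=1 vs s=0 on labeled training data only); threshold constant,
  fitted on training data.
* **Sign-only (SO)**: a_n = sign(λ_n(1) − λ_n(0)) ∈ {−1, +1}; zero
  differences get +1.
* **Baselines**: L2-penalized logistic regression at strength 1, and a
  linear-kernel SVM at default regularization, both on per-presentation
  summed counts.

The strength sweep reproduces the characteristic trade-off: ideal-observer
accuracy decreases monotonically with relative strength (the targeted noise
is strictly detrimental to encoding), while MG accuracy is an inverted U —
zero at no label, limited by encoding corruption at strong modulation —
with SO ≤ MG ≤ optimal at the MG peak.

## Stimulus-response (SR) model and modulated-SR (PLDS) model

The SR model is per-unit Poisson regression on a one-hot design: per
contrast level one indicator for each 50 ms window of the 200 ms stimulus-on
period (8 stimulus dimensions for a two-contrast model), an after-stimulus
indicator for inter-stimulus bins, an always-on offset, optionally a
drift-direction indicator (downstream area) and an external z-scored
modulator covariate. Fits maximize the penalized Poisson likelihood with
ridge α‖β‖² on non-offset coefficients (α = 1 by default; the offset is
unpenalized) by damped Newton iterations; the problem is strictly convex,
so fits are deterministic. Only reference (stimulus 0) presentations enter
the SR/PLDS fits; target responses are used for informativeness and
decoding.

The modulated-SR model adds a D-dimensional AR(1) latent through the
exponential link:

    k_t ~ Poisson(exp(C m_t + B s_t)),  m_{t+1} = A m_t + ε, ε ~ N(0, Q),

with trials independent (the latent restarts from N(0, Q₀) each trial).
Fitting is EM with a per-trial Laplace E-step:

* **E-step** — damped Newton maximization of the joint latent posterior;
  the Hessian is block-tridiagonal (D×D blocks), solved by a block Thomas
  algorithm batched over equal-length trials; marginal and one-step cross
  covariances come from the standard block-tridiagonal inverse recursion.
* **M-step** — closed-form updates for A, Q, Q₀ from the posterior latent
  moments; per-unit damped Newton updates for (C_n, B_n) on the expected
  complete-data likelihood, using E[exp(cᵀm)] = exp(cᵀμ + ½cᵀΣc); the same
  ridge α applies to B (couplings are unpenalized — their scale is pinned
  by the latent convention).
* **Identifiability conventions** — after every iteration the latent is
  rescaled to stationary variance 1 per dimension (C carries the
  magnitude; only the product of coupling scale and latent scale is
  identifiable) and at the end the sign is fixed by ΣC ≥ 0 per dimension
  (needed to compare modulators across areas).
* **Initialization** — B from an SR-only fit; C from the top eigenvector of
  the Pearson-residual covariance (rescaled by unit rates); A = 0.5·I,
  stationary-variance-1 innovation noise.
* **Convergence** — the Laplace-approximate marginal likelihood is a
  surrogate, not the exact objective; after its maximum the EM path can
  drift slowly downward. The fit stops at the first non-improving
  iteration (relative change < 1e-6, or any decrease) and returns the best
  iterate, so the reported trace is non-decreasing. A sharp decrease
  (relative 1e-3) raises a warning. Singular covariances are jittered
  (1e-8 on the diagonal); dynamics with spectral radius ≥ 1 are shrunk
  back to 0.998.

**Model comparison** is trial-stratified K-fold cross-validation (10 folds
by default) scored by held-out leave-one-neuron-out (LOO) prediction for
latent models: the posterior is inferred from the remaining units, 100
latent paths are sampled from the Gaussian approximation (dense Cholesky of
the per-trial precision; trials are short), and the held-out unit's counts
are scored by the sample-averaged predictive likelihood. D = 0 (the SR
model) is scored by its plain held-out likelihood. Ties select the smaller
D. Fit quality is also reported as pseudo-R² — the fraction of the
null-to-saturated log-likelihood gain — with the mean-rate model as the SR
null and the SR model as the PLDS null; the saturated model is the
per-observation Poisson with rate equal to the observed count.

**Modulator summaries**: time constant τ = −1/log(A) bins (reported in ms;
undefined for A ≤ 0 — non-decaying or oscillatory dynamics are not
modeled), absolute strength Var(m)·√(ΣC²) (= √(ΣC²) under the
stationary-variance-1 convention), relative strength divided by the
stimulus drive Σ_{n,i} Var(X_i B_{n,i}) over the block's design rows.

## Task statistics

* **d′** = |μ₀ − μ₁| / √(½(σ₀² + σ₁²)) on window-summed responses.
  Significance uses a permutation null from random splits of the
  stimulus-0 responses into two disjoint subsets. The subsets match the
  true group sizes as closely as the n₀ samples allow ((n₀−n₁, n₁)): a
  proportional split makes the null d′ over-dispersed relative to the
  observed statistic and the test conservative (measured type-I 0.002 at
  nominal 0.01); with matched sizes the test is calibrated (0.006, inside
  the binomial band). 1000 permutations by default, add-one smoothed
  p-values, α = 0.01.
* **Choice d′**: same formula over hit vs miss trials (target-presentation
  window sums — the choice of window is a package default).
* **Partial correlation**: covariates (e.g. mean rate, or rate +
  informativeness) are linearly regressed out of the target; residuals are
  Spearman-correlated with the predictor. With no covariates this is
  ordinary Spearman. All rank correlations in the package are Spearman.
* **Fano factors** are computed within matched stimulus conditions
  (contrast × stimulus by default) and averaged, so stimulus-driven rate
  differences do not inflate them.
* **Cross-correlograms** between modulator traces are Pearson correlations
  at integer lags over valid within-trial overlaps only (no correlation
  across trial boundaries); positive lag means the first trace leads.

## Synthetic data: what it emulates, and what it does not

Two population regimes:

* **Theory population** (decoding experiments): N units split into
  informative (stimulus-dependent rates, log-ratio 0.6–1.2), uninformative
  active (near-equal rates; a small log-ratio spread of SD 0.05 reflects
  that real units respond similarly, not identically), and inactive
  (1 Hz, exactly equal rates, hence exactly zero coupling). Rates 10–40
  spikes/s for active units. These values are package defaults, chosen as
  typical cortical ranges.
* **Experiment-like population** (model-fitting experiments): a continuum
  of informativeness — per-unit log-rate differences ~ N(0, 0.4) — because
  recorded populations show a broad |d′| distribution rather than a
  discrete split. This matters for coupling-recovery metrics: with mostly
  exactly-zero couplings, rank correlations are capped by ties (~0.70 for
  a 10/40 split) regardless of fit quality.

Block structure: trials of geometric(0.25) repeats truncated to [2, 12]
(the acceptance recovery setting uses p = 0.125 for ~60-bin trials), each
presentation 4 stimulus-on bins (200 ms) + 4 off bins at 25% of the
reference rate, two contrast levels (low = 0.5× rate), an AR(1) modulator
per bin restarting each trial from its stationary distribution, and
hit/miss outcomes drawn from a logistic function of the standardized pooled
informative-unit target response (base hit rate ≈ 0.73, near observed
behavior). Downstream (MT-like) units inherit the primary modulator trace
through their own couplings with an optional integer-bin feedforward lag,
plus optional drift-direction tuning.

The generators do **not** emulate: eye movements, adaptation within
repeats, oscillatory or on–off latent dynamics, residual pairwise
correlations beyond the single shared modulator, or multi-dimensional
modulators by default. Passing tests therefore demonstrate correctness of
the estimators and the internal consistency of the theory under its own
assumptions — not robustness to every structure present in real
recordings.

## Hierarchical network

A four-stage feedforward model: 288 fixed Gabor filters (8 orientations ×
6×6 RF grid, unit-norm, zero-mean) over 28×28 images with exponential
activation h⁰ = exp(w·s + m c); one locally connected processing layer
(3×3-grid patches, stride 1, 50 channels → 800 units, untied weights,
rectifier); multiplicative gains g ≥ 0 on those units; a fully connected
10-way decision layer. The full-scale configuration (56×56 input, 2560
encoding units, two processing layers, 7840-unit top layer) is
constructable and reproduces the decision-layer parameter count of 78,410
exactly; training at that scale is not attempted here.

Training stages: (1) pretraining of processing + decision weights on
10-class glyph classification (procedurally generated stroke glyphs at
random positions — a stand-in requiring no dataset download; a real digit
set can be substituted through the same `TaskDataset` interface) with
pixel noise SD 0.2 and L1 penalty; the penalty strength is chosen by
validation accuracy, giving 1e-4 at this scale. (2) A fresh 10-way
orientation readout trained on single positioned gratings, all else
frozen. (3) Task fine-tuning on binary orientation discrimination at a
fixed position with 5 distractor gratings: only the encoding couplings c
are trained by gradient descent (slow scale, m = 1, learning rate 0.01 —
larger rates destabilize because the gradient scales with exp(c)), while
the gains are set on the fast scale by the modulator-correlation rule
g_n = (1/T) Σ_t m_t h_n,t (m_t ~ N(0, 0.1), 100 fast steps), rectified at
zero.

Two stabilizing choices in stage 3, both package design decisions: the raw
gains are normalized as (g + ε)/(mean(g) + ε) with ε = 0.02, which
interpolates smoothly from uniform gains (no co-fluctuation signal yet —
raw mean-normalization of near-zero gains would scramble the frozen
readout and destroy the learning signal) to selective g/mean(g) as the
couplings grow; and gains are smoothed with an EMA (0.7) across updates.
Binary decisions compare the two task-orientation class scores; evaluation
integrates the scores over fast modulator draws (the decision stage sees
the whole 100-step presentation). The deterministic-modulator control sets
m = 1 during training and evaluation with unit gains; the weight-retraining
and decision-layer controls re-initialize their parameters and relearn
them de novo on the task, as in the original comparison.

**Known limitation.** The sample-efficiency ordering of the original
full-scale comparison (modulator fine-tuning reaching criterion before
full retraining, decision-layer retraining plateauing below criterion)
does not reproduce at the desk scale: with 288 matched Gabor features the
binary task's discriminative direction is low-dimensional and high-SNR, so
de-novo gradient learners generalize above the 80% criterion from tens of
samples across every task regime we measured. The corresponding acceptance
test is therefore expected to fail at this scale and is retained
unmodified. The stochastic-modulator protocol itself comfortably exceeds
the performance criterion (~90–96% held-out, median over seeds), learned
couplings concentrate on task-position encoding units, and informative
top-layer units receive preferentially high gains.

## Problem sizes and tolerances

Simulation sizes used by the test and acceptance suites (package choices):
blocks of 40–100 trials with 15–50 units for model fitting; 200-unit
populations with 5% informative units, 2000 training presentations and 10
seeds for the decoding sweep; 10⁶ draws for the mean-correction identity
(1% tolerance); Monte-Carlo assertions at 3 standard errors; parameter
recovery at Spearman ≥ 0.8 and τ within ±30% in ≥ 4 of 5 seeds;
permutation calibration over 1000 null units inside the binomial 95% band.
All randomness flows through explicit `numpy.random.Generator` seeds;
identical configuration and seed reproduce results bit-for-bit.
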