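# modlabel

Targeted stochastic gain modulation as a task-relevance label: simulation,
estimation and decoding tools for multiplicatively modulated neural
population activity.

## The scientific problem

During flexible sensory behavior, a downstream circuit must read out the
handful of task-informative neurons from a large sensory population — and
re-select them within a few trials whenever the task changes. Learning
readout weights by regression is too slow, and nothing in single-neuron
response statistics marks which units matter. The theory implemented here
proposes that a shared, rapidly fluctuating multiplicative gain signal (a
*modulator*) preferentially targets task-informative neurons, so that the
induced co-variability acts as a label a decoder can exploit.

The package is for computational neuroscientists who want to simulate,
fit, and probe this labeling scheme:

* **Encoding**: spike counts k ~ Poisson(λ(s)·exp(c·m − σ²c²/2)), with
  coupling c = |log λ(1) − log λ(0)| proportional to informativeness and a
  mean correction that turns modulation into pure excess variability.
* **Estimation**: a stimulus-response (SR) Poisson regression, and a
  modulated-SR model — a Poisson linear dynamical system with an AR(1)
  latent modulator fitted by EM with a Laplace E-step — with
  cross-validated latent-dimensionality selection via leave-one-neuron-out
  prediction, pseudo-R² fit metrics, and modulator summaries (time
  constant τ = −1/log A, absolute and relative strength).
* **Decoding**: the exact ideal observer (linear weights
  a = log λ(1) − log λ(0) with a modulator-dependent threshold), the
  modulator-guided (MG) decoder whose weight magnitudes are the
  modulator/response correlations (1/T)Σ m_t k_t with signs from trial
  feedback, a sign-only decoder, and regression/SVM baselines — plus
  training-size sweeps and the accuracy-vs-modulator-strength trade-off.
* **Statistics**: d′ informativeness with a calibrated permutation null,
  choice-d′ (hit vs miss), rank-based partial correlations, grouped
  comparisons, within-condition Fano factors, and within-trial modulator
  cross-correlograms between areas.
* **Hierarchy**: a four-stage Gabor-front-end network in which encoding
  couplings are learned by task feedback while top-layer gains follow the
  modulator-correlation rule g = (1/T)Σ m_t h_t, demonstrating that the
  label propagates through processing stages and re-tunes a frozen
  readout.

Everything runs on synthetic data generated by the package itself —
experiment-like blocks of repeated reference presentations ending in a
target, two contrast levels, hit/miss outcomes, and downstream
(MT-like) populations inheriting the primary-area modulator.

## Worked example

Simulate one experiment-like block (40 units, 80 trials, one-dimensional
AR(1) modulator targeting informative units), fit the modulated-SR model,
and ask whether the estimated coupling labels informativeness:

```python
import numpy as np
from scipy.stats import spearmanr
from modlabel import (BlockSimConfig, simulate_ar1_block, reference_subset,
                      build_design_matrix, fit_plds_em, modulator_summaries,
                      dprime, partial_correlation)
from modlabel.synthetic_data import experiment_population

pop = experiment_population(40, sigma_m=0.6, ar_coef=0.5, seed=7)
blk = BlockSimConfig(n_trials=80, seed=7)
rec, m_true = simulate_ar1_block(pop, blk)

ref = reference_subset(rec)           # reference presentations only
design = build_design_matrix(ref)     # contrast x time-window one-hots
fit = fit_plds_em(ref, design, D=1, seed=0)
summ = modulator_summaries(fit, design, bin_width_ms=rec.bin_width_ms)
print(f"modulator time constant: {summ['tau_ms']:.0f} ms")
print(f"relative modulator strength: {summ['relative_strength']:.2f}")

sums = rec.presentation_sums()
meta = rec.presentation_meta
s0 = (meta["stimulus"] == 0).to_numpy()
s1 = (meta["stimulus"] == 1).to_numpy()
rng = np.random.default_rng(0)
dp = np.array([dprime(sums[u, s0], sums[u, s1], rng=rng).value
               for u in range(rec.n_units)])
coupling = np.abs(fit.C[:, 0])
rho, p = partial_correlation(dp, coupling, ref.rates_hz())
print(f"coupling vs informativeness (rate partialled out): "
      f"Spearman r = {rho:.2f}, p = {p:.1e}")
c_true = pop.couplings(*pop.rates())
print(f"coupling recovery: Spearman(C_hat, C_true) = "
      f"{spearmanr(coupling, c_true).statistic:.2f}")
```

Output:

```
modulator time constant: 74 ms
relative modulator strength: 0.12
coupling vs informativeness (rate partialled out): Spearman r = 0.80, p = 6.7e-10
coupling recovery: Spearman(C_hat, C_true) = 0.91
```

The fitted latent fluctuates on a fast (~74 ms) time scale — well below
the trial duration — and its per-unit coupling magnitudes track the units'
d′ even after regressing out firing rate: the modulator labels the
informative subpopulation. The recovered couplings rank-correlate 0.91
with the generative ones.

Higher-level orchestration is available through configuration-driven
experiments (`modlabel run config.yaml`, or `modlabel.run_experiment`):
the decoding-theory strength sweep, the full block pipeline (simulate →
inclusion criteria → fits → dimensionality selection → statistics), the
downstream-inheritance pipeline, and the network fine-tuning comparison.

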