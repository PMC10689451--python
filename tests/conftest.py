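import numpy as np
import pandas as pd
import pytest

from modlabel import (
    BlockSimConfig,
    PopulationRecording,
    PopulationSimConfig,
    simulate_ar1_block,
)
from modlabel.synthetic_data import experiment_population


def make_recording(counts, *, trials=None, repeats=None, stimulus=None,
                   contrast=None, outcome=None, bin_width_ms=50.0, n_stim_bins=None):
    """Small hand-rolled recording for unit tests."""
    counts = np.asarray(counts)
    U, P = counts.shape[:2]
    if counts.ndim == 2:
        counts = counts[:, :, None]
    n_stim_bins = n_stim_bins or counts.shape[2]
    meta = pd.DataFrame({
        "block": 0,
        "trial": trials if trials is not None else np.arange(P),
        "repeat_index": repeats if repeats is not None else np.ones(P, dtype=int),
        "contrast": contrast if contrast is not None else ["high"] * P,
        "stimulus": stimulus if stimulus is not None else np.zeros(P, dtype=int),
        "outcome": outcome if outcome is not None else ["hit"] * P,
    })
    return PopulationRecording(counts=counts, presentation_meta=meta,
                               bin_width_ms=bin_width_ms, n_stim_bins=n_stim_bins)


@pytest.fixture(scope="session")
def ar1_block():
    """One experiment-like block with a targeted AR(1) modulator."""
    pop = experiment_population(30, sigma_m=0.6, seed=11)
    blk = BlockSimConfig(n_trials=60, seed=11)
    rec, m = simulate_ar1_block(pop, blk)
    return {"pop": pop, "blk": blk, "rec": rec, "m": m}


@pytest.fixture(scope="session")
def theory_population_cfg():
    """Theory-setting population: discrete informative/uninformative split."""
    return PopulationSimConfig(
        n_informative=10, n_uninformative=90, n_inactive=0,
        sigma_m=0.5, modulator_law="iid-gaussian", seed=5,
    )
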