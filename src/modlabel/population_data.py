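"""Data model and I/O for binned population recordings.

A :class:`PopulationRecording` holds spike counts binned at (by default)
50 ms resolution for a population of simultaneously recorded units, together
with per-presentation metadata describing the task structure: blocks of
trials, each trial a sequence of repeated presentations of a reference
stimulus (``stimulus == 0``) terminated by at most one target presentation
(``stimulus == 1``), at high or low contrast, with a behavioral outcome
(hit / miss / excluded) attached to every presentation of the trial.

Each presentation window contains ``n_stim_bins`` stimulus-on bins followed
by optional inter-stimulus (off) bins; the off bins provide the baseline
rate used by the inclusion criteria.

The module also implements the unit/trial inclusion rules applied to every
block before model fitting:

* units whose best per-stimulus mean response is not at least 10% above
  baseline are dropped (``low-response``),
* units with a Fano factor more than 5 population standard deviations above
  the population mean Fano are dropped (``outlier-fano``),
* units with overall mean rate below 1 Hz are dropped (``low-rate``),
* trials without a hit/miss outcome are dropped, the first presentation of
  every trial is removed, and a block retaining fewer than 20 valid trials
  is rejected as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

#: metadata columns required for a valid recording
META_COLUMNS = ("block", "trial", "repeat_index", "contrast", "stimulus", "outcome")
#: optional metadata columns preserved through I/O when present
OPTIONAL_META_COLUMNS = ("drift_direction",)

CONTRAST_LEVELS = ("high", "low")
OUTCOMES = ("hit", "miss", "excluded")
AREAS = ("primary", "downstream")


class RecordingFormatError(ValueError):
    """A recording container is missing a required field or column."""


class RecordingDimensionError(ValueError):
    """Counts and metadata disagree on the number of presentations."""


@dataclass
class PopulationRecording:
    """Binned spike counts plus per-presentation task metadata.

    Parameters
    ----------
    counts
        Nonnegative integer array of shape (units, presentations, bins).
    presentation_meta
        DataFrame with one row per presentation and at least the columns in
        :data:`META_COLUMNS`.
    bin_width_ms
        Width of a time bin in milliseconds.
    n_stim_bins
        Number of leading bins per presentation during which the stimulus is
        on; remaining bins are inter-stimulus.
    unit_ids
        Unit identifiers; defaults to ``0..U-1``.
    area
        ``"primary"`` (V1-like) or ``"downstream"`` (MT-like).
    """

    counts: np.ndarray
    presentation_meta: pd.DataFrame
    bin_width_ms: float = 50.0
    n_stim_bins: int = 4
    unit_ids: np.ndarray | None = None
    area: str = "primary"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.unit_ids is None:
            self.unit_ids = np.arange(self.counts.shape[0])
        else:
            self.unit_ids = np.asarray(self.unit_ids)
        self.presentation_meta = self.presentation_meta.reset_index(drop=True)
        self.validate()

    # -- basic shape accessors -------------------------------------------
    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_presentations(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def stim_window_ms(self) -> float:
        return self.bin_width_ms * self.n_stim_bins

    def validate(self) -> None:
        if self.counts.ndim != 3:
            raise RecordingDimensionError(
                f"counts must be 3-d (units, presentations, bins), got {self.counts.shape}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise RecordingFormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise RecordingFormatError("counts must be nonnegative")
        for col in META_COLUMNS:
            if col not in self.presentation_meta.columns:
                raise RecordingFormatError(f"presentation metadata missing column {col!r}")
        if len(self.presentation_meta) != self.n_presentations:
            raise RecordingDimensionError(
                f"counts has {self.n_presentations} presentations but metadata has "
                f"{len(self.presentation_meta)} rows"
            )
        if len(self.unit_ids) != self.n_units:
            raise RecordingDimensionError("unit_ids length does not match counts")
        if not 1 <= self.n_stim_bins <= self.n_bins:
            raise RecordingFormatError("n_stim_bins must lie in [1, n_bins]")
        if self.area not in AREAS:
            raise RecordingFormatError(f"unknown area {self.area!r}")
        meta = self.presentation_meta
        bad_contrast = set(meta["contrast"].unique()) - set(CONTRAST_LEVELS)
        if bad_contrast:
            raise RecordingFormatError(f"unknown contrast levels {sorted(bad_contrast)}")
        bad_outcome = set(meta["outcome"].unique()) - set(OUTCOMES)
        if bad_outcome:
            raise RecordingFormatError(f"unknown outcomes {sorted(bad_outcome)}")
        if not meta["stimulus"].isin([0, 1]).all():
            raise RecordingFormatError("stimulus identity must be 0 or 1")
        # the target, when present, is unique and terminates its trial
        for (_, _), grp in meta.groupby(["block", "trial"], sort=False):
            targets = grp.index[grp["stimulus"] == 1]
            if len(targets) > 1:
                raise RecordingFormatError("more than one target presentation in a trial")
            if len(targets) == 1:
                order = grp["repeat_index"].to_numpy()
                if grp.loc[targets[0], "repeat_index"] != order.max():
                    raise RecordingFormatError("target is not the final presentation of its trial")

    # -- convenience views ------------------------------------------------
    def stim_counts(self) -> np.ndarray:
        """Counts restricted to the stimulus-on bins, shape (U, P, n_stim_bins)."""
        return self.counts[:, :, : self.n_stim_bins]

    def presentation_sums(self) -> np.ndarray:
        """Per-presentation summed counts over the stimulus window, shape (U, P)."""
        return self.stim_counts().sum(axis=2)

    def rates_hz(self) -> np.ndarray:
        """Per-unit mean firing rate in Hz over all bins."""
        return self.counts.mean(axis=(1, 2)) * 1000.0 / self.bin_width_ms

    def select_presentations(self, mask: np.ndarray) -> "PopulationRecording":
        mask = np.asarray(mask)
        return replace(
            self,
            counts=self.counts[:, mask, :],
            presentation_meta=self.presentation_meta.loc[mask].reset_index(drop=True),
        )

    def select_units(self, unit_index: np.ndarray) -> "PopulationRecording":
        unit_index = np.asarray(unit_index)
        return replace(
            self,
            counts=self.counts[unit_index],
            unit_ids=self.unit_ids[unit_index],
        )


# ---------------------------------------------------------------------------
# container I/O (HDF5)
# ---------------------------------------------------------------------------

def write_recording(rec: PopulationRecording, path) -> None:
    """Write a recording to an HDF5 container (counts + metadata table)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=rec.counts.astype(np.int64))
        f.create_dataset("unit_ids", data=np.asarray(rec.unit_ids, dtype=np.int64))
        f.attrs["bin_width_ms"] = rec.bin_width_ms
        f.attrs["n_stim_bins"] = rec.n_stim_bins
        f.attrs["area"] = rec.area
        g = f.create_group("presentation_meta")
        g.attrs["column_order"] = [str(c) for c in rec.presentation_meta.columns]
        for col in rec.presentation_meta.columns:
            values = rec.presentation_meta[col].to_numpy()
            if values.dtype.kind in "OU":
                g.create_dataset(col, data=np.array([str(v) for v in values], dtype="S32"))
            else:
                g.create_dataset(col, data=values)


def read_recording(path) -> PopulationRecording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    RecordingFormatError
        If a required dataset or metadata column is missing.
    RecordingDimensionError
        If counts and metadata disagree on the presentation count.
    """
    with h5py.File(path, "r") as f:
        for name in ("counts", "unit_ids", "presentation_meta"):
            if name not in f:
                raise RecordingFormatError(f"container missing {name!r}")
        counts = f["counts"][...]
        unit_ids = f["unit_ids"][...]
        g = f["presentation_meta"]
        for col in META_COLUMNS:
            if col not in g:
                raise RecordingFormatError(f"presentation metadata missing column {col!r}")
        order = list(g.attrs.get("column_order", sorted(g)))
        meta = {}
        for col in order:
            values = g[col][...]
            if values.dtype.kind == "S":
                values = values.astype(str)
            meta[col] = values
        return PopulationRecording(
            counts=counts,
            presentation_meta=pd.DataFrame(meta),
            bin_width_ms=float(f.attrs["bin_width_ms"]),
            n_stim_bins=int(f.attrs["n_stim_bins"]),
            unit_ids=unit_ids,
            area=str(f.attrs["area"]),
        )


def export_metadata_csv(rec: PopulationRecording, path) -> None:
    rec.presentation_meta.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# inclusion criteria
# ---------------------------------------------------------------------------

@dataclass
class InclusionReport:
    """Outcome of applying the unit/trial inclusion rules to one block."""

    kept_units: list = field(default_factory=list)
    dropped_units: dict = field(default_factory=dict)  # unit id -> reason code
    kept_trials: list = field(default_factory=list)
    dropped_trials: dict = field(default_factory=dict)  # (block, trial) -> reason code
    n_first_presentations_removed: int = 0
    block_excluded: bool = False
    block_excluded_reason: str | None = None


def _unit_fano_factors(rec: PopulationRecording) -> np.ndarray:
    """Per-unit Fano factor of presentation-summed counts, within condition.

    Conditions are (contrast, stimulus) cells, so stimulus-driven rate
    differences do not inflate the variance; cells with < 2 presentations or
    zero mean are skipped.
    """
    sums = rec.presentation_sums()
    meta = rec.presentation_meta
    fanos = np.full(rec.n_units, np.nan)
    per_cond: list[np.ndarray] = []
    for (_, _), grp in meta.groupby(["contrast", "stimulus"], sort=False):
        idx = grp.index.to_numpy()
        if len(idx) < 2:
            continue
        x = sums[:, idx]
        mu = x.mean(axis=1)
        var = x.var(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_cond.append(np.where(mu > 0, var / mu, np.nan))
    if per_cond:
        stacked = np.vstack(per_cond)
        with np.errstate(invalid="ignore"):
            fanos = np.nanmean(stacked, axis=0)
    return fanos


def apply_inclusion_criteria(
    rec: PopulationRecording,
    *,
    baseline_rate_hz: float | np.ndarray | None = None,
    response_factor: float = 1.10,
    fano_sd_threshold: float = 5.0,
    rate_min_hz: float = 1.0,
    min_trials: int = 20,
) -> tuple[PopulationRecording | None, InclusionReport]:
    """Apply the unit/trial inclusion rules to one block.

    Parameters
    ----------
    baseline_rate_hz
        Per-unit (or scalar) baseline rate. When ``None``, the baseline is
        the mean rate in the inter-stimulus (off) bins; a recording without
        off bins then requires an explicit baseline.

    Returns
    -------
    (recording, report)
        The filtered recording and an :class:`InclusionReport`. When the
        block is rejected (fewer than ``min_trials`` valid trials), the
        recording is ``None`` and ``report.block_excluded`` is set — this is
        a structured result, not an exception.
    """
    report = InclusionReport()
    meta = rec.presentation_meta

    # ---- trials: require a hit/miss outcome ----------------------------
    keep_mask = np.ones(rec.n_presentations, dtype=bool)
    for (blk, trial), grp in meta.groupby(["block", "trial"], sort=False):
        outcome = grp["outcome"].iloc[0]
        if outcome not in ("hit", "miss"):
            keep_mask[grp.index.to_numpy()] = False
            report.dropped_trials[(blk, trial)] = "incomplete-outcome"
        else:
            report.kept_trials.append((blk, trial))

    # ---- remove the first presentation of each trial -------------------
    first = meta["repeat_index"] == 0
    report.n_first_presentations_removed = int((first & keep_mask).sum())
    keep_mask &= ~first.to_numpy()

    filtered = rec.select_presentations(keep_mask)
    n_valid_trials = len(report.kept_trials)
    if n_valid_trials < min_trials:
        report.block_excluded = True
        report.block_excluded_reason = "too-few-trials"
        report.dropped_units = {}
        return None, report

    # ---- unit criteria on the retained presentations -------------------
    scale = 1000.0 / filtered.bin_width_ms  # counts per bin -> Hz
    stim = filtered.stim_counts()
    meta_f = filtered.presentation_meta

    # baseline: inter-stimulus bins when present, else user-supplied
    if filtered.n_bins > filtered.n_stim_bins:
        off = filtered.counts[:, :, filtered.n_stim_bins:]
        baseline = off.mean(axis=(1, 2)) * scale
    elif baseline_rate_hz is not None:
        baseline = np.broadcast_to(np.asarray(baseline_rate_hz, dtype=float), (filtered.n_units,))
    else:
        raise ValueError(
            "recording has no inter-stimulus bins; supply baseline_rate_hz"
        )

    # max over the two per-stimulus mean responses
    per_stim_rates = []
    for s in (0, 1):
        idx = meta_f.index[meta_f["stimulus"] == s].to_numpy()
        if len(idx):
            per_stim_rates.append(stim[:, idx, :].mean(axis=(1, 2)) * scale)
    best_response = np.max(per_stim_rates, axis=0)

    fanos = _unit_fano_factors(filtered)
    finite = np.isfinite(fanos)
    if finite.sum() >= 2:
        fano_cut = fanos[finite].mean() + fano_sd_threshold * fanos[finite].std(ddof=1)
    else:
        fano_cut = np.inf
    mean_rates = filtered.rates_hz()

    keep_units = np.ones(filtered.n_units, dtype=bool)
    for i, uid in enumerate(filtered.unit_ids):
        if best_response[i] < response_factor * baseline[i]:
            report.dropped_units[uid] = "low-response"
            keep_units[i] = False
        elif np.isfinite(fanos[i]) and fanos[i] > fano_cut:
            report.dropped_units[uid] = "outlier-fano"
            keep_units[i] = False
        elif mean_rates[i] < rate_min_hz:
            report.dropped_units[uid] = "low-rate"
            keep_units[i] = False
        else:
            report.kept_units.append(uid)

    filtered = filtered.select_units(np.flatnonzero(keep_units))
    return filtered, report
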