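"""Data model and text-table I/O for spike trains and trial metadata.

The interchange format is deliberately plain: comma-separated text with a
header row, spike times in milliseconds relative to stimulus onset (negative
values are pre-stimulus spikes). Spike trains are represented downstream as
1 kHz binary vectors, so duplicate spikes falling in the same 1 ms bin are
collapsed on read (a 1 kHz 0/1 signal cannot hold two spikes per sample).

Column schemas
--------------
spikes.csv : unit_id, trial_id, spike_time_ms
trials.csv : trial_id, dom_contrast, nondom_contrast, drift_freq_hz,
             spatial_freq_cpd, chromatic_axis, is_blank, stim_duration_ms
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPIKE_COLUMNS = ("unit_id", "trial_id", "spike_time_ms")
TRIAL_COLUMNS = (
    "trial_id",
    "dom_contrast",
    "nondom_contrast",
    "drift_freq_hz",
    "spatial_freq_cpd",
    "chromatic_axis",
    "is_blank",
    "stim_duration_ms",
)

CHROMATIC_AXES = ("achromatic", "L+M", "L-M", "S", "none")


class FormatError(ValueError):
    """A table is missing required columns or fails validation."""


@dataclass
class SpikeTable:
    """Spike times per (unit, trial), stimulus-onset-aligned, in ms."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SPIKE_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"spike table missing column(s): {missing}")
        self.df = self.df.sort_values(list(SPIKE_COLUMNS), kind="mergesort").reset_index(
            drop=True
        )

    @property
    def units(self) -> list:
        return list(pd.unique(self.df["unit_id"]))

    def n_spikes(self) -> int:
        return len(self.df)

    def trials_for_unit(self, unit_id) -> list:
        return list(pd.unique(self.df.loc[self.df["unit_id"] == unit_id, "trial_id"]))

    def spikes_for(self, unit_id, trial_id) -> np.ndarray:
        sel = (self.df["unit_id"] == unit_id) & (self.df["trial_id"] == trial_id)
        return self.df.loc[sel, "spike_time_ms"].to_numpy(dtype=float)

    def for_unit(self, unit_id) -> "SpikeTable":
        return SpikeTable(self.df[self.df["unit_id"] == unit_id].copy())


@dataclass
class TrialTable:
    """Per-trial stimulus condition metadata."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"trial table missing column(s): {missing}")
        df = self.df
        if df["trial_id"].duplicated().any():
            raise FormatError("trial table contains duplicate trial_id values")
        for col in ("dom_contrast", "nondom_contrast"):
            c = df[col].to_numpy(dtype=float)
            if np.any((c < 0) | (c > 1)):
                raise FormatError(f"{col} outside [0, 1]")
        blanks = df["is_blank"].astype(bool)
        if np.any(blanks & ((df["dom_contrast"] != 0) | (df["nondom_contrast"] != 0))):
            raise FormatError("blank trials must have zero contrast in both eyes")
        if np.any(~blanks & (df["drift_freq_hz"].to_numpy(dtype=float) <= 0)):
            raise FormatError("drift_freq_hz must be positive for non-blank trials")
        self.df = df.reset_index(drop=True)

    def condition_of(self, trial_id) -> pd.Series:
        row = self.df[self.df["trial_id"] == trial_id]
        if row.empty:
            raise KeyError(f"trial_id {trial_id!r} not in trial table")
        return row.iloc[0]

    @property
    def trial_ids(self) -> list:
        return list(self.df["trial_id"])


def validate_pair(spikes: SpikeTable, trials: TrialTable) -> None:
    """Every trial referenced by a spike must exist in the trial table."""
    known = set(trials.df["trial_id"])
    referenced = set(pd.unique(spikes.df["trial_id"]))
    orphans = referenced - known
    if orphans:
        raise FormatError(
            f"{len(orphans)} trial_id(s) in spike table absent from trial table, "
            f"e.g. {sorted(orphans)[:5]}"
        )


def _dedupe_1ms(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse spikes sharing a 1 ms bin within the same (unit, trial)."""
    bins = np.floor(df["spike_time_ms"].to_numpy(dtype=float)).astype(np.int64)
    key = df.assign(_bin=bins)
    keep = ~key.duplicated(subset=["unit_id", "trial_id", "_bin"])
    return df[keep.to_numpy()], int((~keep).sum())


def read_spike_table(path) -> SpikeTable:
    """Read spikes.csv; duplicate spikes within a 1 ms bin collapse to one.

    Raises :class:`FormatError` on a missing column and ``ValueError`` naming
    the offending row for non-numeric spike times.
    """
    df = pd.read_csv(path)
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {missing}")
    times = pd.to_numeric(df["spike_time_ms"], errors="coerce")
    bad = times.isna() & df["spike_time_ms"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: non-numeric spike_time_ms at data row {row}")
    df["spike_time_ms"] = times
    df = df.dropna(subset=["spike_time_ms"])
    df = df.sort_values(["unit_id", "trial_id", "spike_time_ms"], kind="mergesort")
    df, n_dropped = _dedupe_1ms(df)
    if n_dropped:
        logger.warning("%s: collapsed %d duplicate spike(s) within 1 ms bins", path, n_dropped)
    return SpikeTable(df[list(SPIKE_COLUMNS)].reset_index(drop=True))


def write_spike_table(table: SpikeTable, path) -> None:
    table.df.to_csv(path, index=False)


def read_trial_table(path) -> TrialTable:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {missing}")
    df["is_blank"] = df["is_blank"].astype(bool)
    return TrialTable(df)


def write_trial_table(table: TrialTable, path) -> None:
    table.df.to_csv(path, index=False)


def binarize(spike_times, window, fs: float = 1000.0) -> np.ndarray:
    """Bin spike times (ms) into a 0/1 vector over ``window = (t0, t1)``.

    The vector has one entry per 1/fs-second bin; an entry is 1 iff at least
    one spike falls in that bin. Spikes outside the window are ignored.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"window end {t1} must exceed start {t0}")
    n = int(round((t1 - t0) * fs / 1000.0))
    out = np.zeros(n, dtype=np.int8)
    times = np.asarray(spike_times, dtype=float)
    idx = np.floor((times - t0) * fs / 1000.0).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < n)]
    out[idx] = 1
    return out


# ---------------------------------------------------------------------------
# Contrast binning

@dataclass(frozen=True)
class BinnedContrast:
    """One of the study's consolidated contrast ranges."""

    label: str
    lo: float
    hi: float

    @property
    def representative(self) -> float:
        """Median of the range — the value population data are presented at."""
        return 0.5 * (self.lo + self.hi)

    def contains(self, c: float) -> bool:
        return self.lo <= c <= self.hi


#: Contrast levels varied across recording days cluster into these ranges;
#: population averages pool within a range and are plotted at its median.
CONTRAST_BINS: tuple[BinnedContrast, ...] = (
    BinnedContrast("zero", 0.0, 0.0),
    BinnedContrast("very_low", 0.025, 0.05),
    BinnedContrast("low", 0.106, 0.135),
    BinnedContrast("medium", 0.318, 0.368),
    BinnedContrast("high", 0.8, 1.0),
)

#: Sentinel for contrasts falling between ranges; excluded from averaging.
UNBINNED = BinnedContrast("unbinned", float("nan"), float("nan"))


def bin_contrast(c: float) -> BinnedContrast:
    """Map a Michelson contrast to its consolidated range.

    Contrasts in the gaps between ranges return the :data:`UNBINNED`
    sentinel and are excluded from population averaging rather than snapped.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"contrast {c} outside [0, 1]")
    for b in CONTRAST_BINS:
        if b.contains(c):
            return b
    return UNBINNED


def bin_by_label(label: str) -> BinnedContrast:
    for b in CONTRAST_BINS:
        if b.label == label:
            return b
    raise KeyError(label)
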