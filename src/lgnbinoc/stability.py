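"""Detection and trimming of non-stationary trial spans in a recording.

Slow electrode drift or loss of isolation shows up as step changes in a
unit's mean spike rate across trials. Per-trial spike counts over a wide
window around the stimulus (default -600 to +1300 ms) are smoothed with a
centered running mean (default 20 trials) and segmented by a mean-shift
change-point model: change points minimize total within-segment squared
deviation from segment means, with the number of changes chosen by a
penalized cost (BIC-like penalty 2*sigma^2*log(n) per change by default,
sigma estimated robustly from first differences of the raw counts so the
steps being sought do not inflate it). Detected segments are then either
kept/dropped by comparing segment means (default policy) or reduced to the
single longest stable segment.

Trimming never reorders trials and the retained set is a union of
contiguous segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import SpikeTable

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # makes the MAD a consistent estimator of the Normal SD


def _robust_sigma(x: np.ndarray) -> float:
    """Noise SD from scaled MAD of first differences (step-insensitive)."""
    d = np.diff(np.asarray(x, dtype=float))
    return MAD_SCALE * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


@dataclass
class TrialCountSeries:
    unit_id: object
    trial_ids: list
    counts: np.ndarray      # spikes per trial in the counting window
    smoothed: np.ndarray    # centered running mean of counts

    def __len__(self) -> int:
        return len(self.counts)


def trial_counts(spike_table: SpikeTable, unit_id, trial_order,
                 window=(-600.0, 1300.0), smooth_window: int = 20
                 ) -> TrialCountSeries:
    """Per-trial spike counts in ``window``, in presentation order."""
    if unit_id not in spike_table.units:
        raise KeyError(f"unit {unit_id!r} not present in spike table")
    sub = spike_table.df[spike_table.df["unit_id"] == unit_id]
    t0, t1 = window
    times = sub["spike_time_ms"].to_numpy(dtype=float)
    in_win = (times >= t0) & (times <= t1)
    per_trial = sub.loc[in_win].groupby("trial_id").size()
    counts = np.array([per_trial.get(tr, 0) for tr in trial_order], dtype=float)
    return TrialCountSeries(
        unit_id=unit_id,
        trial_ids=list(trial_order),
        counts=counts,
        smoothed=running_mean(counts, smooth_window),
    )


def running_mean(series: np.ndarray, window_trials: int = 20) -> np.ndarray:
    """Centered moving mean; edge windows shrink to the available samples."""
    if window_trials < 1:
        raise ValueError("window_trials must be >= 1")
    x = np.asarray(series, dtype=float)
    return (
        pd.Series(x).rolling(window=window_trials, center=True, min_periods=1)
        .mean().to_numpy()
    )


def detect_change_points(smoothed: np.ndarray, penalty: float | None = None,
                         min_segment: int = 10,
                         noise_scale: float | None = None) -> list[int]:
    """Mean-shift change points by penalized optimal partitioning.

    Returns ordered indices where new segments begin (a change at k means
    segments ``[..k)`` and ``[k..)``). The dynamic program is exact: it
    minimizes total within-segment SSE plus ``penalty`` per change.
    ``penalty`` defaults to ``2 * sigma^2 * log(n)``; sigma comes from
    ``noise_scale`` if given (callers pass the raw-count noise SD) else
    from first differences of ``smoothed``. Equal-cost placements break
    toward the earliest index. Series shorter than ``2*min_segment`` return
    no change points, with a warning.
    """
    x = np.asarray(smoothed, dtype=float)
    n = len(x)
    if n < 2 * min_segment:
        logger.warning("series of length %d too short for change-point search", n)
        return []
    if penalty is None:
        sigma = noise_scale if noise_scale is not None else _robust_sigma(x)
        penalty = 2.0 * max(float(sigma), 1e-6) ** 2 * np.log(n)
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    # F[j]: best penalized cost of x[0:j]; one penalty per change, so the
    # first segment is free.
    F = np.full(n + 1, np.inf)
    last = np.zeros(n + 1, dtype=int)
    F[0] = -penalty
    idx = np.arange(n + 1)
    for j in range(min_segment, n + 1):
        i = idx[: j - min_segment + 1]
        lens = j - i
        s = c1[j] - c1[i]
        sse = (c2[j] - c2[i]) - s * s / lens
        cost = F[i] + penalty + sse
        k = int(np.argmin(cost))  # first minimizer -> earliest index on ties
        F[j], last[j] = cost[k], k
    cps = []
    j = n
    while j > 0:
        i = last[j]
        if i > 0:
            cps.append(i)
        j = i
    return sorted(cps)


def _segments(n: int, change_points) -> list[tuple[int, int]]:
    bounds = [0] + list(change_points) + [n]
    return [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]


def trim_unstable(counts: np.ndarray, change_points,
                  policy: str = "drop_outlier_segments",
                  mad_k: float = 3.0) -> np.ndarray:
    """Retained trial indices after removing unstable segments.

    ``longest_stable_segment`` keeps the single longest inter-change
    segment (earliest on ties). ``drop_outlier_segments`` keeps segments
    whose mean count is within ``mad_k`` scaled MADs of the median segment
    mean; with only two segments the MAD across means cannot flag either,
    so each mean is judged against ``mad_k`` standard errors of the segment
    mean instead, and if both deviate the longer segment is kept. Raises if
    nothing would be retained.
    """
    x = np.asarray(counts, dtype=float)
    n = len(x)
    segs = _segments(n, list(change_points))
    lengths = np.array([b - a for a, b in segs])
    if policy == "longest_stable_segment":
        a, b = segs[int(np.argmax(lengths))]
        return np.arange(a, b)
    if policy != "drop_outlier_segments":
        raise ValueError(f"unknown policy {policy!r}")
    if len(segs) == 1:
        return np.arange(n)
    means = np.array([x[a:b].mean() for a, b in segs])
    med = np.median(means)
    smad = MAD_SCALE * np.median(np.abs(means - med))
    if len(segs) >= 3 and smad > 0:
        keep = np.abs(means - med) <= mad_k * smad
    elif len(segs) >= 3:  # zero MAD: only exact-median segment means survive
        if not np.allclose(means, med):
            logger.warning("zero MAD of segment means; keeping exact-median segments")
        keep = np.isclose(means, med)
    else:
        resid = np.concatenate([x[a:b] - x[a:b].mean() for a, b in segs])
        spread = MAD_SCALE * np.median(np.abs(resid))
        if spread == 0:
            keep = np.ones(len(segs), dtype=bool)
        else:
            keep = np.abs(means - med) <= mad_k * spread / np.sqrt(lengths)
        if not keep.any():
            keep = np.zeros(len(segs), dtype=bool)
            keep[int(np.argmax(lengths))] = True
    if not keep.any():
        raise ValueError("all segments trimmed; unit unusable")
    return np.concatenate([np.arange(a, b) for (a, b), k in zip(segs, keep) if k])


@dataclass
class StabilityReport:
    unit_id: object
    n_trials: int
    change_points: list[int]
    segment_means: list[float]
    retained_indices: np.ndarray
    retained_trial_ids: list

    @property
    def fraction_retained(self) -> float:
        return len(self.retained_indices) / self.n_trials if self.n_trials else float("nan")


def screen_unit(spike_table: SpikeTable, unit_id, trial_order,
                window=(-600.0, 1300.0), smooth_window: int = 20,
                penalty: float | None = None, min_segment: int = 10,
                policy: str = "drop_outlier_segments",
                mad_k: float = 3.0) -> StabilityReport:
    """Full stability screen for one unit: count, smooth, segment, trim."""
    series = trial_counts(spike_table, unit_id, trial_order,
                          window=window, smooth_window=smooth_window)
    cps = detect_change_points(series.smoothed, penalty=penalty,
                               min_segment=min_segment,
                               noise_scale=_robust_sigma(series.counts))
    retained = trim_unstable(series.counts, cps, policy=policy, mad_k=mad_k)
    segs = _segments(len(series), cps)
    return StabilityReport(
        unit_id=unit_id,
        n_trials=len(series),
        change_points=cps,
        segment_means=[float(series.counts[a:b].mean()) for a, b in segs],
        retained_indices=retained,
        retained_trial_ids=[series.trial_ids[i] for i in retained],
    )
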