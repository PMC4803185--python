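"""Peak finding and per-cycle period/amplitude statistics.

The measurement pipeline mirrors how single-cell reporter traces are scored:
the background-subtracted trace is smoothed, local maxima are detected,
minima are located between successive maxima, and peaks are filtered by two
rules before cycles are computed:

* **size rule** — a peak whose height above the higher of its two adjacent
  troughs is smaller than ``min_prominence_frac`` (default 0.1) times the
  dynamic range (max - min of the smoothed trace) is discarded;
* **edge rule** — a peak closer than ``edge_margin`` (default 40 min) to
  either end of the recording is discarded.

Periods are the intervals between consecutive retained peaks, and intervals
longer than ``max_period`` (default 140 min) are flagged as not accepted —
they are read as elapsed time between disconnected oscillatory episodes
rather than genuine cycles.  The amplitude of a cycle is the mean of the
differences between a peak's height and its two adjacent minima, which makes
it robust to signal drift across one cycle.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .timeseries import TimeSeries

__all__ = [
    "PeakSet",
    "CycleStats",
    "PeakParams",
    "DEFAULT_PRESET",
    "ISOLATED_PRESET",
    "subtract_background",
    "smooth",
    "detect_peaks",
    "compute_cycles",
    "classify_persistence",
    "cohort_prominence_floor",
    "refined_peak_intervals",
    "analyze_trace",
]

#: reason codes for discarded peaks
BELOW_DYNAMIC_RANGE = "below_dynamic_range"
EDGE_PROXIMITY = "edge_proximity"


@dataclass(frozen=True)
class PeakParams:
    """Tunable knobs of the peak pipeline (minutes / dimensionless)."""

    smooth_window: float = 10.0
    min_prominence_frac: float = 0.1
    edge_margin: float = 40.0
    max_period: float = 140.0


#: the standard parameterisation used for low-density cohorts
DEFAULT_PRESET = PeakParams()
#: a less stringent preset for short recordings of fully isolated cells
ISOLATED_PRESET = PeakParams(min_prominence_frac=0.05, edge_margin=20.0)


@dataclass
class PeakSet:
    """Detected peaks/troughs of one trace plus the discard ledger."""

    peak_times: np.ndarray
    peak_heights: np.ndarray
    trough_times: np.ndarray
    trough_heights: np.ndarray
    discarded: list = field(default_factory=list)  # (time, reason) tuples
    meta: dict = field(default_factory=dict)

    @property
    def n_peaks(self) -> int:
        return self.peak_times.size


@dataclass
class CycleStats:
    """Per-cycle periods and amplitudes derived from a PeakSet."""

    periods: np.ndarray          # min, between consecutive retained peaks
    accepted: np.ndarray         # bool, False where period > max_period
    amplitudes: np.ndarray       # au, one per retained peak
    n_peaks: int
    duration: float              # min, recording length
    meta: dict = field(default_factory=dict)

    @property
    def accepted_periods(self) -> np.ndarray:
        return self.periods[self.accepted]

    @property
    def n_cycles(self) -> int:
        return int(self.accepted.sum())

    @property
    def median_period(self) -> float:
        acc = self.accepted_periods
        return float(np.median(acc)) if acc.size else float("nan")

    @property
    def mean_amplitude(self) -> float:
        return float(np.mean(self.amplitudes)) if self.amplitudes.size else float("nan")


def subtract_background(raw: TimeSeries, background: TimeSeries | None = None,
                        trend_window: float = 200.0) -> TimeSeries:
    """Remove low-frequency baseline trends from a raw trace.

    When a locally measured background channel is available it is subtracted
    pointwise (both traces must share a time grid).  Without one, a slow
    trend is estimated with a wide centred moving average (``trend_window``
    minutes) and subtracted; which path was taken is recorded in
    ``meta['background']``.
    """
    if background is not None:
        if background.t.size != raw.t.size or not np.allclose(background.t, raw.t):
            raise ValueError("raw and background traces must share a time grid")
        return raw.copy_with(raw.v - background.v, meta={"background": "measured"})
    trend = smooth(raw, trend_window).v
    return raw.copy_with(raw.v - trend, meta={"background": "trend_estimate"})


def smooth(series: TimeSeries, window: float = 10.0) -> TimeSeries:
    """Centred moving average with reflected ends (linear phase, no time shift).

    ``window`` is in minutes and is rounded to an odd number of samples so
    the kernel is symmetric.
    """
    dt = series.dt_sample
    if window < dt:
        raise ValueError("window must be at least one sampling interval")
    if window > series.duration:
        raise ValueError("window exceeds the trace length")
    half = max(1, int(round(window / dt)) // 2)
    n_k = 2 * half + 1
    padded = np.concatenate([series.v[half:0:-1], series.v, series.v[-2:-half - 2:-1]])
    out = np.convolve(padded, np.ones(n_k) / n_k, mode="valid")
    return series.copy_with(out, meta={"smooth_window": window})


def _local_extrema(v: np.ndarray) -> np.ndarray:
    """Indices of local maxima; the leftmost sample of any tied plateau.

    Boundary samples that exceed their single neighbour count as candidate
    maxima too — the edge rule is what discards them, and it records why.
    """
    idx, props = find_peaks(v, plateau_size=(1, None))
    idx = props["left_edges"] if idx.size else idx
    out = list(idx)
    if v.size >= 2 and v[0] > v[1]:
        out.insert(0, 0)
    if v.size >= 2 and v[-1] > v[-2]:
        out.append(v.size - 1)
    return np.asarray(out, dtype=int)


def detect_peaks(series: TimeSeries,
                 min_prominence_frac: float = 0.1,
                 edge_margin: float = 40.0,
                 smooth_window: float = 10.0,
                 min_prominence_abs: float = 0.0,
                 min_separation: float = 40.0) -> PeakSet:
    """Detect and filter peaks of a background-subtracted trace.

    The trace is smoothed, local maxima are found on the smoothed version,
    and troughs are the minima between successive maxima (plus the segments
    between the trace boundaries and the outermost maxima, so every peak has
    two adjacent troughs).  Filters are applied in order: size rule first,
    then the edge rule; discarded peaks are kept in ``discarded`` with their
    reason code.  Peak and trough heights are read from the *unsmoothed*
    series at the located times.

    ``min_prominence_abs`` adds an absolute floor to the size rule; cohort
    pipelines use it to stop noise-scale wiggles of never-oscillating cells
    from passing a purely relative threshold (see
    :func:`cohort_prominence_floor`).  ``min_separation`` merges candidate
    maxima closer than the resolvable period floor (40 min, the lower edge
    of the analysis period band) before any filtering, keeping the higher
    of each pair.
    """
    if len(series) < 3:
        raise ValueError("series must contain at least 3 samples")
    sm = smooth(series, smooth_window)
    v = sm.v
    t = series.t
    dyn = float(v.max() - v.min())
    idx = _local_extrema(v)
    empty = np.array([])
    if idx.size == 0 or dyn == 0.0:
        return PeakSet(empty, empty, empty, empty, [],
                       meta={"dynamic_range": dyn})
    # candidate maxima closer than the resolvable period floor cannot both
    # be genuine cycles; merge each such pair by keeping the higher one
    if min_separation > 0:
        idx = list(idx)
        changed = True
        while changed and len(idx) > 1:
            changed = False
            for k in range(len(idx) - 1):
                if t[idx[k + 1]] - t[idx[k]] < min_separation:
                    del idx[k if v[idx[k]] < v[idx[k + 1]] else k + 1]
                    changed = True
                    break
        idx = np.asarray(idx, dtype=int)

    # troughs between successive candidate maxima + boundary segments
    def segment_min(lo: int, hi: int) -> int:
        seg = v[lo:hi + 1]
        return lo + int(np.argmin(seg))

    bounds = np.concatenate([[0], idx, [v.size - 1]])
    trough_idx = np.array([segment_min(bounds[k], bounds[k + 1])
                           for k in range(len(bounds) - 1)], dtype=int)

    threshold = max(min_prominence_frac * dyn, min_prominence_abs)
    discarded: list[tuple[float, str]] = []
    kept = []
    for k, i in enumerate(idx):
        # a boundary maximum has no trough on its outer side: judge its
        # size against the inner trough only
        sides = [v[trough_idx[k]]] if trough_idx[k] != i else []
        if trough_idx[k + 1] != i:
            sides.append(v[trough_idx[k + 1]])
        size = v[i] - max(sides) if sides else 0.0
        if size < threshold:
            discarded.append((float(t[i]), BELOW_DYNAMIC_RANGE))
        elif t[i] - t[0] < edge_margin or t[-1] - t[i] < edge_margin:
            discarded.append((float(t[i]), EDGE_PROXIMITY))
        else:
            kept.append(i)
    kept = np.asarray(kept, dtype=int)
    if kept.size == 0:
        return PeakSet(empty, empty, empty, empty, discarded,
                       meta={"dynamic_range": dyn})

    # recompute troughs between the retained peaks so they alternate strictly
    bounds = np.concatenate([[0], kept, [v.size - 1]])
    trough_idx = np.array([segment_min(bounds[k], bounds[k + 1])
                           for k in range(len(bounds) - 1)], dtype=int)
    return PeakSet(
        peak_times=t[kept].astype(float),
        peak_heights=series.v[kept].astype(float),
        trough_times=t[trough_idx].astype(float),
        trough_heights=series.v[trough_idx].astype(float),
        discarded=discarded,
        meta={"dynamic_range": dyn, "threshold": threshold},
    )


def compute_cycles(peaks: PeakSet, duration: float | None = None,
                   max_period: float = 140.0) -> CycleStats:
    """Derive per-cycle periods and amplitudes from a PeakSet.

    With fewer than 2 peaks the period list is empty.  Each retained peak
    contributes one amplitude: the mean of its height above its left and
    right adjacent troughs.
    """
    n = peaks.n_peaks
    if duration is None:
        duration = float(peaks.meta.get("duration", np.nan))
    periods = np.diff(peaks.peak_times) if n >= 2 else np.array([])
    accepted = periods <= max_period if periods.size else np.array([], dtype=bool)
    if n and peaks.trough_times.size == n + 1:
        amp = peaks.peak_heights - 0.5 * (peaks.trough_heights[:-1]
                                          + peaks.trough_heights[1:])
    else:
        amp = np.array([])
    return CycleStats(periods, accepted, amp, n_peaks=n, duration=duration,
                      meta={"max_period": max_period})


def classify_persistence(cycles: CycleStats, duration: float | None = None,
                         dataset_median_period: float | None = None,
                         threshold: float = 0.80,
                         edge_margin: float = 40.0) -> tuple[str, float]:
    """Classify a cell and compute its oscillating time fraction.

    The oscillating fraction is ``min(1, n_peaks * median_period /
    duration)`` where the median period is the *dataset-level* median when
    provided (falling back to the cell's own).  A cell is ``persistent``
    when its longest chain of sequential peaks — consecutive peaks whose
    intervals all pass the accepted-period rule — spans at least
    ``threshold`` of the *observable* recording, i.e. the recording net of
    the two edge margins where peaks cannot be detected;
    ``non_oscillating`` when it has fewer than 2 peaks; otherwise
    ``intermittent``.
    """
    if duration is None:
        duration = cycles.duration
    if not np.isfinite(duration) or duration <= 0:
        raise ValueError("duration must be positive")
    med = dataset_median_period
    if med is None or not np.isfinite(med):
        med = cycles.median_period
    if np.isfinite(med):
        fraction = min(1.0, cycles.n_peaks * med / duration)
    else:
        fraction = 0.0
    if cycles.n_peaks < 2:
        return "non_oscillating", fraction
    # longest run of sequential peaks (consecutive accepted intervals);
    # a chain of n peaks evidences n cycles, as in the fraction formula
    best = run = 1
    for ok in cycles.accepted:
        run = run + 1 if ok else 1
        best = max(best, run)
    observable = max(duration - 2 * edge_margin, 1e-9)
    if np.isfinite(med) and best * med >= threshold * observable:
        return "persistent", fraction
    return "intermittent", fraction


def cohort_prominence_floor(series_list: list[TimeSeries],
                            smooth_window: float = 10.0,
                            frac: float = 0.1) -> float:
    """Absolute peak-size floor for a cohort: ``frac`` x median dynamic range.

    Cohort assembly keeps only rhythmic cells, so the relevant intensity
    scale is set by the population, not by each trace alone.  Passing this
    floor to :func:`detect_peaks` prevents never-oscillating cells (whose own
    dynamic range is pure noise) from contributing spurious peaks.
    """
    dyns = []
    for s in series_list:
        v = smooth(s, smooth_window).v
        dyns.append(v.max() - v.min())
    return frac * float(np.median(dyns))


def refined_peak_intervals(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Inter-peak intervals of a densely sampled signal, with sub-step
    parabolic refinement of each maximum's position."""
    idx, _ = find_peaks(x)
    idx = idx[(idx > 0) & (idx < x.size - 1)]
    if idx.size < 2:
        return np.array([])
    dt = t[1] - t[0]
    num = x[idx - 1] - x[idx + 1]
    den = x[idx - 1] - 2 * x[idx] + x[idx + 1]
    shift = np.where(den != 0, 0.5 * num / den, 0.0)
    return np.diff(t[idx] + shift * dt)


def analyze_trace(series: TimeSeries, params: PeakParams = DEFAULT_PRESET,
                  min_prominence_abs: float = 0.0) -> CycleStats:
    """Convenience wrapper: detect peaks and compute cycles with one preset."""
    ps = detect_peaks(series,
                      min_prominence_frac=params.min_prominence_frac,
                      edge_margin=params.edge_margin,
                      smooth_window=params.smooth_window,
                      min_prominence_abs=min_prominence_abs)
    cs = compute_cycles(ps, duration=series.duration,
                        max_period=params.max_period)
    return cs
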