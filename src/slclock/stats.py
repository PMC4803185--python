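"""Cycle-correlation statistics, model-data comparison, and parameter sweeps.

Successive-cycle analyses ask whether the amplitude (or period) of cycle
``i+1`` remembers cycle ``i`` within the same cell.  Values are normalised
to the data-set mean, pairs are formed only within cells, and a randomized
control redraws values from the pooled list to show what no memory looks
like.  The perpendicular distance of a pair to the identity line,
``D_i = |v_{i+1} - v_i| / sqrt(2)``, and the pair average
``v_i* = (v_i + v_{i+1}) / 2`` summarise the scatter.

The two sweeps connect the model to data: the colored-noise sweep maps the
median oscillating-time fraction over the ``(sigma_mu2, tau_mu)`` plane, and
the additive-noise sweep traces the median quality factor (with 68% CI and a
two-sample KS p-value against a reference sample) along a ``sigma_z2`` grid.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .peaks import (DEFAULT_PRESET, PeakParams, analyze_trace,
                    classify_persistence, cohort_prominence_floor)
from .precision import quality_factor
from .simulator import SLParams, render_trace, simulate_ensemble
from .timeseries import TimeSeries

__all__ = [
    "PairData",
    "SweepResult",
    "successive_pairs",
    "randomized_control",
    "correlation_summary",
    "period_amplitude_correlation",
    "ks_compare",
    "analyze_cohort",
    "cohort_cycles",
    "sweep_colored_noise",
    "sweep_additive_noise",
]


@dataclass
class PairData:
    """Ordered consecutive-cycle value pairs, normalised to the data-set mean."""

    table: pd.DataFrame       # columns: cell_id, cycle_index, v1, v2
    normalizer: float         # the mean used for normalisation (1.0 if none)

    @property
    def v1(self) -> np.ndarray:
        return self.table["v1"].to_numpy()

    @property
    def v2(self) -> np.ndarray:
        return self.table["v2"].to_numpy()

    @property
    def v_star(self) -> np.ndarray:
        """Per-pair average (v_i + v_{i+1}) / 2."""
        return 0.5 * (self.v1 + self.v2)

    @property
    def distance_to_identity(self) -> np.ndarray:
        """Perpendicular distance D_i = |v_{i+1} - v_i| / sqrt(2)."""
        return np.abs(self.v2 - self.v1) / math.sqrt(2.0)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SweepResult:
    """Gridded summary statistics of a noise-parameter sweep."""

    table: pd.DataFrame
    mode: str                 # 'colored' or 'additive'
    n_sims: int
    seed: int
    meta: dict = field(default_factory=dict)


def successive_pairs(values_per_cell: dict, normalize: bool = True) -> PairData:
    """Form (v_i, v_{i+1}) pairs of consecutive cycle values within cells.

    ``values_per_cell`` maps cell id to an ordered array of accepted cycle
    values; cells with fewer than two values contribute nothing.  With
    ``normalize`` the pooled data-set mean divides all values (recorded in
    ``normalizer``).
    """
    arrays = [np.asarray(v, float) for v in values_per_cell.values()
              if len(v)]
    pooled = np.concatenate(arrays) if arrays else np.array([])
    norm = float(pooled.mean()) if (normalize and pooled.size) else 1.0
    rows = []
    for cid, vals in values_per_cell.items():
        vals = np.asarray(vals, float) / norm
        for i in range(len(vals) - 1):
            rows.append((cid, i, vals[i], vals[i + 1]))
    table = pd.DataFrame(rows, columns=["cell_id", "cycle_index", "v1", "v2"])
    return PairData(table, norm)


def randomized_control(pairs: PairData, seed=None) -> PairData:
    """Control pairs drawn at random from the pooled value list.

    Destroys within-cell ordering while preserving the marginal
    distribution and the pair count; seeded for reproducibility.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    rng = np.random.default_rng(seed)
    pool = np.concatenate([pairs.v1, pairs.v2[-1:]])  # all cycle values
    v1 = rng.choice(pool, size=len(pairs), replace=True)
    v2 = rng.choice(pool, size=len(pairs), replace=True)
    table = pairs.table.copy()
    table["v1"] = v1
    table["v2"] = v2
    return PairData(table, pairs.normalizer)


def correlation_summary(pairs: PairData, method: str = "pearson",
                        bins: int = 20) -> dict:
    """Correlation of (v_i, v_{i+1}) plus the D_i and v_i* histograms.

    Returns a dict with ``r`` (NaN-flagged when a margin is degenerate),
    ``n``, and fixed-binning histograms of the pair averages and identity
    distances.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    v1, v2 = pairs.v1, pairs.v2
    if np.std(v1) == 0 or np.std(v2) == 0:
        r = 1.0 if np.allclose(v1, v2) else float("nan")
    elif method == "pearson":
        r = float(sps.pearsonr(v1, v2).statistic)
    elif method == "spearman":
        r = float(sps.spearmanr(v1, v2).statistic)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    vs = pairs.v_star
    di = pairs.distance_to_identity
    h_vs = np.histogram(vs, bins=bins, range=(0.0, max(2.0, vs.max())))
    h_di = np.histogram(di, bins=bins, range=(0.0, max(1.0, di.max())))
    return {"r": r, "n": len(pairs), "v_star_hist": h_vs, "d_hist": h_di}


def period_amplitude_correlation(periods: np.ndarray, amplitudes: np.ndarray,
                                 n_permutations: int = 999, seed=None) -> dict:
    """Per-cycle (T_i, A_i) correlation with a permutation p-value."""
    T = np.asarray(periods, float)
    A = np.asarray(amplitudes, float)
    if T.size != A.size or T.size < 3:
        raise ValueError("need >= 3 matched (period, amplitude) cycles")
    if np.std(T) == 0 or np.std(A) == 0:
        return {"r": float("nan"), "p": float("nan"), "n": T.size}
    r = float(sps.pearsonr(T, A).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        rp = float(sps.pearsonr(T, rng.permutation(A)).statistic)
        if abs(rp) >= abs(r):
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return {"r": r, "p": p, "n": T.size}


def ks_compare(sample_a, sample_b, min_n: int = 5) -> dict:
    """Two-sample Kolmogorov-Smirnov comparison of quality-factor samples."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    flagged = a.size < min_n or b.size < min_n
    if a.size < 2 or b.size < 2:
        raise ValueError("samples too small for a KS comparison")
    res = sps.ks_2samp(a, b, method="asymp")
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "n_a": a.size, "n_b": b.size, "small_sample": flagged}


# ---------------------------------------------------------------------------
# cohort pipeline helpers and sweeps

def analyze_cohort(series_list: list[TimeSeries],
                   preset: PeakParams = DEFAULT_PRESET,
                   cohort_floor: bool = True) -> list:
    """Run the peak pipeline on every trace of a cohort.

    With ``cohort_floor`` the absolute peak-size floor (0.1 x cohort median
    dynamic range) supplements each trace's relative threshold, mirroring
    how data sets are assembled from rhythmic cells only.
    """
    floor = cohort_prominence_floor(series_list, preset.smooth_window) \
        if cohort_floor else 0.0
    return [analyze_trace(s, preset, min_prominence_abs=floor)
            for s in series_list]


def cohort_cycles(cycles_list) -> pd.DataFrame:
    """Tidy per-cycle table (cell, period, accepted, amplitude) for a cohort."""
    rows = []
    for i, cs in enumerate(cycles_list):
        for j, (T, acc) in enumerate(zip(cs.periods, cs.accepted)):
            # amplitude of the cycle: the mean of its two bounding peaks'
            amp = 0.5 * (cs.amplitudes[j] + cs.amplitudes[j + 1]) \
                if cs.amplitudes.size > j + 1 else float("nan")
            rows.append((i, j, float(T), bool(acc), float(amp)))
    return pd.DataFrame(rows, columns=["cell", "cycle", "period",
                                       "accepted", "amplitude"])


def _simulate_traces(params: SLParams, n_sims: int, seed: int,
                     dt_sample: float = 2.0) -> list[TimeSeries]:
    trajs = simulate_ensemble(params, n_sims, seed=seed)
    return [render_trace(tr, dt_sample) for tr in trajs]


def sweep_colored_noise(sigma_mu2_grid, tau_mu_grid, base: SLParams,
                        n_sims: int = 100, seed: int = 0,
                        dt_sample: float = 2.0) -> SweepResult:
    """Median oscillating-time fraction over the (sigma_mu2, tau_mu) plane.

    For each grid point, ``n_sims`` cells are simulated, the peak pipeline
    (with cohort floor) is run, and the median over cells of the
    oscillating-time fraction — peak count times the data-set median period
    over the recording length, capped at 1 — is recorded.
    """
    rows = []
    point = 0
    for s2 in sigma_mu2_grid:
        for tau in tau_mu_grid:
            params = base.with_(sigma_mu2=float(s2), tau_mu=float(tau))
            traces = _simulate_traces(params, n_sims, seed + 7919 * point,
                                      dt_sample)
            cycles = analyze_cohort(traces)
            pooled = np.concatenate([c.accepted_periods for c in cycles]) \
                if cycles else np.array([])
            med_T = float(np.median(pooled)) if pooled.size else float("nan")
            fracs = [classify_persistence(c, dataset_median_period=med_T)[1]
                     for c in cycles]
            rows.append((float(s2), float(tau), float(np.median(fracs)),
                         med_T, len(pooled)))
            point += 1
    table = pd.DataFrame(rows, columns=["sigma_mu2", "tau_mu",
                                        "oscillating_fraction",
                                        "median_period", "n_cycles"])
    return SweepResult(table, "colored", n_sims, seed)


def sweep_additive_noise(sigma_z2_list, base: SLParams, n_sims: int = 1000,
                         seed: int = 0, reference_q=None,
                         window_cycles: float = 6.5,
                         dt_sample: float = 2.0) -> SweepResult:
    """Median quality factor (68% CI, KS p vs a reference) along sigma_z2.

    ``base`` should have ``sigma_mu2 = 0`` so that additive noise is the
    only stochastic influence; each grid point simulates ``n_sims`` cells
    and runs the full wavelet-phase Q pipeline.
    """
    rows = []
    q_samples = {}
    for k, s2 in enumerate(sigma_z2_list):
        params = base.with_(sigma_z2=float(s2))
        traces = _simulate_traces(params, n_sims, seed + 104729 * k, dt_sample)
        qs = np.array([quality_factor(t, window_cycles=window_cycles).Q
                       for t in traces])
        qs = qs[np.isfinite(qs)]
        lo, med, hi = np.percentile(qs, [16, 50, 84])
        p = float("nan")
        if reference_q is not None:
            p = ks_compare(qs, reference_q)["p"]
        rows.append((float(s2), med, lo, hi, p, qs.size))
        q_samples[float(s2)] = qs
    table = pd.DataFrame(rows, columns=["sigma_z2", "q_median", "q_lo68",
                                        "q_hi68", "ks_p", "n"])
    return SweepResult(table, "additive", n_sims, seed,
                       meta={"q_samples": q_samples})
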