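"""Wavelet phase extraction and the quality factor Q = t_c / T.

Precision of an oscillator is quantified by how many cycles it completes
before losing phase memory.  The pipeline is:

1. :func:`extract_phase` — continuous wavelet transform (complex Morlet)
   over scales spanning a period band; the phase is read along the
   maximum-power ridge, and samples with ridge power below a noise-floor
   threshold are masked invalid.
2. :func:`phase_autocorrelation` — normalised autocorrelation of
   ``cos(theta)`` over the valid samples (per-lag unbiased normalisation).
3. :func:`fit_acf` — nonlinear least-squares fit of the damped cosine
   ``exp(-tau/t_c) cos(2 pi tau / T)``; the correlation time ``t_c`` is
   capped at 10x the window length when the decay is unresolvable.
4. :func:`quality_factor` — applies 1-3 to windows of a fixed number of
   cycles (default 6.5) tiled over the trace and reports the median
   ``Q = t_c / T``.  Fixed-length windows make Q comparable across datasets
   with different recording lengths.

Finite 6.5-cycle windows make the naive per-window fit biased: the free
period absorbs each window's mean frequency offset (for diffusing phase this
removes the ``tau^2/L`` part of the phase-increment variance), and the
wavelet ridge low-passes the phase over the Morlet envelope, hiding
short-lag diffusion.  :func:`fit_acf` therefore fits
``exp(-g(tau)/t_c) cos(2 pi tau/T)`` with the analytically corrected
diffusion time ``g(tau) = max(h(tau; sigma_t) - tau^2/L, 0)``, and
:func:`quality_factor` removes the remaining (approximately uniform)
finite-window bias by inverting a calibration curve measured on the
phase-diffusion reference process — the process with
``d theta = omega dt + sqrt(D) dW`` whose exact quality factor is
``Q = omega / (pi D)``.  The uncorrected estimator (``bias_correction=False``)
shows the well-known decrease of apparent Q with window length; the
corrected one is approximately window-independent.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pywt
from scipy.optimize import curve_fit
from scipy.special import erf

from .timeseries import TimeSeries

__all__ = [
    "PhaseSeries",
    "QualityResult",
    "ACFFit",
    "extract_phase",
    "phase_autocorrelation",
    "fit_acf",
    "quality_factor",
]

#: default complex Morlet; bandwidth 1.0 balances phase-smoothing bias
#: against noise rejection, centre frequency 1 maps scale to period directly
DEFAULT_WAVELET = "cmor1.0-1.0"
DEFAULT_BAND = (40.0, 140.0)
DEFAULT_N_SCALES = 30
#: ridge power must exceed this multiple of the white-noise ridge expectation
MASK_SNR = 2.0


@dataclass
class PhaseSeries:
    """Instantaneous phase of a trace read along the wavelet ridge."""

    t: np.ndarray
    theta: np.ndarray          # rad, wrapped to [-pi, pi]
    mask: np.ndarray           # True where the phase is trustworthy
    ridge_period: np.ndarray   # min, period of the max-power scale
    ridge_power: np.ndarray    # rectified |W|^2 / scale at the ridge
    dt_sample: float

    @property
    def cos_theta(self) -> np.ndarray:
        return np.cos(self.theta)

    @property
    def valid_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class ACFFit:
    """Result of a damped-cosine fit to a phase autocorrelation."""

    T: float
    t_c: float
    capped: bool
    converged: bool
    residual: float = float("nan")


@dataclass
class QualityResult:
    """Quality factor of one trace.

    ``Q = t_c / T`` counts the cycles over which phase correlations persist.
    ``capped`` marks decays too slow to resolve in the window;
    ``insufficient_length`` marks traces shorter than one window.
    """

    T: float
    t_c: float
    Q: float
    window_cycles: float
    n_windows: int = 0
    capped: bool = False
    converged: bool = False
    insufficient_length: bool = False
    raw_Q: float = float("nan")
    meta: dict = field(default_factory=dict)


def _morlet_bandwidth(wavelet: str) -> float:
    """Bandwidth parameter B of a 'cmorB-C' name."""
    body = wavelet.replace("cmor", "")
    return float(body.split("-")[0])


@lru_cache(maxsize=16)
def _white_ridge_power(wavelet: str, n_scales: int, band_ratio: float,
                       spc: int = 39) -> float:
    """Mean rectified ridge power of unit-variance white noise.

    Monte-Carlo constant (fixed seed) used by the validity mask: a sample's
    ridge power must exceed ``MASK_SNR`` times this expectation scaled by the
    trace variance to count as a genuine oscillation.
    """
    rng = np.random.default_rng(1234567)
    n = 4096
    v = rng.normal(size=n)
    fc = pywt.central_frequency(wavelet)
    periods = np.geomspace(spc, spc * band_ratio, n_scales)  # in samples
    scales = fc * periods
    W, _ = pywt.cwt(v, scales, wavelet)
    P = np.abs(W) ** 2 / scales[:, None]
    interior = slice(n // 8, -n // 8)
    return float(P.max(axis=0)[interior].mean())


def extract_phase(series: TimeSeries,
                  period_band: tuple[float, float] = DEFAULT_BAND,
                  wavelet: str = DEFAULT_WAVELET,
                  n_scales: int = DEFAULT_N_SCALES) -> PhaseSeries:
    """Extract the instantaneous phase along the wavelet ridge.

    Scales are log-spaced so that wavelet periods span ``period_band``
    (minutes).  At each time the scale with maximum rectified power
    ``|W|^2 / scale`` defines the ridge; the phase is the argument of the
    transform there.  The validity mask is False where the ridge power does
    not exceed ``MASK_SNR`` times the power expected from white noise of the
    trace's variance — flat or noise-dominated stretches carry no phase.
    """
    lo, hi = period_band
    dt = series.dt_sample
    if lo <= 2 * dt:
        raise ValueError("lower period band edge must exceed twice the sampling interval")
    if hi <= lo:
        raise ValueError("period band must be increasing")
    if series.duration < 2 * hi:
        raise ValueError("trace shorter than twice the maximal period in the band")
    fc = pywt.central_frequency(wavelet)
    periods = np.geomspace(lo, hi, n_scales)
    scales = fc * periods / dt
    v = series.v - series.v.mean()
    W, _ = pywt.cwt(v, scales, wavelet, sampling_period=dt)
    P = np.abs(W) ** 2 / scales[:, None]
    ridge = np.argmax(P, axis=0)
    cols = np.arange(len(series))
    ridge_power = P[ridge, cols]
    theta = np.angle(W[ridge, cols])
    var = float(np.var(v))
    noise_floor = _white_ridge_power(wavelet, n_scales, hi / lo) * var
    mask = ridge_power > MASK_SNR * noise_floor
    return PhaseSeries(series.t, theta, mask, periods[ridge], ridge_power, dt)


def phase_autocorrelation(phase: PhaseSeries, max_lag: int | None = None,
                          start: int = 0, stop: int | None = None,
                          min_pairs: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Normalised autocorrelation of ``cos(theta)`` over valid samples.

    Uses per-lag unbiased normalisation (sums of valid products divided by
    the number of valid pairs), then scales so the zero-lag value is 1.

    Returns
    -------
    lags : ndarray
        Lag times in minutes.
    acf : ndarray
        Autocorrelation values (NaN where fewer than ``min_pairs`` valid
        pairs exist).
    """
    seg = slice(start, stop)
    m = phase.mask[seg].astype(float)
    if m.sum() < 2 * np.nanmedian(phase.ridge_period) / phase.dt_sample:
        raise ValueError("fewer than two cycles of valid phase")
    c = np.cos(phase.theta[seg])
    mean = (c * m).sum() / m.sum()
    cm = (c - mean) * m
    n = cm.size
    if max_lag is None:
        max_lag = n - 1
    max_lag = min(max_lag, n - 1)
    num = np.correlate(cm, cm, "full")[n - 1:n + max_lag]
    cnt = np.correlate(m, m, "full")[n - 1:n + max_lag]
    with np.errstate(invalid="ignore", divide="ignore"):
        acf = np.where(cnt >= min_pairs, num / np.maximum(cnt, 1), np.nan)
    acf = acf / acf[0]
    lags = np.arange(max_lag + 1) * phase.dt_sample
    return lags, acf


def _smoothed_diffusion_time(tau: np.ndarray, sigma_t: float) -> np.ndarray:
    """Effective diffusion time of a Wiener phase smoothed by a Gaussian.

    For phase smoothed with a Gaussian kernel of width ``sigma_t`` the
    variance of an increment at lag tau is ``D * h(tau)`` with
    ``h(tau) = E[(tau - |Z|)^+]``, ``Z ~ N(0, 2 sigma_t^2)``.
    """
    tau = np.asarray(tau, dtype=float)
    if sigma_t <= 0:
        return tau
    s = math.sqrt(2.0) * sigma_t
    z = tau / s
    return tau * erf(z / math.sqrt(2)) - s * math.sqrt(2 / math.pi) * (
        1.0 - np.exp(-z * z / 2.0))


def fit_acf(lags: np.ndarray, acf: np.ndarray, T_guess: float | None = None,
            cap: float | None = None, window_length: float | None = None,
            smoothing_width: float = 0.0) -> ACFFit:
    """Fit ``exp(-g(tau)/t_c) cos(2 pi tau / T)`` to an autocorrelation.

    With no window context (``window_length=None``, ``smoothing_width=0``)
    ``g(tau) = tau`` and this is the plain damped-cosine model.  When the
    ACF comes from a single finite window of wavelet-ridge phase, passing
    the window length ``L`` and the ridge smoothing width subtracts the
    detrending loss ``tau^2/L`` and corrects the smoothing, so that ``t_c``
    estimates the true phase correlation time.

    Non-convergence returns a flagged result rather than raising.  ``t_c``
    is capped at ``cap`` (default ``10 * window_length`` when a window is
    given, else ``10 * max lag``) with the ``capped`` flag set.
    """
    lags = np.asarray(lags, dtype=float)
    acf = np.asarray(acf, dtype=float)
    ok = np.isfinite(acf)
    lags, acf = lags[ok], acf[ok]
    if lags.size < 8:
        return ACFFit(float("nan"), float("nan"), False, False)
    if cap is None:
        cap = 10.0 * (window_length if window_length else lags[-1])
    if T_guess is None:
        # first zero crossing of a damped cosine sits near T/4
        neg = np.nonzero(acf < 0)[0]
        T_guess = 4.0 * lags[neg[0]] if neg.size else 2.0 * lags[-1]
    g = _smoothed_diffusion_time(lags, smoothing_width)
    if window_length:
        g = np.maximum(g - lags ** 2 / window_length, 0.0)
    t_c0 = 2.0 * T_guess

    # the free prefactor A absorbs lag-independent decorrelation (white
    # measurement noise in the phase), which would otherwise bias t_c low
    def model(tau, T, t_c, A):
        return A * np.exp(-g / t_c) * np.cos(2 * np.pi * tau / T)

    try:
        (T, t_c, _A), _ = curve_fit(
            model, lags, acf, p0=[T_guess, t_c0, 1.0],
            bounds=([0.3 * T_guess, 1.0, 0.2], [3.0 * T_guess, 100.0 * cap, 1.1]),
            maxfev=5000)
    except (RuntimeError, ValueError):
        return ACFFit(float("nan"), float("nan"), False, False)
    resid = float(np.sqrt(np.mean((model(lags, T, t_c, _A) - acf) ** 2)))
    capped = t_c >= cap
    return ACFFit(float(T), float(min(t_c, cap)), capped, True, resid)


# ---------------------------------------------------------------------------
# finite-window bias calibration on the phase-diffusion reference process

_CAL_X = np.array([0.08, 0.15, 0.3, 0.5, 0.8, 1.2, 1.8, 2.7, 4.0, 6.0, 9.6])  # true t_c / L
_CAL_SEED = 20180331
_CAL_REPS = 200
_CAL_T = 78.0
_CAL_DT = 2.0


def _raw_window_q(series: TimeSeries, window_cycles: float,
                  max_lag_cycles: float, period_band, wavelet,
                  n_scales, min_lag_cycles: float = 0.0) -> QualityResult:
    """Uncorrected windowed Q estimate (steps 1-3 of the pipeline)."""
    try:
        ph = extract_phase(series, period_band, wavelet, n_scales)
    except ValueError:
        return QualityResult(*[float("nan")] * 3, window_cycles,
                             insufficient_length=True)
    valid = np.nonzero(ph.mask)[0]
    if valid.size < 0.25 * len(ph.t):
        return QualityResult(*[float("nan")] * 3, window_cycles,
                             insufficient_length=True)
    T_est = float(np.median(ph.ridge_period[ph.mask]))
    dt = ph.dt_sample
    wlen = int(round(window_cycles * T_est / dt))
    lo, hi = valid[0], valid[-1] + 1
    if hi - lo < wlen:
        return QualityResult(*[float("nan")] * 3, window_cycles,
                             insufficient_length=True)
    L = wlen * dt
    cap = 10.0 * L
    sigma_t = math.sqrt(_morlet_bandwidth(wavelet) / 2.0) * T_est
    max_lag = int(round(min(max_lag_cycles * T_est, 0.9 * L) / dt))
    fits = []
    for k in range((hi - lo) // wlen):
        a, b = lo + k * wlen, lo + (k + 1) * wlen
        if ph.mask[a:b].mean() < 0.6:
            continue
        try:
            lg, ac = phase_autocorrelation(ph, max_lag=max_lag, start=a, stop=b)
        except ValueError:
            continue
        keep = lg >= min_lag_cycles * T_est
        fit = fit_acf(lg[keep], ac[keep], T_guess=T_est, cap=cap,
                      window_length=L, smoothing_width=sigma_t)
        if fit.converged:
            fits.append(fit)
    if not fits:
        return QualityResult(float("nan"), float("nan"), float("nan"),
                             window_cycles, n_windows=0)
    T = float(np.median([f.T for f in fits]))
    t_c = float(np.median([f.t_c for f in fits]))
    capped = t_c >= 0.999 * cap
    return QualityResult(T, t_c, t_c / T, window_cycles,
                         n_windows=len(fits), capped=capped, converged=True)


@lru_cache(maxsize=16)
def _window_bias_curve(window_cycles: float, n_samples: int,
                       max_lag_cycles: float, wavelet: str,
                       n_scales: int) -> tuple:
    """Median raw ``t_c/L`` versus true ``t_c/L`` on phase-diffusion traces.

    Calibration traces replicate the measurement setting (same number of
    samples, sampling interval and window tiling as the analysed trace) and
    run the identical raw pipeline.  Computed once per configuration with a
    fixed internal seed; part of the estimator definition, not of any
    experiment's randomness.
    """
    rng = np.random.default_rng(_CAL_SEED)
    omega = 2 * math.pi / _CAL_T
    L = window_cycles * _CAL_T
    n_t = n_samples
    band = (DEFAULT_BAND[0] / 78.0 * _CAL_T, DEFAULT_BAND[1] / 78.0 * _CAL_T)
    raw = []
    for x in _CAL_X:
        t_c = x * L
        D = 2.0 / t_c
        qs = []
        for _ in range(_CAL_REPS):
            dth = omega * _CAL_DT + math.sqrt(D * _CAL_DT) * rng.normal(size=n_t - 1)
            th = rng.uniform(-math.pi, math.pi) + np.concatenate([[0.0], np.cumsum(dth)])
            tr = TimeSeries.from_values(np.cos(th), _CAL_DT)
            res = _raw_window_q(tr, window_cycles, max_lag_cycles, band,
                                wavelet, n_scales)
            if res.converged:
                qs.append(res.t_c / L)
        raw.append(np.median(qs) if qs else np.nan)
    # smooth the Monte-Carlo jitter in log-log, then enforce monotonicity
    lr = np.log(np.asarray(raw))
    inner = np.convolve(lr, [0.25, 0.5, 0.25], mode="valid")
    lr[1:-1] = inner
    raw = np.maximum.accumulate(np.exp(lr))
    return tuple(_CAL_X), tuple(raw)


def _debias(x_raw: float, window_cycles: float, n_samples: int,
            max_lag_cycles: float, wavelet: str,
            n_scales: int) -> tuple[float, bool]:
    """Invert the calibration curve; returns (true t_c/L estimate, capped)."""
    xt, xr = _window_bias_curve(window_cycles, n_samples, max_lag_cycles,
                                wavelet, n_scales)
    xt, xr = np.asarray(xt), np.asarray(xr)
    if x_raw >= xr[-1]:
        return float(xt[-1]), True
    if x_raw <= xr[0]:
        # extrapolate proportionally below the calibrated range
        return float(x_raw * xt[0] / xr[0]), False
    lx = np.interp(math.log(x_raw), np.log(xr), np.log(xt))
    return float(math.exp(lx)), False


def quality_factor(series: TimeSeries, window_cycles: float = 6.5,
                   period_band: tuple[float, float] = DEFAULT_BAND,
                   wavelet: str = DEFAULT_WAVELET,
                   n_scales: int = DEFAULT_N_SCALES,
                   max_lag_cycles: float = 3.0,
                   bias_correction: bool = True) -> QualityResult:
    """Quality factor of a trace from fixed-length phase windows.

    The trace's phase is extracted once; windows of
    ``window_cycles x (median ridge period)`` tile the valid stretch, each
    window's ``cos(theta)`` autocorrelation is fitted, and the median fitted
    ``t_c`` and ``T`` give the raw ``Q``.  With ``bias_correction=True``
    (default) the finite-window bias is removed via the phase-diffusion
    calibration curve, making the estimate approximately window-length
    independent and directly comparable to the closed form
    ``Q = omega/(pi D)``.  With ``bias_correction=False`` the raw,
    window-length-dependent estimate is returned, matching how fixed-window
    measurements are usually reported.
    """
    res = _raw_window_q(series, window_cycles, max_lag_cycles, period_band,
                        wavelet, n_scales)
    if not res.converged:
        return res
    res.raw_Q = res.Q
    if bias_correction:
        x_raw = res.t_c / (window_cycles * res.T)
        x_true, capped = _debias(x_raw, window_cycles, len(series),
                                 max_lag_cycles, wavelet, n_scales)
        res.t_c = x_true * window_cycles * res.T
        res.Q = res.t_c / res.T
        res.capped = res.capped or capped
    return res
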