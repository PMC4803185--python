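"""Ground-truth fixtures emulating single-cell segmentation-clock recordings.

Every generator returns traces *with the answer attached*, so each stage of
the pipeline can be tested against a known truth without any external data:

* :func:`make_sinusoid` — pure cosine with exact peak times;
* :func:`make_phase_diffusion` — ``cos(theta)`` with a diffusing phase,
  whose ensemble autocorrelation ``0.5 exp(-D tau/2) cos(omega tau)`` gives
  the closed-form quality factor ``Q = omega / (pi D)``;
* :func:`make_flatline` — constant plus optional noise (no peaks);
* :func:`make_cohort` — a Stuart-Landau-simulated population rendered as
  fluorescence-like intensities with slow baseline drift and a recorded
  local-background channel, mimicking a low-density culture recorded for
  600 min at 2-min intervals (period ~ 78 min, slow amplitude modulation
  with tau_mu ~ 476 min and sigma_mu2 ~ 6.84, additive noise
  sigma_z2 ~ 0.486);
* :func:`make_stuttering` — cohort variant with the mean bifurcation
  parameter near 0, so cells repeatedly start and stop oscillating.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulator import SLParams, render_trace, simulate_ensemble
from .timeseries import TimeSeries

__all__ = [
    "CohortSpec",
    "make_sinusoid",
    "make_phase_diffusion",
    "make_flatline",
    "make_cohort",
    "make_stuttering",
]

#: study-condition defaults for the emulated low-density data set
PAPER_COHORT = dict(mu=1.0, b=1.0, omega=2 * math.pi / 78.0, q=0.0,
                    sigma_z2=0.486, sigma_mu2=6.84, tau_mu=476.0)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of an emulated low-density cohort."""

    n_cells: int = 147
    duration: float = 600.0
    dt_sample: float = 2.0
    params: SLParams = SLParams(**PAPER_COHORT)
    intensity_scale: float = 100.0
    baseline_amplitude_frac: float = 0.2
    background_offset: float = 50.0
    seed: int = 0


def make_sinusoid(period: float = 78.0, amplitude: float = 1.0,
                  duration: float = 600.0, dt_sample: float = 2.0,
                  phi0: float = 0.0, offset: float = 0.0,
                  noise_sd: float = 0.0, seed=None
                  ) -> tuple[TimeSeries, np.ndarray]:
    """Cosine trace plus the exact times of its maxima.

    ``v(t) = amplitude * cos(2 pi t / period + phi0) + offset`` (+ optional
    Gaussian noise).  Returns the trace and the analytic peak times within
    the recording; a zero amplitude gives a flatline with no peaks.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if amplitude < 0 or noise_sd < 0:
        raise ValueError("amplitude and noise_sd must be non-negative")
    n = int(round(duration / dt_sample)) + 1
    t = dt_sample * np.arange(n)
    v = amplitude * np.cos(2 * np.pi * t / period + phi0) + offset
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    if amplitude == 0:
        truth = np.array([])
    else:
        # maxima at (2 pi k - phi0) / omega
        k0 = math.ceil(phi0 / (2 * math.pi))
        k1 = math.floor((2 * math.pi * t[-1] / period + phi0) / (2 * math.pi))
        truth = np.array([(2 * math.pi * k - phi0) * period / (2 * math.pi)
                          for k in range(k0, k1 + 1)])
        truth = truth[(truth >= 0) & (truth <= t[-1])]
    return TimeSeries(t, v, {"kind": "sinusoid", "period": period}), truth


def make_phase_diffusion(D: float, omega: float = 2 * math.pi / 78.0,
                         duration: float = 600.0, dt_sample: float = 2.0,
                         seed=None) -> TimeSeries:
    """Pure phase-diffusion trace ``cos(theta)``, ``d theta = omega dt + sqrt(D) dW``.

    The ensemble autocorrelation is ``0.5 exp(-D tau / 2) cos(omega tau)``,
    so the true correlation time is ``t_c = 2/D`` and the true quality
    factor ``Q = t_c / T = omega / (pi D)`` — the closed-form oracle for the
    precision pipeline.  ``D = 0`` gives a perfect sinusoid.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt_sample)) + 1
    dth = omega * dt_sample + math.sqrt(D * dt_sample) * rng.normal(size=n - 1)
    theta = rng.uniform(-math.pi, math.pi) + np.concatenate([[0.0], np.cumsum(dth)])
    return TimeSeries.from_values(np.cos(theta), dt_sample,
                                  meta={"kind": "phase_diffusion", "D": D,
                                        "omega": omega})


def make_flatline(level: float = 0.0, duration: float = 600.0,
                  dt_sample: float = 2.0, noise_sd: float = 0.0,
                  seed=None) -> TimeSeries:
    """Constant trace, optionally with white measurement noise."""
    n = int(round(duration / dt_sample)) + 1
    v = np.full(n, float(level))
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return TimeSeries.from_values(v, dt_sample, meta={"kind": "flatline"})


def _slow_baseline(n: int, dt: float, amplitude: float, rng) -> np.ndarray:
    """Smooth slow drift: cubic interpolation through sparse random knots."""
    from scipy.interpolate import CubicSpline

    n_knots = max(4, int(round(n * dt / 300.0)) + 2)
    tk = np.linspace(0, (n - 1) * dt, n_knots)
    yk = rng.uniform(-1.0, 1.0, n_knots)
    t = dt * np.arange(n)
    drift = CubicSpline(tk, yk)(t)
    span = drift.max() - drift.min()
    if span > 0:
        drift = drift / span * amplitude
    return drift - drift.min()


def make_cohort(spec: CohortSpec = CohortSpec()) -> dict:
    """Emulated low-density cohort in the raw/background/subtracted layout.

    Each Stuart-Landau trajectory is rendered as a non-negative intensity,
    a slow spline baseline (amplitude <= ``baseline_amplitude_frac`` of the
    signal range) plus a constant offset is added to emulate local
    background, and the background channel is recorded alongside — so the
    background-subtraction step of the measurement pipeline has real work to
    do.  Returns a dict with keys ``raw``, ``background``, ``subtracted``
    (lists of :class:`TimeSeries`), and ``trajectories`` (ground truth).
    """
    if spec.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    params = spec.params.with_(duration=spec.duration, seed=spec.seed)
    trajs = simulate_ensemble(params, spec.n_cells, seed=spec.seed)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xBA5E]))
    raws, bgs, subs = [], [], []
    for i, tr in enumerate(trajs):
        clean = render_trace(tr, spec.dt_sample,
                             intensity_scale=spec.intensity_scale)
        sig_range = clean.v.max() - clean.v.min()
        drift = _slow_baseline(len(clean), spec.dt_sample,
                               spec.baseline_amplitude_frac * sig_range, rng)
        background = drift + spec.background_offset
        raw = clean.copy_with(clean.v + background,
                              meta={"cell_id": f"cell{i:03d}"})
        bg = clean.copy_with(background, meta={"cell_id": f"cell{i:03d}"})
        sub = clean.copy_with(raw.v - bg.v, meta={"cell_id": f"cell{i:03d}"})
        raws.append(raw)
        bgs.append(bg)
        subs.append(sub)
    return {"raw": raws, "background": bgs, "subtracted": subs,
            "trajectories": trajs, "spec": spec}


def make_stuttering(n_cells: int = 20, seed: int = 0,
                    duration: float = 600.0) -> dict:
    """Cohort whose mean bifurcation parameter sits at the Hopf point.

    With ``mu = 0`` the colored noise drives ``mu(t)`` across the
    bifurcation repeatedly, reproducing start/stop and stuttering
    phenotypes.
    """
    params = SLParams(**{**PAPER_COHORT, "mu": 0.0})
    spec = CohortSpec(n_cells=n_cells, duration=duration, params=params,
                      seed=seed)
    out = make_cohort(spec)
    out["spec"] = spec
    return out
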