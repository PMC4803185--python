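"""Stochastic Stuart-Landau oscillator near a supercritical Hopf bifurcation.

The model describes a single segmentation-clock cell as a generic limit-cycle
oscillator.  In complex form, with ``z = x + i y``,

    dz/dt = (mu(t) + i omega) z - (b + i q) |z|^2 z + xi(t)

* ``mu(t) = mu + xi_mu(t)`` is the bifurcation parameter: for ``mu > 0`` a
  stable limit cycle of radius ``r* = sqrt(mu/b)`` exists, for ``mu < 0`` the
  origin is a stable fixed point and oscillations die out.  ``xi_mu`` is slow
  colored (Ornstein-Uhlenbeck) noise with stationary variance ``sigma_mu2``
  and correlation time ``tau_mu``, which drives the cell in and out of the
  oscillatory state on the timescale of several cycles.
* ``omega`` is the autonomous angular frequency and ``q`` the
  non-isochronicity: the phase obeys ``dtheta/dt = omega - q r^2``, so for
  ``q != 0`` amplitude excursions modulate the instantaneous frequency.
* ``xi(t)`` is additive white noise applied independently to both Cartesian
  variables.  Its strength is parameterised by ``sigma_z2``, the noise
  variance accumulated over one autonomous period ``T0 = 2 pi / omega``
  (units au^2 per cycle); the corresponding spectral intensity is
  ``sigma_z2 / T0`` au^2/min.  On the limit cycle this produces phase
  diffusion with coefficient ``D = sigma_z2 / (T0 r*^2)`` and therefore an
  intrinsic quality factor ``Q = omega / (pi D) = 2 r*^2 / sigma_z2``.

Integration is Euler-Maruyama for the oscillator variables with an exact
exponential update for the OU sub-process.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "SLParams",
    "SLTrajectory",
    "ou_process",
    "simulate_sl",
    "simulate_ensemble",
    "render_trace",
    "limit_cycle_radius",
    "limit_cycle_period",
]


@dataclass(frozen=True)
class SLParams:
    """Parameters of the noisy Stuart-Landau oscillator.

    Attributes
    ----------
    mu : float
        Mean bifurcation parameter (1/min).  Positive values place the cell
        above the Hopf bifurcation.
    b : float
        Amplitude saturation coefficient (1/(min au^2)); must be positive.
    omega : float
        Autonomous angular frequency (rad/min).
    q : float
        Non-isochronicity coefficient (rad/(min au^2)); couples amplitude
        to instantaneous frequency via ``dtheta/dt = omega - q r^2``.
    sigma_z2 : float
        Variance of the additive white noise accumulated over one autonomous
        period, per oscillator variable (au^2/cycle).
    sigma_mu2 : float
        Stationary variance of the colored noise in ``mu`` ((1/min)^2).
    tau_mu : float
        Correlation time of the colored noise (min).
    dt : float
        Integration step (min).
    duration : float
        Length of the recorded trajectory after burn-in (min).
    burn_in : float
        Initial stretch discarded so the observation window is stationary (min).
    seed : int
        Master RNG seed.
    """

    mu: float = 1.0
    b: float = 1.0
    omega: float = 2 * math.pi / 78.0
    q: float = 0.0
    sigma_z2: float = 0.0
    sigma_mu2: float = 0.0
    tau_mu: float = 476.0
    dt: float = 0.1
    duration: float = 600.0
    burn_in: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be positive")
        if self.tau_mu <= 0:
            raise ValueError("tau_mu must be positive")
        if self.sigma_z2 < 0 or self.sigma_mu2 < 0:
            raise ValueError("noise variances must be non-negative")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        # the integrator must resolve both the cycle and the colored noise
        limit = min(2 * math.pi / self.omega, self.tau_mu) / 50.0
        if self.dt > limit:
            raise ValueError(
                f"dt={self.dt} too coarse: must be <= min(period, tau_mu)/50 = {limit:.4g}"
            )

    @property
    def noise_intensity(self) -> float:
        """Spectral intensity of the additive noise (au^2/min) per variable."""
        return self.sigma_z2 * self.omega / (2 * math.pi)

    def with_(self, **kw) -> "SLParams":
        return replace(self, **kw)


@dataclass
class SLTrajectory:
    """Simulated state path of one oscillator.

    ``theta`` is wrapped to [-pi, pi] and flagged undefined (``phase_defined``
    False) wherever the amplitude is numerically zero — below the bifurcation
    the oscillator sits at a fixed point and has no phase.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    mu_t: np.ndarray
    params: SLParams
    meta: dict = field(default_factory=dict)

    @property
    def r(self) -> np.ndarray:
        """Amplitude r = sqrt(x^2 + y^2) (au)."""
        return np.hypot(self.x, self.y)

    @property
    def theta(self) -> np.ndarray:
        """Phase wrapped to [-pi, pi]; NaN where the amplitude vanishes."""
        th = np.arctan2(self.y, self.x)
        th[~self.phase_defined] = np.nan
        return th

    @property
    def phase_defined(self) -> np.ndarray:
        return np.hypot(self.x, self.y) > 1e-12

    def __len__(self) -> int:
        return self.t.size


def ou_process(tau: float, sigma2: float, dt: float, n: int,
               seed=None) -> np.ndarray:
    """Sample a stationary Ornstein-Uhlenbeck path.

    The OU process is the minimal stationary Gaussian process with an
    exponential autocorrelation ``sigma2 * exp(-lag/tau)``; it supplies the
    slow colored fluctuations of the bifurcation parameter.  The initial
    value is drawn from the stationary distribution N(0, sigma2) and the
    update is the exact transition
    ``xi(t+dt) = xi(t) e^(-dt/tau) + N(0, sigma2 (1 - e^(-2 dt/tau)))``.

    Parameters
    ----------
    tau : float
        Correlation time (min), > 0.
    sigma2 : float
        Stationary variance, >= 0.
    dt : float
        Sampling step (min), > 0.
    n : int
        Number of samples, >= 1.
    seed : int, Generator or SeedSequence, optional

    Returns
    -------
    ndarray of shape (n,)
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma2 == 0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    a = math.exp(-dt / tau)
    s = math.sqrt(sigma2 * (1 - a * a))
    innov = rng.normal(0.0, 1.0, n)
    innov[0] *= math.sqrt(sigma2) / s  # stationary start
    from scipy.signal import lfilter

    return lfilter([s], [1.0, -a], innov)


def _integrate_block(params: SLParams, n_cells: int,
                     child_seeds) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Euler-Maruyama integration of ``n_cells`` independent oscillators.

    Noise for each cell comes from its own counter-based substream so the
    trajectory of cell *i* is identical whether simulated alone or in a
    batch.  The time loop is vectorised across cells.
    """
    p = params
    n_steps = int(round((p.duration + p.burn_in) / p.dt))
    n_keep = int(round(p.duration / p.dt)) + 1
    k0 = n_steps - n_keep + 1

    gens = [np.random.Generator(np.random.Philox(s)) for s in child_seeds]
    # per-cell noise rows drawn up-front from the substreams
    z_noise = p.noise_intensity > 0
    mu_noise = p.sigma_mu2 > 0
    r0 = math.sqrt(p.mu / p.b) if p.mu > 0 else 0.1
    x = np.empty(n_cells)
    y = np.empty(n_cells)
    xi = np.zeros(n_cells)
    wx = wy = wmu = None
    if z_noise:
        wx = np.empty((n_cells, n_steps))
        wy = np.empty((n_cells, n_steps))
    if mu_noise:
        wmu = np.empty((n_cells, n_steps))
    for i, g in enumerate(gens):
        th0 = g.uniform(-math.pi, math.pi)
        x[i] = r0 * math.cos(th0)
        y[i] = r0 * math.sin(th0)
        if mu_noise:
            xi[i] = g.normal(0.0, math.sqrt(p.sigma_mu2))
            wmu[i] = g.normal(size=n_steps)
        if z_noise:
            wx[i] = g.normal(size=n_steps)
            wy[i] = g.normal(size=n_steps)

    a_ou = math.exp(-p.dt / p.tau_mu)
    s_ou = math.sqrt(p.sigma_mu2 * (1 - a_ou * a_ou))
    sn = math.sqrt(p.noise_intensity * p.dt)

    X = np.empty((n_cells, n_keep))
    Y = np.empty((n_cells, n_keep))
    MU = np.empty((n_cells, n_keep))
    errstate = np.errstate(over="ignore", invalid="ignore")
    errstate.__enter__()
    j = 0
    for i in range(n_steps + 1):
        if i >= k0:
            X[:, j] = x
            Y[:, j] = y
            MU[:, j] = p.mu + xi
            j += 1
        if i == n_steps:
            break
        m = p.mu + xi
        r2 = x * x + y * y
        dx = (m * x - p.omega * y - r2 * (p.b * x - p.q * y)) * p.dt
        dy = (m * y + p.omega * x - r2 * (p.q * x + p.b * y)) * p.dt
        if z_noise:
            dx += sn * wx[:, i]
            dy += sn * wy[:, i]
        x = x + dx
        y = y + dy
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
            errstate.__exit__(None, None, None)
            raise FloatingPointError(
                f"Stuart-Landau integration diverged at step {i} "
                f"(t = {i * p.dt - p.burn_in:.1f} min)"
            )
        if mu_noise:
            xi = a_ou * xi + s_ou * wmu[:, i]
    errstate.__exit__(None, None, None)
    t = np.arange(n_keep) * p.dt
    return t, X, Y, MU


def simulate_sl(params: SLParams) -> SLTrajectory:
    """Integrate one stochastic Stuart-Landau trajectory.

    The oscillator starts on the deterministic limit cycle at a random phase
    (or near the origin when ``mu <= 0``), the colored noise starts from its
    stationary distribution, and ``params.burn_in`` minutes are discarded so
    the recorded window is stationary.
    """
    child = np.random.SeedSequence(params.seed).spawn(1)
    t, X, Y, MU = _integrate_block(params, 1, child)
    return SLTrajectory(t, X[0], Y[0], MU[0], params,
                        meta={"seed": params.seed})


def simulate_ensemble(params: SLParams, n_cells: int,
                      seed: int | None = None) -> list[SLTrajectory]:
    """Simulate ``n_cells`` independent oscillators.

    Per-cell noise substreams are spawned deterministically from the master
    seed, so the output is reproducible bit-for-bit given
    ``(params, n_cells, seed)``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    master = params.seed if seed is None else seed
    children = np.random.SeedSequence(master).spawn(n_cells)
    t, X, Y, MU = _integrate_block(params, n_cells, children)
    return [
        SLTrajectory(t, X[i], Y[i], MU[i], params,
                     meta={"seed": master, "cell_index": i})
        for i in range(n_cells)
    ]


def render_trace(traj: SLTrajectory, dt_sample: float = 2.0,
                 intensity_scale: float = 1.0, offset: float | None = None,
                 baseline: np.ndarray | None = None) -> TimeSeries:
    """Render a trajectory as a fluorescence-like sampled trace.

    ``x(t)`` is subsampled at ``dt_sample`` (which must be an integer
    multiple of the integration step) and mapped affinely to a non-negative
    intensity ``v = intensity_scale * x + offset (+ baseline)``.  The default
    offset shifts the minimum to zero.  The affine mapping is recorded in
    ``meta`` so tests can invert it.

    Parameters
    ----------
    baseline : ndarray, optional
        Slow additive drift evaluated on the output grid (same length as the
        subsampled trace); emulates the low-frequency background trends that
        the measurement pipeline removes by local background subtraction.
    """
    ratio = dt_sample / traj.params.dt
    stride = int(round(ratio))
    if stride < 1 or abs(ratio - stride) > 1e-9:
        raise ValueError(
            f"dt_sample={dt_sample} must be a positive integer multiple of dt={traj.params.dt}"
        )
    t = traj.t[::stride]
    x = traj.x[::stride]
    if offset is None:
        offset = -intensity_scale * float(x.min())
    v = intensity_scale * x + offset
    if baseline is not None:
        baseline = np.asarray(baseline, dtype=float)
        if baseline.shape != v.shape:
            raise ValueError("baseline must match the subsampled grid")
        v = v + baseline
    meta = dict(traj.meta)
    meta.update({"intensity_scale": intensity_scale, "offset": offset,
                 "dt_sample": dt_sample, "has_baseline": baseline is not None})
    return TimeSeries(t, v, meta)


def limit_cycle_radius(params: SLParams) -> float:
    """Deterministic limit-cycle radius ``sqrt(mu/b)`` (au); 0 below the bifurcation."""
    return math.sqrt(params.mu / params.b) if params.mu > 0 else 0.0


def limit_cycle_period(params: SLParams) -> float:
    """Deterministic period ``2 pi / (omega - q mu / b)`` on the limit cycle (min)."""
    w_eff = params.omega - params.q * params.mu / params.b
    if w_eff <= 0:
        raise ValueError("effective frequency is non-positive for these parameters")
    return 2 * math.pi / w_eff
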