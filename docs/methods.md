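# Methods

## Model

The oscillator is the Stuart–Landau normal form of a supercritical Hopf
bifurcation, written for z = x + iy as

    dz/dt = (mu(t) + i omega) z − (b + i q) |z|^2 z + xi(t).

Above the bifurcation (mu > 0) the deterministic system settles on a limit
cycle of radius r* = sqrt(mu/b); below it, the origin is a stable fixed
point and the amplitude decays.  The phase obeys theta' = omega − q r^2, so
positive non-isochronicity q slows large-amplitude cycles.  The sign
convention is fixed by the compensation behaviour: with q = +0.005 the
autonomous frequency must be raised to omega = 2·pi/65.5 min⁻¹ to keep the
mean observed period at 78 min, because the amplitude excursions driven by
the colored noise (whose conditional mean above the bifurcation is ≈ 2.5)
reduce the instantaneous frequency.

Two noise sources enter:

* **Colored noise in the bifurcation parameter**, mu(t) = mu + xi_mu(t),
  with xi_mu an Ornstein–Uhlenbeck process — the minimal stationary
  Gaussian process with the two knobs that matter, a stationary variance
  sigma_mu2 and a correlation time tau_mu.  At the study conditions
  (mu = 1 min⁻¹, sigma_mu2 = 6.84, tau_mu = 476 min) the process spends
  ~35% of its time below the bifurcation, producing the start/stop and
  stuttering phenotypes, and it induces the slow amplitude memory seen in
  consecutive-cycle correlations.
* **Additive white noise in both Cartesian variables**, independent and of
  equal strength (isotropy preserves rotational invariance).

### Units of the additive noise

`sigma_z2` is defined as the noise **variance accumulated over one
autonomous period** T0 = 2·pi/omega, per variable; the spectral intensity
is sigma_z2/T0 au²/min.  This convention is what makes the printed
numbers mutually consistent: on the unit limit cycle it yields phase
diffusion D = sigma_z2/(T0·r*²) and hence an intrinsic quality factor

    Q = omega / (pi D) = 2 r*^2 / sigma_z2,

so sigma_z2 = 0.486 corresponds to Q ≈ 4.1 — the regime measured for
persistent cells.  Reading sigma_z2 instead as a raw spectral intensity in
au²/min would give Q ≈ 0.05 at the same nominal value — a trace with no
visible rhythm — which is inconsistent with every other quantity in the
analysis; that reading was tested and rejected.

### Integration

Euler–Maruyama at dt = 0.1 min by default (a guard enforces
dt ≤ min(period, tau_mu)/50), with the OU sub-process advanced by its exact
exponential transition.  Initial conditions: (x, y) on the deterministic
limit cycle at a uniform random phase, xi_mu from its stationary
distribution; a 100-min burn-in is discarded so the 600-min observation
window is stationary.  A step-halving test keeps the ensemble median period
and amplitude stable within Monte-Carlo error.  Each cell draws its noise
from a counter-based (Philox) substream spawned from the master seed, so a
cell's trajectory is bit-for-bit identical whether simulated alone or in a
batch.

## Peak pipeline

Traces are background-subtracted (measured local background channel when
present, otherwise a wide moving-average trend estimate, with the path
recorded in provenance), smoothed with a centred 10-min moving average
(reflected ends; sensitivity over 6–20 min windows is part of the test
suite), and local maxima are detected on the smoothed trace — taking the
leftmost sample of tied plateaus, and letting boundary samples be
candidates so the edge rule can record them.  Candidate maxima closer than
40 min — the lower edge of the analysis period band, below which two
genuine cycles cannot both fit — are merged, keeping the higher; without
this, strong additive noise splits peaks via shallow troughs and the
measured oscillating fraction artificially collapses.  Troughs are minima
between successive peaks (boundary segments supply the outer troughs).

Filters, in order: a peak whose height above the higher adjacent trough is
below 0.1× the trace's dynamic range is discarded
(`below_dynamic_range`); a peak within 40 min of either end is discarded
(`edge_proximity`).  Heights are read from the unsmoothed trace at the
located times.  Periods are intervals between consecutive retained peaks;
intervals above 140 min are flagged not-accepted (disconnected episodes).
Cycle amplitude is the mean of a peak's height above its two adjacent
troughs, which cancels linear drift across one cycle.

**Cohort floor.**  The relative 0.1×dynamic-range rule is scale-free, so a
never-oscillating cell (pure noise) passes it with noise-scale wiggles.
Data sets are in practice assembled from rhythmic cells, so cohort
analyses add an absolute size floor of 0.1× the cohort-median dynamic
range (`cohort_prominence_floor`); oscillating cells are unaffected while
flat cells contribute no spurious peaks.

**Persistence.**  The oscillating-time fraction is
min(1, n_peaks × median period / duration) with the data-set-level median
period.  A cell is *persistent* when its longest chain of sequential peaks
(consecutive accepted intervals) covers ≥ 80% of the observable recording —
the recording net of the two 40-min edge margins, where peaks cannot be
detected.  Counting chain time as n_peaks × median period (one cycle per
peak, as in the fraction formula) makes the criterion attainable by a
noise-free oscillator regardless of its starting phase, which a literal
first-to-last-peak span is not.

## Quality factor

Pipeline per trace: complex Morlet CWT (`cmor1.0-1.0`; bandwidth 1.0
balances phase-smoothing bias against noise rejection) over 30 log-spaced
scales spanning 40–140 min; phase along the maximum rectified-power
(|W|²/scale) ridge; a validity mask requiring ridge power > 2× the
expectation for white noise of the trace's variance (flat or
noise-dominated stretches carry no phase); the cos θ autocorrelation over
valid samples with per-lag unbiased normalisation; and a least-squares fit
of

    A · exp(−g(tau)/t_c) · cos(2 pi tau / T)

over lags up to 3 cycles, with T bounded to [0.3, 3]× the ridge period,
t_c capped at 10× the window length (capped flag), and the prefactor A
absorbing lag-independent decorrelation from white phase-measurement
noise.  Windows of 6.5 × (median ridge period) tile the valid stretch; the
reported Q = t_c/T is the median over windows.

**Finite-window corrections.**  A naive single-window fit is biased high,
for two reasons with analytic form: (i) the free period absorbs the
window's mean frequency offset, which for diffusing phase removes the
tau²/L part of the phase-increment variance (L the window length); (ii) the
wavelet ridge smooths the phase over the Morlet envelope
(sigma_t = sqrt(B/2)·T), suppressing short-lag diffusion — for a
Gaussian-smoothed random walk the increment variance is D·h(tau) with
h(tau) = E[(tau − |Z|)⁺], Z ~ N(0, 2 sigma_t²).  The fit therefore uses
g(tau) = max(h(tau; sigma_t) − tau²/L, 0).  The residual bias
(≈ ×1.3–1.5, approximately uniform in Q) is removed by inverting a
calibration curve: median raw t_c/L versus true t_c/L, measured with a
fixed internal seed on the phase-diffusion reference process
(d theta = omega dt + sqrt(D) dW, exact Q = omega/(pi D)) simulated at the
same trace length, sampling and window tiling as the analysed data.  The
calibration is part of the estimator definition, cached per configuration.

With `bias_correction=False` the raw fixed-window estimate is returned; it
decreases with window length (short windows inflate apparent Q) while
preserving the ordering of datasets compared at equal window length —
which is why cross-dataset comparisons are only made at a fixed
`window_cycles`.  The corrected estimator is approximately
window-independent and agrees with the closed form within ~15% over
Q = 1–8 on phase-diffusion fixtures.

**Estimator variance.**  Single-trace Q estimates at 6.5-cycle windows are
heavy-tailed — the interquartile range spans roughly a factor of ten, as
broad as published single-cell Q distributions — so only medians over
ensembles of ≳150 traces are meaningful.  The calibration point at
sigma_z2 = 0.486 uses 1000 simulations.

## Synthetic data

The cohort generator emulates a low-density culture recording: 600-min
traces at 2-min sampling, SL dynamics at the study conditions (78-min
period, sigma_z2 = 0.486, sigma_mu2 = 6.84, tau_mu = 476 min), rendered as
non-negative intensities with a recorded slow spline baseline (amplitude
≤ 20% of signal range — there to exercise background subtraction) plus
offset, stored as raw/background/subtracted column triplets.  It
deliberately omits several features of real recordings: cell movement and
division, photobleaching, focal drift, heavy-tailed measurement noise, and
any cell-to-cell parameter heterogeneity — every simulated cell shares one
parameter set and differs only by its noise realisation.  Passing tests
therefore demonstrate that the pipeline recovers known answers under the
modelled noise structure, not that the model captures everything in real
data.  The stuttering variant sets mu = 0 so cells cross the bifurcation
repeatedly; sinusoid, flatline and phase-diffusion fixtures carry exact
ground truth (peak times; closed-form Q).

## Numerical choices and edge cases

* Phase is undefined where the amplitude vanishes (flagged, not
  interpolated); the wavelet mask plays the same role for measured traces.
* ACF fits with fewer than 8 finite points, or that fail to converge,
  return flagged results rather than raising.
* Fit start values: T from 4× the ACF's first zero crossing, t_c = 2×T.
* Flat traces yield empty peak sets; cells with < 2 peaks are
  non-oscillating and contribute no cycles.
* Triplet-table reading tolerates per-cell trailing gaps (trimmed), and
  per-sheet cell counts in spreadsheets; ragged or non-numeric blocks are
  reported with block and row indices.
* All randomness flows from explicit seeds; ensembles are reproducible
  bit-for-bit.

## Problem sizes

Test-suite ensembles are scaled for speed (60–200 cells per check;
calibration curves use 200 phase-diffusion traces per grid point), with
tolerances that account for the resulting Monte-Carlo error.  The
acceptance script runs the full-size ensembles (1000 simulations for the
Q calibration point, 500 for the non-isochronous period check).

## Known limitations

* The quality-factor calibration curve is computed for the default wavelet
  and band at a 78-min carrier; other configurations trigger a fresh
  calibration (a few tens of seconds) and extreme period ratios within the
  band would dilute its accuracy.
* The bias correction is calibrated on pure phase diffusion; processes
  with strong amplitude-phase coupling (large q) or heavy measurement
  noise retain a residual bias of order 10%.
* The peak pipeline's absolute floor assumes cohorts in which at least
  half the cells oscillate; a cohort of mostly silent cells would need an
  externally supplied intensity scale.
* Persistence classification depends on the dataset median period; for
  single isolated traces the cell's own median is used as a fallback and
  flagged accordingly.
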