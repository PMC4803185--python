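# slclock

Analysis toolkit for **single-cell genetic oscillators near a Hopf
bifurcation**, built around the zebrafish segmentation clock: cells
dissociated from the tailbud keep oscillating on their own (period ≈ 78 min
in vitro), but they do so noisily — amplitudes wander on a slow timescale,
some cells stop and restart, and the phase of even the most persistent cells
drifts.  `slclock` packages the three pieces needed to make that story
quantitative:

1. **A stochastic Stuart–Landau simulator.**  The normal form of a
   supercritical Hopf bifurcation with two noise sources,

   d*z*/d*t* = (μ(*t*) + iω) *z* − (*b* + i*q*) |*z*|² *z* + ξ(*t*),
   *z* = *x* + i*y*,

   where μ(*t*) = μ + ξ<sub>μ</sub>(*t*) carries slow Ornstein–Uhlenbeck
   fluctuations (variance σ<sub>μ</sub>², correlation time τ<sub>μ</sub>)
   that push the cell across the bifurcation and back, and ξ(*t*) is
   additive white noise in both variables (variance-per-cycle
   σ<sub>z</sub>²) that jiggles amplitude and, above all, phase.  On the
   limit cycle *r*\* = √(μ/*b*) the phase obeys θ̇ = ω − *q* *r*², and the
   additive noise produces phase diffusion with
   *D* = σ<sub>z</sub>²/(*T*₀ *r*\*²).

2. **A peak/period/amplitude pipeline** for fluorescence-like traces:
   background subtraction, smoothing, peak detection with a 0.1×dynamic-range
   size rule and a 40-min edge rule, the 140-min accepted-period cutoff,
   per-cycle amplitudes, persistence classification and the
   oscillating-time fraction.

3. **A wavelet-phase precision estimator.**  The quality factor
   *Q* = *t<sub>c</sub>*/*T* — how many cycles before phase memory is lost —
   measured from the damped-cosine fit of the cos θ autocorrelation, θ taken
   along the ridge of a complex-Morlet wavelet transform, always on windows
   of a fixed number of cycles (6.5 by default) so datasets of different
   lengths compare fairly.  The estimator is calibrated against the
   phase-diffusion process, whose exact answer is *Q* = ω/(π*D*).

Statistics utilities (successive-cycle correlations with randomized
controls, period–amplitude independence, two-sample KS comparison, and the
noise-parameter sweeps that connect model to data) sit on top.

## Worked example

```python
import numpy as np
from slclock import SLParams, analyze_cohort, quality_factor, render_trace, simulate_ensemble

# 200 cells, additive noise only, 600 min at 2-min sampling
params = SLParams(sigma_z2=0.486)          # variance per cycle, au^2
traces = [render_trace(t, 2.0) for t in simulate_ensemble(params, 200, seed=101)]

cycles = analyze_cohort(traces)
pooled = np.concatenate([c.accepted_periods for c in cycles])
print(round(np.median(pooled), 1))         # 78.0  -> the clock period, min

qs = np.array([quality_factor(t).Q for t in traces])
print(round(np.nanmedian(qs), 1))          # 4.1   -> median quality factor
```

The first number is the median accepted inter-peak interval — the 78-min
in-vitro clock period.  The second says a cell at this noise level keeps
phase memory for about four cycles, which is the precision measured for
persistently oscillating cells; halve the noise and the median Q roughly
doubles (`sweep_additive_noise` maps the whole curve, with 68% CIs and KS
p-values against a reference Q sample).

The `examples/` scripts are short narrative versions of each capability
(simulation regimes, peak statistics, quality factors, the two noise
sweeps, cycle correlations); each prints a few numbers and what they mean.
A thin CLI covers the same stages on files: `slclock simulate | fixtures |
peaks | qfactor | sweep | correlate` (see `slclock --help`).

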