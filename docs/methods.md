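# Methods

This note documents the models, measurement definitions, numerical choices
and synthetic study conditions implemented in `ecphys`, and what the
package's tests do and do not establish about real recordings.

## Membrane model

Subthreshold dynamics are a two-variable linear system,

    C  dV/dt = −g_L (V − E_L) − a·w + I(t) + synaptic current
    τ_w dw/dt = (V − E_L) − w

with C in pF, conductances in nS, V in mV, I in pA and time in ms (so that
pF/ms carries units of nS and 1/nS = GΩ). The recovery variable `w` is a
linearised slow current (an h-current/M-current stand-in): for `a > 0` it
produces sag on hyperpolarizing steps, a post-EPSP rebound, and band-pass
subthreshold impedance

    Z(ω) = (1 + iωτ_w) / [ (g_L + iωC)(1 + iωτ_w) + a ],

whose DC limit is the steady-state input resistance `1/(g_L + a)`. Spikes
are not modelled dynamically: when V crosses the threshold `V_T` a
stereotyped piecewise-linear template (rise to `ap_peak` in `ap_rise_ms`,
fall to the reset `V_r` in `ap_fall_ms`) is pasted and integration resumes
from `V_r`. This makes spike threshold, amplitude and duration exactly
known, which is what the suprathreshold measurements are validated against.

**Integration.** The 2×2 system is discretised exactly for zero-order-hold
input via its matrix exponential (implemented as two first-order complex
recursions with `scipy.signal.lfilter`, diagonalising the propagator).
Piecewise-constant stimuli are therefore integrated without discretisation
error; smooth stimuli (ramps, chirps, synaptic kernels) are sampled at step
midpoints, making the residual error second order in the 0.05 ms step
(measured: ≤ 1e-3 mV against the closed forms). Integration proceeds in
20 000-sample chunks so that a spike only discards the tail of its own
chunk; sweeps with many spikes remain linear in sweep length.

**Noise.** Recording noise is an additive Ornstein–Uhlenbeck process
(default τ = 5 ms) on the recorded voltage, not a current in the dynamics.
This choice keeps the subthreshold integrator exact and spike times
deterministic per seed, and mimics the band-limited baseline fluctuation of
a real recording; it does not model channel noise or noise-driven spiking.
White noise would also break the 1 mV/ms spike-threshold criterion at
20 kHz sampling, which the OU bandwidth avoids.

**Sampling.** 0.05 ms (20 kHz) throughout; the acquisition rate of the
experimental recordings is not constrained by the analysis definitions, and
20 kHz resolves both the 3 ms light pulses and the derivative threshold
criterion. No anti-alias filtering is applied before measurement.

## Synaptic model

Each response component — fast EPSP (AMPA-like), slow EPSP (NMDA-like,
unused by default), fast IPSP (GABA_A-like), slow IPSP (GABA_B-like) — is a
difference-of-exponentials **current** kernel injected at the soma,
calibrated per cell so that the component alone, on the noise-free
membrane, peaks at exactly its specified somatic amplitude (measured
calibration error < 0.1%). Current kernels rather than conductances were
chosen because the measurements being validated are somatic PSP amplitudes
and time courses, and current kernels give exactly controllable ground
truth; the cost is that reversal-potential effects (driving-force
saturation, shunting) are absent. A consequence worth noting: with current
kernels every component's tail relaxes at the membrane time constant, so a
fast IPSP of the same kernel speed as a larger EPSP would be completely
masked. The fast-IPSP kernel therefore decays over 45 ms (rise 2.5 ms)
versus 8 ms (rise 0.6 ms) for the fast EPSP, emulating the fact that the
GABA_A conductance outlasts the AMPA current; the slow IPSP uses
50 ms rise / 180 ms decay with a +5 ms latency, and the fast IPSP follows
the EPSP by +1.5 ms (disynaptic feedforward path). Exact kinetic constants
are not reported for the recorded cells; these values are plausible
defaults, and all recovery tests compare against the generator's own
recorded ground truth, not against literature kinetics.

Trains apply per-pulse multiplicative scaling factors to each component's
kernel; temporal summation on top of that scaling is emergent (the 180 ms
slow IPSP summates strongly at 10 Hz, the 45 ms fast IPSP by ~12%).

## Synthetic cohort: study conditions

`default_cohort_config()` encodes the emulated study design. Per-class cell
counts and response-class mixtures follow the reported tabulations
(stellate cells: 21 none / 2 suprathreshold / 56 biphasic / 27 excitatory /
5 inhibitory out of 111 — the printed subclass counts are internally
inconsistent by 2 and the biphasic count absorbs the difference; pyramidal
cells 10/2/19/16 of 47; analogous mixtures for L3/L5 cells and L1/L2
interneurons). `scale` multiplies all counts for reduced-size runs.

Choices where the source reports no number, fixed once as realistic
conditions:

- **Membranes.** Stellate: C ≈ 200 pF, g_L ≈ 8 nS, a ≈ 4 nS, τ_w ≈ 25 ms
  (R_in ≈ 80 MΩ, weak theta-band resonance, sag); pyramidal/interneuron:
  passive, C ≈ 150 pF, g_L ≈ 6.5 nS. Each ±15% per-cell jitter; resting
  potential N(−65, 2.5) mV. The stellate resonance gain is deliberately
  modest: the rebound after a large EPSP scales with `a`, and above
  ~0.5 mV it would (correctly, but unhelpfully for validation) make purely
  excitatory responses measure as biphasic.
- **Amplitudes.** Component peaks are lognormal (stellate EPSP median
  3.5 mV, pyramidal 6 mV) clipped to [1.2, 8] mV — above the 0.5 mV
  detection floor and below the range where rebound or cancellation would
  change the apparent class. Biphasic cells draw an E–I ratio from a Beta
  distribution — broad for stellate cells (mean ≈ 0.55, spanning 0–1),
  narrow and excitation-biased for pyramidal cells (mean ≈ 0.76) — and the
  implied IPSP is kept ≥ max(2 mV, 30% of the EPSP) so it stays detectable
  under the overlapping EPSP.
- **Slow-inhibition share.** Stellate IPSPs are 25–50% slow (GABA_B-like),
  pyramidal IPSPs 2–15%. This follows the qualitative finding that slow
  feedforward inhibition is prominent in stellate cells, and it is what
  preserves the reported train phenomenology: stellate E–I ratios drop and
  broaden across a 10 Hz train (slow-IPSP summation plus a per-cell IPSP
  growth factor drawn around 1.5), while pyramidal ratios barely move.
- **Sweeps.** 10 repeats per cell for single pulses (the recordings used
  10–30), 1 train sweep, OU noise 0.2 mV.

## Measurement definitions and numerics

- Baselines: mean of [onset−500, onset−10) ms (single pulse) or
  [onset−1000, onset−10) ms (train). Step measurements use a 200 ms
  pre-onset baseline and the last 500 ms of the 3 s step as steady state.
- The "peak" of an evoked component is the centred 1 ms boxcar mean of the
  averaged trace at its extremum. The depolarising peak is located first;
  the hyperpolarising trough is searched after the peak only when the peak
  itself clears the detection floor (otherwise a noise maximum could hide a
  pure IPSP that occurs earlier).
- Detection floor for classification: max(0.5 mV, 3× the SD of the
  averaged-trace baseline). A response is suprathreshold if any individual
  sweep spikes within 50 ms of the stimulus.
- Latency is the 10%-of-peak deviation time of the governing (leading)
  component, reported only for amplitudes ≥ 1 mV; note it includes the
  subthreshold rise lag, so it exceeds the synaptic delay by ~1 ms for
  realistic kinetics. Half-width uses linear interpolation at the 50%
  crossings.
- Spike threshold: first sample of an excursion with centred-difference
  dV/dt > 1 mV/ms, accepted only if the voltage reaches −20 mV within
  2 ms (rejects large fast PSPs), with a 2 ms refractory grouping and one
  event per excursion above its own threshold.
- τ is the linearly interpolated 63.21% (1 − 1/e) crossing; for resonant
  membranes the reference value in tests is the 63% crossing of the exact
  matrix-exponential step response, not C/g_L.
- Impedance spectra restrict the FFT ratio to the chirp band (0.5–20 Hz
  over 20 s by default) and smooth with a 0.5 Hz boxcar normalised by the
  number of in-band bins (plain convolution would bias the band edges);
  the resonance peak therefore has an effective resolution of the
  smoothing width. Ties break toward lower frequency; a peak in the lowest
  bin is flagged non-resonant.
- Densities use half-open boxes [a, b) everywhere; mediolateral bins are
  [0,150), …, [750,900) µm from the parasubiculum border.
- Statistics: midranks for ties; exact signed-rank null by DP over the
  doubled ranks (n ≤ 25); exact U by insertion DP without ties
  (n₁n₂ ≤ 400) or labeling enumeration with ties; exact KS by vectorised
  labeling enumeration while C(n, n₁) ≤ 50 000; otherwise normal/χ²
  approximations with tie and continuity corrections (KS: the asymptotic
  Kolmogorov distribution with the small-sample √n_e correction). Two-sided
  exact p = 2·min(lower, upper tail), capped at 1. Kendall's W is reported
  as χ²/(N(k−1)) without tie correction in W itself (the χ² is
  tie-corrected); an all-tied design returns χ² = 0, W = 0.

## Synthetic anatomy

Puncta fields are homogeneous Poisson within each layer-slab × 150 µm
mediolateral bin, with per-layer intensities (defaults L1 4790 mm⁻³, then
1200/300/400/800 for L2/L3/L5a/L5b) and a decreasing mediolateral gradient
from the parasubiculum border (1.5 → 0.7 across six bins). The default
geometry stacks anatomically plausible layer widths (100/150/250/150/250
µm) with a 1000 µm z-extent; the z-extent represents a pooled image-stack
volume rather than one 20 µm optical section, chosen so each 150 µm extract
expects tens-to-hundreds of puncta and density rankings are stable, as the
small reported SEMs imply. Intensity profiles are Gaussian bumps plus
Gaussian noise, clipped to the 8-bit gray range.

## Problem sizes

Defaults are sized for interactive use and the bundled test suite: the
pipeline's default cohort scale is 0.2 (≈ 50 cells), the recovery sweeps
use 50 random parameter points, calibration checks 1 000 null replicates,
and Monte-Carlo structure checks 100 seeds of 24 + 24 layer-2 cells. The
full-size design (`scale=1`, 286 cells, intrinsic protocols included) runs
in a few minutes. The null-calibration study evaluates each asymptotic test
at sizes within its operating regime (n = 30 pairs, 25 + 25, 3×15, 20
subjects × 5 conditions, n = 30 regression); the Friedman χ² approximation
in particular is a few thousandths conservative at small k.

## What passing tests show — and what they do not

The validation loop is closed against the generator's own ground truth and
against closed-form solutions of the same linear model that produced the
data. Passing therefore shows that the measurement chain is correct and
numerically tight under the stated assumptions (linear subthreshold
dynamics, stereotyped spikes, current-kernel synapses, OU recording noise,
stationary baselines). It does not establish robustness to phenomena the
generator omits: dendritic filtering and reversal-potential effects,
electrode drift and series-resistance errors, bridge-balance artefacts,
seal instability, spike-shape variability, heteroscedastic or
non-stationary noise, and manual-threshold variability in puncta
segmentation (segmentation itself is out of scope; point tables are the
input). Classification-recovery rates quoted anywhere in the package refer
to the synthetic conditions above, where true component amplitudes are kept
away from the detection floor by construction.
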