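# Methods

## The phase model

A repetitively firing neuron is reduced to one variable, the phase
φ ∈ [0, 1), with dynamics dφ/dt = ω + Z(φ)·I(t). ω (spikes/ms) is the
unperturbed firing rate; Z(φ) (cycles per pA·ms) is the infinitesimal
phase-resetting curve; a spike fires when φ crosses 1. The model assumes
perturbations are weak enough that the cell never strays far from its
limit cycle, so input only advances or delays progress along it. All PRCs
handled here are type 1 (non-negative): depolarising charge always
advances phase.

Integration is explicit first order on a fixed grid,
φ ← φ + Δt·(ω + Z(φ)·I), with the driving current held constant within
each of its samples. Two post-crossing conventions are implemented:

- **restart** — φ resets at the crossing, producing an ongoing spike
  train. With `refine=True` the spike time is placed at the linear
  sub-step crossing of φ = 1 and the overshoot carried into the next
  cycle, making the zero-noise interval exactly 1/ω; without it spikes
  land on the first grid time with φ ≥ 1 (the convention of a
  fixed-step discrete-time simulation).
- **drift-after-crossing** — used for ensembles: at the crossing the input
  is discontinued and φ drifts on at ω. Phases > 1 then map linearly onto
  time since the spike, so a vertical slice through the ensemble at any
  time gives the latent-phase distribution, and the per-trajectory first
  crossing times give the ISI distribution.

φ is clamped at 0 from below (a large hyperpolarising pulse cannot push
the cell "before" its spike); the clamp count is exposed on the results
and is zero in all shipped configurations.

Ensembles default to 5000 trajectories at Δt = 1 ms with a 1 s period.
Per-trajectory noise streams are seeded from (seed, trajectory index), so
ensembles are bit-reproducible and independent of execution order. Phase
snapshots are stored in float32 to bound memory; the integration state and
crossing times are float64.

## Pulsed Gaussian noise

Noise is a sequence of contiguous constant-current pulses of fixed
duration d whose amplitudes are i.i.d. N(0, σ²) — the finite-bandwidth
realisation of current noise that an amplifier can actually deliver, and
one whose capacitative voltage transients let a rig verify charge
delivery (`pulse_slope_qc` checks that per-pulse voltage-ramp slopes,
first sample excluded, are proportional to pulse amplitude). Draws use
NumPy's PCG64 generator; any high-quality Gaussian source is equivalent
for these purposes.

## Closed-form ISI variability

Each pulse delivers charge with variance d²σ², and there are 1/(dω)
pulses per mean interval, so squared charge accumulates at rate d·σ²/ω
per interval. Under the small-noise approximation the latent-phase
variance grows with the local squared PRC,

    Var_phase(t) = (d σ² / ω) ∫₀^{ωt} Z(u)² du,

and the ISI variance equals the phase variance at t = 1/ω scaled by 1/ω².
Hence CV = σ·√(d·S/ω) with sensitivity S = ∫₀¹ Z². No further spectral
correction for pulse bandwidth is applied — the d²σ² per pulse × 1/(dω)
pulses bookkeeping *is* the pulse adaptation. The approximation assumes
the phase distribution stays narrow; measured against Monte Carlo
ensembles (raised-cosine PRC, d·ω = 0.001) the relative error is under
2% at CV ≤ 0.25 and reaches 15% near CV ≈ 0.40 ± 0.02 — beyond that the
distribution spreads into low-Z regions and the closed form overpredicts.

## PRC estimation by noise regression

Each interval α is divided into n phase bins; the injected charge in bin
i is Q<sub>α,i</sub> (each current sample assigned to the bin containing
its start time). OLS of y<sub>α</sub> = T<sub>α</sub>/T̄ on the columns of
Q plus a free intercept gives the PRC as the negated slopes: charge
arriving where Z > 0 shortens the interval. Standard errors are the
classical OLS ones, √(s²·diag((X'X)⁻¹)); R² is the share of ISI variance
attributable to the injected noise. Design choices:

- **Bin count**: n = min(⌊T̄/d⌋, 50) — on average one pulse per bin keeps
  the per-bin charges statistically independent; estimation requires at
  least n + 10 intervals.
- **Time→phase mapping**: `interpolated` divides time since the previous
  spike by that interval's own length (conserves charge per interval;
  error spread evenly over the cycle); `mean_period` divides by T̄
  (charge past bin n discarded; late-phase standard errors inflate as
  noise-driven phase variance accumulates). On matched simulations the
  mean-period mean SE is ≥ 2× the interpolated one, with the gap
  concentrated at late phases.
- **Intercept**: estimated freely (≈ 1 for normalised intervals) rather
  than fixed, absorbing slow rate drift without biasing Z.
- **Standard errors** include the residual-variance factor s² (plain
  diag((Q'Q)⁻¹) without it is not an estimator of the coefficient
  variance); SE *ratios* between binning modes are insensitive to this
  common factor.
- **T̄** is computed per episode.

The fitted curve is tabulated at bin centers (i−½)/n and interpolated
linearly with pinned endpoints Z(0) = Z(1) = 0; phases past 1 map to
zero. Sensitivity is integrated exactly on that piecewise-linear
interpolant (segment-wise h(a² + ab + b²)/3), and the centroid is
ΣφᵢZᵢ/ΣZᵢ over the tabulated bins.

**Validity regime.** Interpolated phase is a first-order stand-in for
latent phase, so binning errors act like measurement error in the charge
matrix and attenuate the estimate as total ISI CV grows: measured
S_est/S_true is ≈ 0.98 at CV 0.09, 0.80 at CV 0.26, 0.70 at CV 0.38, and
the regression R² has a corresponding ceiling (0.94 at CV 0.26 even with
no intrinsic noise). Consequently PRC estimation is most accurate at the
lowest noise that still dominates the intrinsic variability — with
intrinsic noise present, R² rises with σ and saturates, and the
sensitivity estimate is stable (< 20% variation) across noise amplitudes
only while the total CV stays ≲ 0.3. Parameter-recovery tests therefore
run in that regime; outside it the attenuation is reproducible and
documented, not corrected.

## Spike-time prediction

Given a PRC and an episode's recorded current, the phase model is
restarted at every actual spike and integrated at Δt = 0.05 ms (with
linear sub-step crossing refinement); the first crossing of φ = 1 is the
predicted next spike. ω defaults to the reciprocal of the episode's mean
interval and can be overridden. An interval with no crossing within five
mean periods is reported unpredicted. Accuracy is scored as variance
explained, 1 − SS_res/SS_tot about the mean actual interval — the
SS-based form penalises bias and can go negative; squared Pearson
correlation is available as an alternative.

## Synthetic experiments

`synth_experiment` emulates a perforated-patch noise-injection recording.
Defaults are the study conditions: intrinsic rate 10 spikes/s (observed
range 4.5–31.9), ground-truth PRC from the beta family (p=2, q=3 —
early-peaked, as in most autonomously firing STN cells) calibrated to
sensitivity 4×10⁻⁷ cycles²/(pA²·ms²) (mid-range of the observed
10⁻⁷–10⁻⁶), injected noise 60 pA / 0.5 ms, and two 60 s episodes.
Intrinsic variability is modelled as a second, *hidden* pulsed-Gaussian
current (30 pA, same pulse duration) acting through the same PRC: additive
independent phase perturbations make the variance partition analytic —
expected regression R² ≈ σ²_inj/(σ²_inj + σ²_int) — and the 2:1 SD ratio
sets the injected share to ≈ 80%. Baseline (noise-free) episodes then
show CV ≈ 0.13, inside the observed 0.04–0.35. What this generator does
*not* emulate: correlated or non-stationary intrinsic noise, spike
frequency adaptation, rate- or conductance-dependent PRC reshaping, and
synaptic (conductance) input — so passing tests validate the estimator
and theory under the phase model's own assumptions, not those biological
complications.

The raised-cosine family Z = A(1−cos 2πφ)/2 serves as the generic/Monte
Carlo shape. For ensemble studies at a 1 s period its amplitude is set so
that sensitivity = 4×10⁻¹⁰, placing the 25–800 pA pulse-amplitude range
at ISI CVs up to ≈ 0.5 (the regime the desk-scale Monte Carlo
comparisons cover).

## Numerical and testing notes

- Problem sizes: estimation experiments use 600–1200 intervals (60 s at
  10 spikes/s, or 1200 s at 1 spike/s); ensembles 3000–5000 trajectories.
- Sequential inner loops (long restart runs, per-interval prediction) are
  numba-compiled; ensembles are vectorised NumPy. Seeded runs are
  bit-reproducible.
- The end-to-end pipeline (estimate on episode 1, predict episode 2) at
  the default calibration yields variance explained of 0.60–0.74 across
  20 replicates (mean 0.66): slightly below the regression R² because the
  hidden noise also perturbs the phases at which the injected pulses act,
  and because of the estimator attenuation at total CV ≈ 0.3.
- Degenerate inputs fail loudly: rank-deficient charge matrices report the
  offending columns, intervals shorter than one sample or two pulses
  raise, all-equal pulse amplitudes make the QC regression degenerate.
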