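# Methods

This note documents the model and procedure implemented in `acfc`, the
parameter choices that matter, and the limits of what the synthetic
validation shows.

## Signal model and preprocessing

Each channel is a uniformly sampled `Recording` (EMG, EKG or respiratory
belt; ≥ 500 Hz, 1 kHz in all defaults). Conditioning is a 4th-order
Butterworth band-pass applied forward–backward (zero phase): 5–250 Hz for
EMG, 0.5–150 Hz for EKG, plus a 1-Hz-wide Butterworth band-stop at the
mains frequency (60 Hz default, configurable to 50 Hz). Zero-phase
filtering is load-bearing: the coupling analysis is explicitly *zero-lag*,
so filters must not introduce group delay. Reflect padding suppresses
startup transients on short segments. The filter family and order are this
package's choice — standard surface-EMG practice — since only the corner
frequencies are method-prescribed.

## Band-power decomposition

Windows of 2 s (1-s step) are tapered (Hamming, configurable) and
Fourier-transformed as one segment; power lands on a 0.5-Hz bin grid. When
the window is longer than 1/bin_width (the 20-s respiratory windows),
native FFT bins are summed onto the coarser 0.5-Hz grid.

**Bin convention.** The ten 19.5-Hz bands are half-open, [low, low+width)
on the 0.5-Hz grid, giving 39 bins per band with printed edges
F1 = [10–29.5] … F10 = [205–224.5]. Inclusive edges would yield 40 grid
points per band and contradict the stated bin count of 39; the half-open
reading reconciles edges and count. Bands start every 20 Hz and skip the
50–65 Hz mains-notch exclusion zone, so the scheme is intentionally not
contiguous there. Windows not fully contained in the recording are dropped
(no padding) to avoid edge-biased power estimates; series timestamps sit
at window *centers*, so a 2-s/1-s analysis produces values at t = 1, 2, …
s, exactly aligned with the 1-s heart-rate grid.

Band series are z-scored over the whole segment before global coupling
(removes amplitude differences between muscles and bands). A linear
detrending variant is provided as a control for protocols with slow
monotonic power drift (e.g. incremental ergometer tests).

## Rate series

* **Heart rate.** R peaks via the Pan–Tompkins cascade (5–15 Hz band-pass,
  derivative, squaring, 150-ms moving-window integration, adaptive
  two-level thresholding with a 0.25-s refractory floor), implemented
  in-package with every stage zero-phase, followed by refinement to the
  local raw-waveform maximum. HR = 60/RR is anchored at the later beat of
  each interval (a causal convention; the method source does not fix one)
  and cubic-spline resampled to a uniform 1-s grid of integer timestamps.
  Artifact correction: a sample deviating more than 2 SD from its centered
  10-s window mean is replaced by the mean of the *other* samples in that
  window. Flagging includes the sample itself (otherwise any deviation from
  a locally constant neighbourhood would be flagged); replacement excludes
  it so an isolated spike is restored to the local baseline. Values are
  clamped to 25–250 BPM.
* **Breathing rate.** Two extractors: breath-peak detection (clean, resting
  recordings), and a windowed-spectrum ridge for exercise data — 20-s
  windows, 0.5-s step, linear detrend, Hamming taper, 4× zero padding,
  peak bin within 0.05–1.0 Hz refined by parabolic interpolation, then a
  2-s moving average. The ridge extractor is a self-contained replacement
  for external wavelet TFR toolboxes; on chirps from 12 to 24 breaths/min
  it tracks the truth to well under 0.1 breaths/min. Clamps: 4–80
  breaths/min. Windows without an in-band peak are flagged and bridged by
  linear interpolation.

## Coupling

**Global (phase 1).** Equal-time Pearson matrices on the trimmed common
time support of the two series sets; lags are expressed in series steps and
`best_lag` scans a candidate list with ties broken toward the smallest
|lag| (negative before positive). Group averaging is a plain element-wise
mean of correlation coefficients (Fisher-z averaging is deliberately not
the default, matching the method as described); missing cells are
mean-ignored with per-cell counts recorded. Link-strength classes are
config-driven with four shipped presets because the method leaves the
breakpoints to the analyst and uses different sets in different contexts.

**Dynamic (phase 2).** 6-s windows, 3-s step, *locally* z-scored (ddof=1)
so that 1/(W−1) Σ P̂₁P̂₂ is exactly the within-window Pearson coefficient;
window counts follow floor((N−W)/hop)+1 with fully-contained windows only.
Zero-variance windows propagate as missing (NaN) through histograms and
statistics — never imputed. Histograms span [−1, 1] at Δc = 0.05 (40 bins)
and are rescaled to their modal count.

## Variability

Moment conventions are explicit in every output: SD with ddof=1, kurtosis
in the Pearson convention (normal = 3) with excess alongside, biased g₁
skewness. DFA integrates the mean-centred series into a profile, detrends
non-overlapping windows at each scale with a polynomial (order 1 default),
pools residuals from both a start-anchored and an end-anchored pass so no
samples are discarded, and fits α as the log-log slope over ~15 log-spaced
scales from 4 to N/4. These are community-standard defaults; the method
source cites the original DFA formulation without parameters. Note that
because DFA detrends the *profile*, order-1 DFA annihilates a constant
input (flat profile), while a linear input ramp (quadratic profile)
requires order 2. The magnitude–sign decomposition drops increments that
would span a missing window (gap flag) rather than bridging them.

## Surrogates

Plain Fourier phase randomization preserves the amplitude spectrum exactly
(DC and Nyquist untouched) but Gaussianizes the marginal distribution;
preserving both the spectrum and the amplitude distribution simultaneously
is impossible for this surrogate class, so an AAFT mode (distribution-exact,
spectrum-approximate) is offered as an alternative. Cross-participant
pairing is exhaustive over unordered pairs (35 participants → 595 pairs;
6 muscle pairs × 100 links × 595 = 357,000 pooled values), and surrogate
link strengths are produced by the *same* band-power → normalization →
coupling code path as real data. Th = μ_surr + 2σ_surr by definition. The
human-cohort value Th = 0.11 depends on the study data and is out of scope
here; on synthetic cohorts the threshold is recomputed from scratch.

## Synthetic cohort: what it emulates, and what it does not

Each EMG channel is Σ_b √(w_b · E_b(t)) · ξ_b(t): per band, unit-variance
band-limited Gaussian noise ξ_b multiplied by a log-normal power envelope
E_b = exp(a·z_b − a²/2), with z_b a slow latent Gaussian process (2nd-order
low-pass, 0.25 Hz bandwidth — the squat-cycle timescale; generated with
discarded burn-in margins so no filter transient leaks in). Cross-channel
coupling is imposed on the latents via a Cholesky mixture; the latent
correlation is solved analytically, ρ_z = ln(1 + ρ(e^{a²} − 1))/a², so the
*envelope* correlation equals the designed ρ exactly in expectation. The
truth table stores the designed ρ, ρ_z, and the correlation measured
between the generated envelopes.

Defaults: n = 5 participants, 600 s at 1 kHz, modulation depth a = 1
(power-envelope CV ≈ 1.3, deep task-like modulation), ρ = 0.6 for
same-type muscle pairs, 0.2 across types, 1% broadband noise floor, HR
ramping 75→95 BPM, BR 15→18 breaths/min.

**Known attenuation.** The pipeline's recovered coupling is the Pearson
correlation of *estimated* band power, and the χ²-like estimation noise of
a 39-bin, 2-s spectral sum attenuates it by v/(v + (1+v)q), where v is the
envelope-power variance and q ≈ 0.04 the relative estimation variance —
about 0.93 at the default depth, i.e. recovered r ≈ 0.56 for designed
ρ = 0.6, within the ±0.07 recovery contract. The generator does **not**
emulate movement artifacts, electrode noise, nonstationary band-weight
drift, motor-unit structure, ECG cross-talk into EMG, or genuine
cardio-/respiratory-muscular coupling (HR/BR profiles are independent of
the EMG envelopes). Passing the validation suite therefore demonstrates
correctness of the estimator chain on signals with known coupling — not
robustness to every artifact class of real exercise recordings.

## Numerical choices and degenerate inputs

Readers reject NaN cells naming row and column; matrix CSVs are written at
17 significant digits and re-read with round-trip float parsing, so
write→read is bit-identical. Constant series raise dead-channel errors in
global z-scoring and coupling; constant *windows* become missing values in
dynamic coupling. Correlations are clipped to [−1, 1] after floating-point
rounding. Overlaps shorter than 10 points are rejected. DFA scales above
N/4 are dropped with a warning; fewer than 4 usable scales is an error.
sgn(0) = 0 is kept as-is. All generators and surrogates are pure functions
of (spec/inputs, seed).

## Problem sizes used in the validation suite

The shipped tests run the default 5 × 600-s cohort once (shared fixture),
exercise the full surrogate pairing at n = 5, and estimate the DFA limits
at length 10,000 over 20 seeds — sizes chosen so the complete suite
finishes in a few minutes on one CPU while keeping every statistical
assertion comfortably inside its tolerance.

## Known limitations

EDF ingestion is not implemented (delimited text + sidecar only).
Graph-theoretic summaries beyond link counts/strengths, multifractal DFA,
time-varying lag tracking, ectopic-beat classification and figure
rendering are out of scope. The surrogate default Gaussianizes marginals
(see above). The 6-s/3-s dynamic windows contain only 6 samples at the
default resolution, so individual window correlations are noisy by
construction — the method's histograms and variability statistics are the
intended consumers, not single-window values.
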