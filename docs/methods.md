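# Methods

This note documents the models, the parameter defaults and why they hold,
the numerical choices, what the synthetic generators do and do not
emulate, and the known limitations.

## Signal model and conditioning

Every analysis channel is a uniformly sampled real series: ECG at
f_s = 1 kHz, array/ventilatory channels at f_k = 500 Hz, and the optical
(gill-ROI mean brightness) ventilatory signal at f_c = 100 fps.  The
conditioning chain is fixed across conditions:

1. **Bandpass.** 3rd-order Butterworth, applied forward–backward
   (`sosfiltfilt`), passbands 1–10 Hz (ventilation) and 5–120 Hz (ECG).
   Zero-phase filtering was chosen because peak *times* feed the interval
   statistics; the price is a squared magnitude response, which only
   steepens the skirts.  The 120 Hz ECG cutoff requires the 1 kHz rate;
   applying the ECG spec at 500 Hz raises a spec error rather than
   silently aliasing.  Filtering precedes segmentation so segment
   boundaries see no filter startup transients; the recording's first and
   last ~1/low_hz seconds do (measured: a 1 Hz low cutoff leaves ~1.4%
   residual transient at 1 s, ~0.01% at 2 s).  No trimming is performed.
2. **Segmentation.** Non-overlapping 5-s windows from t = 0; an
   incomplete tail is discarded.  120 s therefore yields exactly 24
   segments, which is what makes cohort bookkeeping exact (5 fish ×
   24 = 120 rows per dose; 96 when one fish is excluded).
3. **Standardization.** Per-segment z-score (mean 0, sample SD 1).  A
   (near-)constant segment cannot be standardized and is marked invalid;
   the pipeline excludes invalid segments listwise per metric rather than
   imputing, so reported row counts are interpretable.

## Ventilatory frequency: Burg AR spectra

The ventilatory frequency of a segment is the argmax of an autoregressive
power spectral density fitted by Burg's method.  The recursion minimizes
the summed forward+backward prediction error through reflection
coefficients k_m = −2Σf·b / Σ(f²+b²), with Levinson coefficient updates
and E_m = (1−k_m²)E_{m−1}; |k_m| < 1 guarantees a stable model and E_p is
non-increasing in p.  One sweep to p_max = 50 yields the whole error
sequence, so AIC(p) = n·ln(E_p) + 2p over p = 10…50 costs a single fit;
ties break toward smaller p.  The AIC form is the standard least-squares
one (constants cancel in comparisons), and the sweep is verified in tests
against independent per-order refits to 1e-9.

The PSD is S(f) = σ²/(rate·|A(e^{−i2πf/rate})|²) with
A(z) = 1 + Σa_k z^{−k}.  The peak is searched on a dense local grid over
the ventilatory passband (1–10 Hz, 0.01 Hz spacing — finer than the
0.02 Hz resolution the peak contract requires), ties toward the lower
frequency.  A flatness guard (in-band max/min power ratio < 1.001)
reports "no peak" instead of an arbitrary argmax; note this guard only
triggers for genuinely flat fits (e.g. low-order fits to white noise) —
an AIC-selected p ≥ 10 fit to white noise carries ~1–20% random ripple
and will report its ripple maximum.  Filtered physiological segments
always carry in-band structure, so this limitation is theoretical for the
intended inputs.

Two properties anchor correctness: on narrowband segments (interval CV
≈ 0.05, the free-swimming regime) the AR peak and a zero-padded
periodogram agree within 0.1 Hz in ≥95% of replicates; as interval jitter
broadens the line (CV ≥ 0.1) the two estimators legitimately diverge, so
cross-estimator agreement is only asserted in the narrowband regime.
Also, the exact AR(2) peak is cos ω = −a₁(1+a₂)/(4a₂), *not* the pole
angle: a 3 Hz pole at radius 0.98 on a 500 Hz rate peaks at 2.533 Hz
because the mirrored pole is only 6 mHz·rad away; tests assert the closed
form.

## Event statistics

Peaks are local maxima strictly above the nearest differing neighbors
(flat tops, which sampled sinusoids produce, count once at their earliest
sample) with height ≥ θ_p in standardized units, accepted greedily in
decreasing height order under a refractory constraint θ_I (ventilation:
θ_p = 0.5, θ_I = 0.1 s; ECG: θ_p = 0.1, θ_I = 0.2 s).  Greedy-by-height is
the common HRV practice and is verified against brute-force enumeration.
Peak times are at sample resolution (2 ms at 500 Hz), negligible against
the CV scales of interest (≥ 0.017).  ECG polarity is configurable
(needle-electrode R waves can be negative); detection runs on the signed
standardized signal.

Heart rate is peak count / 5 s, so it is quantized to 0.2 beats/s; an
ideal 2.26 beats/s train yields 11 or 12 beats per window depending on
phase, i.e. 2.2 or 2.4 — tests enumerate phases exhaustively.

Interval variability: each interval is attributed to its terminating
peak, the (time, value) pairs are linearly interpolated onto a 10 Hz grid
spanning the second to the last peak (no extrapolation), and the CV is
sample SD / mean of the grid values within the 5-s window.  Windows whose
defined tachogram spans < 1 s are invalid.  **Estimator bias:** linear
interpolation smooths the interval sequence, so the resampled-tachogram
CV underestimates the true renewal-process CV by ~25% at CV 0.26–0.43
(measured); it is a time-weighted, smoothed variability index — the
default because it mirrors the published procedure — while the raw
interval CV (config `cv_use_resampled: false`) recovers generator truth
to within ~4% and is what the recovery checks use.

## Free-swimming kinematics

The 126 electrodes are modeled as a 14 × 9 lattice at 15 mm pitch
centered in the 210 × 140 mm floor — the unique near-uniform rectangular
factorization of 126 matching the tank aspect; true coordinates can be
supplied as a CSV.  Every 5 s the electrode nearest the mean tracked fish
position (aggregator configurable: mean/median/window-start) is selected,
ties toward the lowest index, and the per-window samples of the selected
electrodes are concatenated into the analysis channel; because selection
windows and analysis segments are both 5 s from t = 0 they align 1:1.
Average swimming speed is path length / elapsed tracked time per window,
in mm/s (the tank is metric and published magnitudes are consistent with
mm/s).  Windows without tracked frames invalidate the segment; windows
with < 2 frames have undefined speed (NaN).

For a moving fish, "the nearest electrode of a window" is only defined
relative to a positional summary; selection robustness is therefore
validated as recovery of the true-trajectory selection from finite-rate
(29.97 fps) tracking with 1 mm Gaussian tracking error (≥95% of windows),
plus exact agreement with exhaustive distance minimization.  The physical
payoff is validated separately: the stitched channel's 1–10 Hz band power
exceeds every fixed electrode's by ≥2× on simulated sessions.

## Dose-effect mixed models

C = ln(x_c + 1) (natural log; log10 is a config switch pending
disambiguation against the deposited data).  Eight candidate structures
add Gaussian random intercepts by concentration, by individual, and/or by
(concentration, individual) to F = β₁C + β₀ + ε.  All fits use maximum
likelihood — AIC across different random structures requires ML, not
REML — with AIC = −2ℓ + 2k, k counting fixed effects, variance
components, and the residual variance; model 1 is ordinary least squares
(equal to the closed-form normal equations to 1e-8).  Inference on fixed
effects is Wald-z with 95% intervals; no df correction is applied
(Satterthwaite is an extension hook).  Because each individual sees one
concentration, "individual" and "(concentration, individual)" intercepts
index the same grouping: models {2,5} and {4,6,7} are
likelihood-equivalent, ties break toward fewer parameters, and fits with
a variance component at zero are flagged `boundary` (returned, excluded
from selection only if the optimizer fails outright).  Piecewise analyses
refit the whole candidate set on the closed dose sections [0,1] and
[1,100] mg/L, the 1 mg/L dose belonging to both.  Significance stars use
the conventional 0.05 / 0.01 / 0.001 bands.

With only 4 dose groups, ML estimates of a concentration-level variance
are poorly determined and Wald-z intervals on β₁ would undercover badly
(measured: ~77% at nominal 95% when half the random variance is placed at
the dose level).  The cohort generator therefore places its single
published random SD (0.384) on the (concentration, individual) term with
the dose-level component at zero — the configuration a fit reports as one
SD, with the dose-level variance on the boundary; measured coverage of
the true slope is then 93–96/100.

## Synthetic generators

All generators are seed-deterministic (identical spec + seed gives
bit-identical output).  Event timing uses Gamma renewal processes
(shape = 1/CV², positive intervals at any CV).  Ventilatory waveforms are
either phase-accumulated cosines (maxima exactly at event times) or
Gaussian pulse trains; ECG beats are band-limited Ricker templates whose
energy sits inside the 5–120 Hz passband, so conditioning preserves
morphology and beat counting is exact at the default 1% noise.
Trajectories are reflected correlated random walks at constant commanded
speed (heading diffusion 1.5 rad/√s); array recordings attenuate the
source as exp(−d/30 mm) — a deliberately simple monotone decay adequate
for selection logic, not a dipole field model.  Cohort builders synthesize
both arms at the published dose-effect scales (restraint ventilation
3.36 + 0.333C with individual SD 0.384, heart rate 2.26 − 0.0529C;
free-swimming ventilation 2.41 + 0.160C; speed following the published
section lines 10.1/23.7 mm/s at 0/1 mg/L and 27.7 − 6.04C above, floored
at 2 mm/s where that line goes negative), clipped to physiological ranges
(ventilation 1–6 Hz, heart rate 1–4 beats/s).  Residual SD for cohort
index tables defaults to 0.8 Hz — the within-individual segment scatter
consistent with index distributions spanning 1–6 Hz — as the published
tables report only the random-intercept SD.

What the generators do **not** emulate: electrode artifacts, body-motion
and fin-movement interference, P/T waves and ectopic beats, tracking
dropouts and identity swaps, dose-dependent interval variability within a
recording (the CV dose effect is exercised at the index-table level), or
pharmacokinetics.  Passing tests therefore demonstrate correctness of the
estimators and inference on signals with known structure at realistic
scales — not robustness to every artifact of real recordings.

## Problem sizes

The test suite and the acceptance script run the full study design where
bookkeeping is asserted (4 doses × 5 individuals × 120 s, both arms) and
reduced designs (2 individuals × 30 s) where only estimator behavior is
exercised; replicate counts are 100–200 for stochastic recovery rates.
These sizes keep the whole suite under a minute of compute beyond the two
full-cohort runs while leaving Monte-Carlo error well inside the asserted
bands.

## Known limitations

- The resampled-tachogram CV is a smoothed index, biased low relative to
  renewal-process truth at high variability (see above).
- The flatness guard does not flag white-noise segments passed through
  the AIC chain.
- Two confounded random terms (models 7, 8) split one variance
  arbitrarily between identical components; only their sum is
  identified, and model 8 frequently fails to converge — honest flags
  are part of the contract.
- Wald-z intervals carry no small-sample df correction; with few dose
  groups, concentration-level variance is weakly identified.
- The default electrode lattice is a geometric assumption; real array
  coordinates should be supplied when known.
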