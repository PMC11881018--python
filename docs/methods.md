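# Methods

This note documents the models and procedures `afgkit` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data can and cannot show.

## Stimuli

A stimulus is a sequence of 50 ms chords. Every tone — figure or ground —
is a sine gated with 10 ms raised-cosine onset/offset ramps
(`0.5·(1 − cos)`), so chords abut without clicks and a gap in the figure is
cued only by the disappearance of its components, never by a broadband
edge.

**Fixed figure.** `coherence` (default 3) distinct frequencies drawn
log-uniformly from the high ground range (180–7246 Hz), repeated over 42
chords. The 6-chord gap is placed uniformly with a 5-chord margin on each
side; the margin keeps the gap detectable and clear of onset/offset
transients (the gap-placement rule and the margin are this package's
choices; only the gap length and track length are fixed constants of the
paradigm).

**Dynamic figures.** A chord-level F0 series is multiplied by the harmonic
set — {2, 3, 4} for the low variant, {5, 10, 20, 30} for the high variant.
Components are checked against the top of the variant's masking range
(3623 / 7246 Hz); an infeasible contour raises an error, and the synthetic
driver resamples contours until feasible. The low set follows the literal
harmonic recipe and does not include the fundamental itself; whether the
original stimuli included F0 is not documented, and this is the
conservative reading.

**Ground.** Per chord, an integer number of tones drawn uniformly from
9–21 (per-chord draw), frequencies i.i.d. log-uniform over the variant's
range. The source battery does not state its ground density; 9–21 is
typical of stochastic figure-ground stimuli and is configurable. Grounds
are drawn independently per interval ("tailored to different figures"),
with no exclusion zone around figure frequencies — no such rule is
documented.

**SNR.** Defined as the per-tone amplitude ratio,
`SNR dB = 20·log10(a_fig/a_ground)`, with the ground tone as unit
reference. This makes the commanded SNR independent of ground density. The
mixture is peak-normalized to 0.95; presentation level in dB HL/SPL is not
modelled. Sample rate defaults to 44.1 kHz.

## Pitch contours

Contours are F0 trajectories at 100 frames/s with unvoiced gaps. The
processing chain mirrors what is needed to turn raw pitch-tracker output
into a figure driver:

1. **Artifact stripping** removes frames outside (10, 300) Hz — the
   sub-audio noise and octave-type errors periodicity analysis introduces.
2. **Conjunction** deletes unvoiced gaps and concatenates voiced runs.
   Interior gaps shorter than `gap_bridge_ms` (50 ms) are linearly
   interpolated instead of deleted; the boundary between "bridge" and
   "delete" is this package's choice — the source describes both gap
   removal and linear interpolation without quantifying the split.
3. **Smoothing** demeans, removes the least-squares linear trend, linearly
   interpolates to 44.1 kHz, applies a minimum-order Kaiser FIR low-pass
   (2000 Hz cutoff, 60 dB stopband, stopband edge 15 % of the way to
   Nyquist) forward-backward for zero phase, samples back to the frame
   grid, and restores trend and mean exactly (the filtered residual is
   recentred to zero first). The 2000 Hz cutoff only has meaning above a
   4 kHz sampling rate, so the upsample-filter-decimate order is forced;
   its purpose is to shave the spikes that interpolation leaves at seam
   joins while passing the contour itself (which lives below ~20 Hz
   modulation) untouched.
4. **Chunking** averages frames into 50 ms windows, one F0 per chord. A
   trailing partial window is dropped below 25 ms and averaged otherwise.

**Synthetic contours** are the sum of a per-sentence centre
(N(131.59, 8²) Hz), a linear declination of 10 % of the mean across the
sentence (the downward drift of read speech), and three random-phase
sinusoids at 0.5–3 Hz whose common amplitude is set so the total variance
matches the target s.d. of 15.61 Hz; values are clipped to
[74.94, 295.44] Hz. These match the descriptive statistics of F0 tracks
from read English sentences but are *not* speech: they have no
microprosody, no segmental structure, and their spectrum is three lines
rather than a 1/f-ish modulation continuum. Tests passing on them verify
the machinery, not perceptual equivalence to sentence-derived figures.

## Adaptive procedures and observers

Transformed up-down staircases: 1-up 1-down (gap task; 6 dB start, 2 dB
steps, 0.5 dB after 3 reversals, 10 reversals total) and 2-down 1-up
(pattern task; 12 dB start, step change after 7 reversals, 22 reversals).
A reversal is logged at the SNR where the movement direction flips; the
first movement defines no reversal. SNR is clamped to [−40, +20] dB
(bounds are this package's choice; none are documented) without logging a
spurious reversal. The score is the median of the last six reversals; the
two fixed-task runs are averaged. The ±5 dB stability screen is read as a
range criterion — max − min of the last six reversals < 5 dB — the only
interpretation that treats all six values symmetrically.

Observers are logistic:
`p(snr) = guess + (1 − guess − lapse)·σ((snr − threshold)/slope)`.
For a 2AFC observer (guess = ½, lapse = 0) the 2-down 1-up track converges
where p² = ½, i.e. `threshold − slope·ln2/2`. A 1-up 1-down track targets
p = ½, which a guess-½ observer only reaches asymptotically at −∞; the
battery's default gap-task observer therefore uses guess = 0, giving the
track a well-defined 50 % target. Observer difficulty depends on SNR only:
the memory load of comparing two patterns, fatigue, and lapses of
attention beyond a constant lapse rate are not modelled, so simulated
pattern-task scores are cleaner than human ones.

## Cohort generator

All variables start standardized on a Gaussian copula:

```
PTA  = 0.746·age + e
AFG  = 0.244·age + 0.373·PTA + e            (latent)
fixed = 0.974·AFG + e
low   = 0.708·AFG + e_low    corr(e_low, e_high) = 0.30
high  = 0.579·AFG + e_high
SIN  = 0.557·AFG + 0.208·PTA + 0.339·age + e   (latent)
WiNw  = 0.816·SIN + 0.039·age + e           (worse-is-higher)
SiB   = 0.745·SIN + e
```

Recorded scores are monotone maps of these: age is the probability
transform onto uniform 18–79 years; PTA, the AFG scores and SiB are affine
maps onto the battery's observed means/s.d.s; the word score is the
logistic squash `1/(1 + exp(−(0.7649 − 0.5095·WiNw)))`, giving a
proportion correct with mean 0.673 and s.d. 0.107 (higher = better, which
is why the analysis layer flips it). SSQ is independent noise on 0–10. A
configurable 6 % of participants are flagged `stable = False` to exercise
the exclusion screen.

**Calibration.** The defaults were chosen by minimizing the expected
number of Spearman pairs falling outside ±0.08 of the published 18-pair
correlation table at n = 10⁴, using the exact copula relation
`ρ_S = (6/π)·asin(ρ_P/2)` (`implied_spearman` exposes it). Two facts shape
the result. First, a single-factor AFG structure forces each task's
correlations with outside variables to be proportional to its loading, and
the printed table is not exactly of that form (e.g. the PTA column decays
faster across fixed → low → high than the SiN column); the best attainable
worst-case deviation is ≈ 0.07, and the chosen defaults trade a uniform
minimax for fewer pairs near the boundary. Second, the direct age → word
path is kept small (0.039): a larger one matches the printed word-score
correlations better but biases what model 3 — which routes all age
influence through the latent SIN — recovers. At 0.039 the population-level
(pseudo-true) bias of every model-3 path is ≤ 0.033, inside the ±0.05
recovery tolerance the tests enforce. The generator *is* the model-3
causal graph; fitting model 3 to its output is a self-consistency check,
not evidence about real listeners.

## SEM engine

RAM parameterisation: directed paths (loadings, regressions) in `A`,
residual (co)variances in `S`,
`Σ(θ) = (I − A)⁻¹ S (I − A)⁻ᵀ` restricted to observed variables. The
normal-theory discrepancy
`F = ln|Σ| + tr(S_sample Σ⁻¹) − ln|S_sample| − p` is minimized with
L-BFGS-B using the analytic gradient (`2·CᵀMW` for paths, `CᵀMC` for
(co)variances, with `M = Σ⁻¹ − Σ⁻¹S_sampleΣ⁻¹`). χ² = (n−1)·F_min with the
ddof-1 sample covariance.

Numerical choices:

* **Identification.** Fixed-marker scaling (one loading per latent fixed
  to 1); observed exogenous variables have their (co)variances fixed to
  sample values (fixed-x). Degrees of freedom = moments − free parameters
  − fixed exogenous moments, so a saturated model has df = 0.
* **Scaling.** The fit runs on s.d.-scaled variables — F and all fit
  indices are invariant under diagonal rescaling of a fixed-marker model —
  and estimates are mapped back to raw units afterwards. This matters
  because the battery mixes a proportion (variance ~0.01) with dB scores
  (variance ~100).
* **Cliff recovery.** F is +∞ outside the positive-definite region, and
  L-BFGS-B's line search can stall against that cliff with a large
  gradient remaining. After each run the projected gradient is checked; if
  it is large, a backtracking (Armijo) step along −∇F restarts the
  quasi-Newton iteration. Up to 5 jittered multi-starts on outright
  failure; start values come from indicator–marker correlations.
* **Convergence / boundaries.** Gradient tolerance 1e−8. Variances are
  bounded below at ~0; a fitted residual variance at the boundary is
  flagged as a Heywood case with a warning (the default cohort's SIN
  residual of 0.10 genuinely sits near the boundary at n ≈ 159, so the
  flag is common at study size and benign).
* **Standard errors** from the inverse numerical Hessian of
  `((n−1)/2)·F`; **standardized solutions** rescale by model-implied node
  s.d.s. **Baseline** for CFI/TLI is the independence model (closed form).
  **SRMR** is the RMS of correlation residuals including the standardized
  variance residuals on the diagonal. **Bootstrap**: refits on
  `floor(0.95·n)`-row subsamples drawn without replacement (100 reps),
  RMSEA distribution plus per-path CI = mean ± 1.96·s.d.
* **Robust (Satorra–Bentler) scaling is not implemented.** The synthetic
  cohorts are Gaussian-copula data, where the correction is asymptotically
  inert; fits to strongly non-normal real data will overstate χ².

The model roster (`build_paper_models`): model 1 — word score on latent
AFG (fixed task as marker, low/high with a residual covariance), PTA and
age; model 2 — the same with the sentence score; model 3 — latent SIN
(word score as marker, sentence score) on AFG, PTA, age; CFA — two
correlated factors including the self-report scale as a third SIN
indicator. Age and PTA enter as fixed-x exogenous variables whose sample
covariance carries the age–PTA association.

## Stepwise regression and correlations

Forward selection on OLS partial F with SPSS defaults (entry p < .05,
removal p > .10), ties broken by larger absolute partial correlation,
collinear candidates dropped with a warning; coefficients are standardized
(fitted on z-scores). Spearman correlations are pairwise-complete with
average-rank ties and t-approximation p-values; Holm–Bonferroni is the
step-down rule with an explicit family-size argument — the battery's
7-variable analysis uses m = 21 unique pairs (a 7 × 7 count would
double-count symmetric pairs).

## Determinism

Every stochastic entry point takes a `numpy.random.Generator`. Sessions
fan a master seed out through named paths
(participant → task → run → trial) via `SeedSequence` spawn keys, so any
branch is reproducible in isolation and full battery reports are
byte-identical across reruns.

## Problem sizes in the test suite

The suite verifies stimulus constants on 1000 generated ground tracks and
500 dynamic stimuli; staircase convergence on 200 runs per rule (within
1 dB of the 70.7 % / 50 % targets); SEM recovery on one 10⁴-row cohort
(±0.05 standardized); and cohort calibration on one 10⁴-row cohort
(±0.08 per Spearman pair). These sizes make the checks sharp while the
whole suite runs in about a minute.

## Known limitations

* Synthetic contours and observers idealize their real counterparts (see
  above); battery-level simulations demonstrate procedure correctness, not
  human performance.
* The generator reproduces the published correlation *structure* only as
  closely as its single-factor form allows (worst pair ≈ 0.07); it is a
  test harness, not a population model.
* No ordinal/WLSMV estimation, no missing-data FIML, no mean structure in
  the SEM; no headphone-calibration or presentation-level modelling in the
  renderer; no real-time presentation or response collection.
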