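# Methods

This note documents the models, estimators, defaults and numerical
choices in `alphagate`, and what the synthetic validation does and
does not establish about real data.

## Forward model (synthetic cohorts)

Each epoch is the sum of two stationary processes, in microvolts:

* **Background**: 1/f noise (power exponent 1, band-limited 0.5–40 Hz),
  RMS 5 µV.  The exponent is the standard broadband EEG value; it is a
  modelling choice, not an estimate from any dataset.
* **Alpha**: 8–12 Hz narrowband Gaussian noise with raised-cosine band
  edges (1 Hz roll-off), multiplied by a slow (< 1 Hz) positive
  amplitude envelope clipped to [0.25, 1.6], base RMS 6 µV.
  Narrowband noise rather than a sinusoid gives wavelet power
  estimates realistic variance; the amplitudes put peak-to-peak epoch
  excursions under the 150 µV rejection bound while keeping the
  alpha-band signal-to-background power share at ~0.94.

Regional structure: temporal channels (T7, F7, CP5, T8, F8, CP6) have
their alpha amplitude multiplied by `surge_gain` (default 2.0, ≈ 6 dB)
inside the surge window (default −65 to 127 ms); central-frontal
channels (F3, Fz, F4, C3, CP1, C4, CP2) are multiplied by
`cf_suppression_gain` (default 0.7, ≈ −3 dB) after onset.  The default
gains are plausible event-related alpha modulations of a few dB; no
published per-subject values exist to anchor them.

Blink artifacts are ~300 ms positive half-cosines, amplitude
N(300, 40) µV on VEOG with a frontal-dominant scalp map (0.6 at Fp,
0.35 frontal, 0.15 fronto-central), injected per epoch with
probability `artifact_rate` (default 0.05).

Clinical tables anchor each (outcome × group) cell to published group
means/SDs for SIS-ADL, FIM, NEADL, WMFT-Time and WMFT-Strength.  The
change-score SD is 0.4 × the pre SD (not reported anywhere; a moderate
test–retest spread).  Scores are clipped to instrument ranges
(SIS-ADL 0–100, FIM 18–126, NEADL 0–66) after noise addition; clipping
slightly attenuates extreme group means and planted correlations (see
below).

Coupling: each subject carries a standardised latent change z.  Every
outcome change is ρ·z + √(1−ρ²)·ε with the group's planted ρ; the
post-session temporal surge gain is shifted by 1.5 dB per SD of z, so
the EEG-recovered temporal index change tracks z.  Planted outliers
displace a subject's (z, outcome) pairs 4.5 robust SDs along the
bivariate minor axis — points the box-plot rule should flag.
Everything planted is returned in `GroundTruth`.

What the generator does **not** emulate: volume conduction and
channel covariance, non-stationary background (drowsiness, movement),
lesion-dependent topography asymmetries, non-blink artifacts (EMG,
electrode pops), or item-level clinical score structure.  Passing
tests therefore demonstrate estimator correctness and calibration
under the assumed signal model, not robustness to every failure mode
of patient EEG.

## Preprocessing

* Band-pass 0.5–40 Hz: zero-phase (forward–backward) Hamming-window
  FIR, transition 0.5 Hz at the low edge; stopband ≥ 20 dB at low/2
  and 2·high by construction, verified by test.
* Line noise: sliding-window (4 s, half-overlap, Hann overlap-add)
  least-squares regression of the 50/60 Hz sine and cosine, subtracted.
  This tracks slow amplitude/phase drift like the CleanLine approach
  and leaves neighbouring frequencies intact, unlike a fixed notch.
* Epoching: half-open window [−1.0, +1.0) s → exactly 1000 samples at
  500 Hz with the t = 0 sample included.  "Contralesional response"
  means a key-press by the hand contralateral to the lesioned
  hemisphere; the convention is one named constant
  (`montage.CONTRALESIONAL_MEANS_HAND_OPPOSITE_LESION`) and flippable.
* Reference: subtract the mean of TP9/TP10 (32-channel actiCAP mastoid
  positions) from every EEG channel; EOG channels untouched.
* Ocular removal: pluggable linear unmixing (default scikit-learn
  FastICA, seeded); components whose time courses correlate with any
  EOG channel above |r| = 0.7 are dropped before reconstruction.  On
  decomposition failure, or on request, plain least-squares EOG
  regression is used instead.  Truncating the decomposition (default
  15 components) makes reconstruction slightly lossy; property tests
  use full rank.
* Artifact gate: epochs with EEG peak-to-peak > 150 µV (a conventional
  bound — no published criterion exists for this step) are flagged
  after ocular cleanup; subjects with < 50 clean epochs per session
  are excluded with an explicit error carrying the count.

## Time–frequency estimation

Morlet wavelets, 5 cycles at every frequency, 1 Hz steps over 8–12 Hz,
truncated at ±3.5 σ_t, peak-normalised in the frequency domain.
Signals are zero-padded to `pad_ratio` (default 4) times their length
before FFT convolution.  Coefficient amplitudes are doubled (one-sided
convention) and squared, so a sinusoid of amplitude A recovers power
A² (verified to < 5%; in practice < 0.1%).  Power is averaged over
clean epochs, then scaled as 10·log10(P / median) with the median over
valid time samples per channel × frequency within the
participant-session; the transform is exactly invariant to channel
gain.  Samples within one wavelet half-width of either epoch edge are
marked invalid and refused by window reductions.

Two estimator properties worth knowing:

* With constant cycles, bandwidth grows ∝ frequency, so white-noise
  band power rises linearly across 8–12 Hz.  This is inherent to the
  amplitude-recovery normalisation; band averages of narrowband alpha
  are unaffected in practice.
* The wavelet's temporal envelope (σ_t ≈ 80 ms at 10 Hz) smooths any
  amplitude step.  A planted gain confined exactly to the −65–127 ms
  window is therefore recovered at only ~70% of its nominal dB value
  when measured in that same window; the dB-recovery validation uses a
  surge window that extends ~150 ms past the measurement window so the
  step is fully covered, and measures the index against a pre-surge
  baseline window so the participant-level median (which the surge
  itself shifts) cancels.  Under those geometry conditions a planted
  gain g is recovered at 20·log10(g) within Monte-Carlo error.

## Window selection

Paired contrasts use pointwise t statistics; adjacent samples
exceeding the two-sided p = 0.05 t-quantile (the default
cluster-forming threshold — configurable; no published value exists)
form clusters, whose summed t is referred to the permutation null of
the maximum |mass| over 1000 sign-flip (paired) or label-shuffle
(unpaired) permutations, with the +1 correction so p > 0.  For ≤ 16
paired subjects all 2^n sign patterns can be enumerated, making the
p-values exact; the Monte-Carlo path is verified against that
enumeration.  When no cluster survives, the pipeline falls back to the
canonical windows −65–0 and 0–127 ms, which are treated as configured
constants: which experimental conditions produced them originally, and
at what threshold, is not recoverable, so they are defaults rather
than reproducible outputs.  In `analysis_windows_ms="derive"` mode the
pooled pre-vs-post temporal-region contrast is clustered and the
first/last significant windows feed the temporal and central-frontal
indexes respectively.

## Indexes

Region-window means are unweighted over the fixed bilateral channel
sets and the closed window on the sampling grid.  The alpha ratio is
computed on the median-scaled dB values (the two quantities the
composite is defined from).  Because median-scaled dB values can pass
through zero, the denominator is floored at ε = 0.1 dB (sign
preserved, result flagged, never fatal); ratio values for
participants near the floor should be interpreted cautiously — this
hazard is intrinsic to defining a ratio of dB quantities and is the
reason the per-cell `ratio_flagged` column exists.

## Skipped correlation

MCD with subset size h = ⌊(n+3)/2⌋ (maximal breakdown at p = 2) is
solved by exhaustive enumeration for n ≤ 15 — exact at the study's
n = 12, where C(12, 7) = 792 subsets — and by concentration-step
refinement from 200 random starts beyond that (verified to match the
exhaustive optimum at desk scale).  Robust distances under the MCD
scatter feed the box-plot rule d > q3 + 1.5·(q3 − q1) with
ideal-fourths quartiles; a singular scatter falls back to scaled
Euclidean distances.  Pearson's r and t = r√(n−2)/√(1−r²) are computed
on retained pairs; r = ±1 yields t = ±∞, flagged rather than fatal.

The 95% CI is a percentile bootstrap over resamples of the retained
pairs with outlier flags frozen (re-flagging per resample is
deliberately not done: flag churn at n ≈ 10 makes the interval
unstable).  The *plain* (2.5, 97.5) percentile interval is badly
anticonservative for Pearson's r at n = 12 — measured null rejection
≈ 12% — so the default uses the standard small-sample-adjusted
cut-points (≈ 1.2/99.0 below n = 40, stepping toward 2.5/97.5 by
n = 250), which restore ≈ 5% null rejection; the literal construction
remains available as `ci_quantiles="plain"`.  Significance is decided
solely by whether 0 lies outside the CI; t is reported but is not the
decision rule.  No multiplicity correction is applied across the 45
battery cells, matching the analysis this package mirrors; an FDR
column can be added downstream.

Known recovery behaviour at n = 12: E[r̂] ≈ ρ(1 − (1−ρ²)/(2(n−1)))
(≈ 0.583 for ρ = 0.6), and box-plot trimming plus instrument-range
clipping each shave a further ~0.02, so recovered means of ~0.54–0.56
against a planted 0.6 are expected, not a defect.  Detection-style
claims (e.g. "the planted cell has the largest |r| among nine cells")
are fundamentally limited at this sample size: null |r| has SD ≈ 0.30,
so the expected maximum of eight null cells ≈ 0.57, comparable to the
planted effect — the best achievable rate is ~63% even for an ideal
estimator.

## Group statistics

The mixed ANOVA uses the classical SS decomposition for one
between-subject factor (3 groups) and one within-subject factor
(pre/post): Group is tested against subjects-within-groups, Time and
the interaction against time × subjects-within-groups; with two
within levels sphericity is moot.  df are (2, 33) and (1, 33) at the
3 × 12 × 2 design.  The decomposition is verified against a
least-squares projection oracle and against pingouin.  KS normality
uses estimated parameters (anti-conservative, as commonly run); Levene
is mean-centred.  The Friedman statistic is computed from the rank
formula with tie correction so the two-condition case (where scipy
refuses) works and reduces to a sign-test-like statistic.  Bonferroni
post-hocs multiply the paired-t p by the number of comparisons, capped
at 1.

## Problem sizes used in validation

Calibration and recovery checks run at the study's own design (n = 12
per group) with replicate counts chosen for stable Monte-Carlo error
on one CPU: 200–500 null replicates for CI calibration, 500 replicates
× 1000 permutations at 100 timepoints for cluster family-wise error,
100 cohort replicates for battery recovery, and 10–16 subjects × 16
epochs for dB-recovery through the full wavelet chain.  The end-to-end
pipeline validation simulates 36 subjects × 2 sessions × 55 epochs.

## Known limitations

* No spatio-temporal (channel-adjacency) clustering or TFCE; the
  cluster test is over time only.
* The ICA stage estimates components per subject-session on epoched
  data; no bad-channel interpolation or impedance handling exists.
* Bilateral region averaging is fixed (no lesion-side flipping), and
  the indexes are sensor-space only.
* BrainVision support covers the float32 multiplexed variant the
  writer emits; exotic header options are untested.
* The ratio index is unstable for participants whose central-frontal
  dB sits near zero; flagged values should be screened before
  correlation.
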