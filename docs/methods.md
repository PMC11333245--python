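# Methods

This note documents the models and numerical choices behind `sleephrv`:
what the pipeline computes, what the synthetic generator emulates (and
does not), and where genuinely open design decisions were resolved.

## Pipeline overview

A recording flows through five stages:

1. **ECG preprocessing** — variance normalization in 10 s blocks,
   residual-variance screening of non-useful segments, Pan–Tompkins
   R-peak detection.
2. **Series construction** — excision of wake epochs and non-useful
   segments from the beat series, merging of the remaining runs onto a
   continuous time base, cubic-spline interpolation of the RR tachogram
   at 4 Hz, and extraction of the MM fluctuations (from the local maxima
   of the tachogram).
3. **MF-DFA** — q-order fluctuation functions, generalized Hurst
   exponents H(q), mass exponent τ(q) = qH(q) − 1, singularity spectrum
   D(h), and the two summary indices width(D) and argmax_h D(h), with
   shuffle surrogates to classify the type of multifractality.
4. **Quarter-wise HRV indices** — meanRR, sdRR, rmsRR (RMSSD), meanMM,
   sdMM, Welch-normalized LFnu/HFnu/LF/HF and the DFA exponent α = H(2),
   on four equal quarters of retained sleep time.
5. **Features and separability** — per-record feature matrix
   (9 indices × 4 quarters), PCA on variance-normalized columns, and
   centroid/silhouette/nearest-centroid separability summaries, plus
   rank-sum and Brown–Forsythe two-group comparisons.

## MF-DFA estimator

The profile is the cumulative sum of the mean-centred series. For each
window size `s`, non-overlapping windows are taken from the start *and*
from the end of the profile (2⌊N/s⌋ in total) so the tail beyond
⌊N/s⌋·s is never discarded. Per window, the residual variance F²(v,s)
about a least-squares polynomial (linear by default) is computed with a
precomputed pseudo-inverse, which makes the vectorised implementation
bit-identical to an explicit-loop evaluation (asserted to 1e−10 in the
tests). The q-order fluctuation function uses the canonical two-level
form — mean of [F²]^{q/2} to the power 1/q, with the log-average at
q = 0 — and H(q) is the ordinary least-squares slope of log F_q(s) vs
log s over the whole configured scale range, with the fit R² reported
per q. Windows with exactly zero residual variance are excluded for
q ≤ 0 (they have no finite contribution there).

The derivative h = dτ/dq uses centred finite differences on the
(non-uniform) seven-point q grid with one-sided ends; no spline
smoothing is applied, trading smoothness for exact reproducibility.
τ concavity is checked through the monotonicity of successive chord
slopes; violations beyond 0.05 flag the spectrum `reliable=False`
rather than raising, since small non-concavities are ordinary
estimation noise.

Validation anchors the estimator to two exactly solvable inputs:

* the deterministic binomial cascade with multiplier `a`, whose
  generalized Hurst exponents are
  `H(q) = 1/q − ln(aᑫ + (1−a)ᑫ)/(q ln 2)` — recovered within ±0.05 at
  depth 16 for q ∈ [−5, 5];
* spectrally shaped monofractal noise, for which H(q) is flat and the
  spectrum width collapses (< 0.15 at N = 2¹⁷).

### Scale ranges

Two conventions coexist:

* `default_scales(n)` — 20 log-spaced integer window sizes in
  [16, min(2048, n/4)] **samples**; this is the dimensionless default of
  the generic estimator and what the cascade/monofractal oracles use.
* `scales_seconds(n, fs)` — windows covering **16 s to 2048 s** of a
  sampled series (64–8192 samples at 4 Hz). All sleep-series analyses
  (RR, MM, quarter-wise α) use this convention. The reason is physical:
  the RR/MM series are spline-interpolated from events ~0.9 s / ~4 s
  apart, so windows much shorter than ~16 s mostly measure the spline,
  not the signal; 16 s–34 min spans a few breathing cycles up to a third
  of a sleep cycle. With sample-unit scales starting at 16 (4 s), the
  interpolation inflates the apparent exponents of even a shuffled
  series to ≈0.8 across the q grid, which contradicts the white-noise
  behaviour surrogates must show; with the seconds convention the
  surrogate exponents centre on 0.5 with the familiar finite-size
  asymmetry (H(−5) ≈ 0.7, H(+5) ≈ 0.45).

### Surrogates and multifractality type

Shuffle surrogates permute the beat-level RR values (uniform seeded
permutation; beat times are rebuilt as cumulative sums, so the value
multiset, mean and variance are preserved to the round-off of the
cumulative sum). Multifractality is attributed to long-range
correlations when the surrogate-ensemble H(q) is indistinguishable from
0.5 (±0.1 per q) while the original spectrum is wider than the
surrogate's; to a broad value distribution when original and surrogate
H(q) coincide; and to neither when the original width falls below 0.15.
The width floor equals the monofractal width bound observed at large N;
the ±0.1 band reflects the seed-to-seed spread of surrogate exponents
at the ~10⁵-sample series lengths this package targets.

## ECG screening and R-peak detection

Each 10 s block is divided by its standard deviation. A block is usable
ECG when the variance of its residual — after removing a linear trend
*and* the smooth morphology component (zero-phase 4th-order Butterworth
low-pass at 20 Hz) — lies in [0.04, 0.2]: flat or lost-contact blocks
fall below the band, broadband motion artifact above it. The two-part
trend is this package's operationalisation of "trend removal": a linear
fit alone cannot separate clean ECG from artifact after unit-variance
normalization, because every non-degenerate block then has residual
variance ≈ 1 regardless of content. The first and last 20 minutes are
always discarded. The band edges are treated as given constants
(inclusive at both ends); they were originally tuned on manually
annotated sleep recordings that are not public, so they are not
re-derived here.

R-peak detection is a canonical Pan–Tompkins chain (5–15 Hz band-pass,
derivative, squaring, 150 ms moving-window integration, adaptive
signal/noise thresholds with search-back, 250 ms refractory period),
with peak times refined to the raw-signal extremum. Two robustness
guards were added to the textbook thresholds: the running signal
estimate is clamped to at most 4× its previous value per update, and it
decays geometrically towards the noise estimate whenever a beat is
overdue and even search-back fails — without these, a single
motion-artifact burst strands the threshold above the signal and the
detector never recovers. On artifact-free synthetic ECG the detector
places ≥99% of peaks within 10 ms of ground truth at every supported
rate (100–512 Hz).

## MM fluctuations

The MM series is built from the local maxima of the beat-level RR
sequence (strict increase on the left, weak decrease on the right, so
plateaus collapse deterministically to their first index). The
**default mode** carries the time gaps between successive maxima — a
quantity with the magnitude of a respiratory period (~4 s), which is
what the meanMM/sdMM indices summarise; an **envelope mode** (RR value
at each maximum) is retained as an option. Gap values are attached to
the later maximum's time and cubic-spline resampled onto the 4 Hz grid.
Since RR maxima recur roughly once per breath, the gap series samples
the instantaneous respiratory period, which is why its mean tracks
respiratory behaviour and its variability grows in REM-rich sleep.

## Quarter-wise indices

Quarters are equal-duration contiguous segments of *retained* (merged,
post-excision) sleep time, not wall-clock time — the indices are
computed after filtering, so the quarters must partition what remains.
meanRR/sdRR/rmsRR are beat-level (RMSSD is defined on successive beat
differences, not on the interpolated series); meanMM/sdMM use the
beat-level gap values before resampling. The Welch PSD uses eight
segments with 50% overlap and Hamming windows on the mean-removed 4 Hz
series (no additional detrending, no zero padding, one-sided), and the
band powers LF [0.04, 0.15) Hz and HF [0.15, 0.5] Hz are normalized so
LFnu + HFnu = 1 exactly. The HF upper edge is 0.5 Hz (not the more
common 0.4 Hz), which matters for breathing rates above 24/min.
α = H(2) shares the MF-DFA code path and the seconds-based scale range,
capped at a quarter of the quarter length.

## Synthetic generator

The generator is the package's test bed: it emulates the statistical
structure of sleep HRV well enough that every pipeline stage can be
validated against known ground truth, without claiming physiological
realism beyond that.

Instantaneous RR is additive:
`baseline + drift·t/T + LF sinusoid + RSA sinusoid + fractal noise`,
evaluated at accumulated beat times and clipped to (0.3, 2.0) s.
Components and their defaults:

* **Group presets** (first-quarter mean RR / overnight lengthening /
  respiratory period): 0.90 s/+0.09 s/4.0 s for non-pregnancy,
  0.83/+0.06/3.7 for early, 0.78/+0.02/3.7 for middle pregnancy —
  the observed cohort magnitudes. The LF amplitude is also a preset
  (0.043/0.025/0.028 s) so the normalized LF share reproduces the
  observed ordering (sympathovagal balance highest outside pregnancy).
* **RSA**: 0.07 s amplitude in NREM, halved in REM (vagal drive and
  breathing coupling weaken in REM). These values place RMSSD in the
  upper part of the observed range; they are deliberately generous so
  respiratory maxima dominate the maxima detection.
* **Fractal component**: Gaussian noise spectrally shaped to a target
  DFA exponent (default H = 1.0, i.e. 1/f), multiplied by a smoothed
  multiplicative-cascade volatility (asymmetry 0.7, depth 14, tempered
  by exponent 0.3 because the raw cascade's log-values have SD
  √depth·|ln(a/(1−a))|/2 ≈ 1.6 — far too intermittent to add, rather
  than dominate, the signal). Amplitude 0.035 s. The volatility
  modulation makes the scaling q-dependent in a way a shuffle destroys:
  multifractality carried by correlations, not by the value
  distribution.
* **Respiratory period process**: the period is modulated by a
  persistent (target H = 1.2) cascade-modulated process with 30% SD,
  amplified ×2.8 in REM (breathing is less stable there) and drifting
  +4% across the night. Two normalisations matter:
  (1) wander slower than ~25 min is removed, otherwise the record-mean
  breathing rate itself becomes a large random effect and ensemble
  means of meanMM are unstable;
  (2) the process is scaled so the preset period equals its *harmonic*
  mean. Inter-maximum gaps sample the period once per cycle —
  short-period stretches contribute more gaps — so the gap mean
  estimates the harmonic, not the arithmetic, mean; without the
  correction meanMM sits ≈ cv²·period ≈ 0.25 s below the preset.
* **Hypnogram**: ~90 min NREM/REM cycles with REM growing across the
  night and occasional one-epoch awakenings; deterministic per seed.
  It exists to gate amplitudes and provide wake epochs for the excision
  logic, not to model sleep architecture.
* **ECG**: Gaussian R wave (unit amplitude, σ = 12 ms) and T wave per
  beat over baseline wander and sensor noise (SD 0.05), with labelled
  motion-artifact (noise SD 3) and flat-line windows injected at a
  configurable hourly rate. The noise floor is chosen so that clean
  blocks land inside the [0.04, 0.2] screening band after
  normalization — i.e. the generator emulates a recording the screening
  rule was designed for.

Everything is seeded through independent substreams of the config seed;
identical configs give bit-identical outputs.

**What the generator does not emulate** — and hence what passing tests
do not demonstrate about real recordings: ectopic beats and arrhythmia,
realistic P/QRS/T morphology and its lead dependence, apnea/desaturation
events, sleep-stage-specific spectral signatures beyond the RSA/jitter
gating, and between-subject covariance structure (each record is an
independent draw around the group preset). Cohort-level numbers from
real polysomnography (the CAP and nuMoM2b databases) are reproduced
only in the calibrated magnitudes listed above, not re-derived.

## Problem sizes

The test suite and the acceptance script run the full pipeline on 7 h
recordings (~29 000 beats, ~10⁵ samples at 4 Hz): ensembles of 10
records for the calibration and shuffled-RR checks and 20 mixed-group
records for the MM multifractality checks, matching the scale of the
cohorts the pipeline is meant for while keeping a complete run in the
low minutes on one CPU.

## Known limitations

* The MM definition is the gap series by default; analyses that expect
  the envelope convention must opt in, and the two are not comparable.
* H(q) is fitted over the full scale range; sleep-cycle crossovers can
  bend log F_q(s), which is why the per-q fit R² is reported, but no
  automatic crossover detection is attempted.
* The Mann-Whitney/Brown-Forsythe helpers cover two groups only; the
  factorial repeated-measures analysis of a full cohort design is out
  of scope and should be done with standard statistical tooling.
* The EDF reader is a thin optional wrapper (`mne`); annotations other
  than a stage-per-epoch text hypnogram are not parsed.
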