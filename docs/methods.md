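# Methods

This note documents the analysis model, its assumptions, the defaults and
the numerical choices, in the package's own terms. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Recording model and I/O

A `Recording` is a channels × time array of microvolt samples at a single
sampling rate with unique labels and a per-channel modality (EMG/EEG).
NaN samples are rejected at ingestion. Streams recorded at different rates
(EMG nominally 2148 Hz, EEG 500 Hz) are aligned by start time, truncated
to their overlapping interval, and linearly interpolated onto a uniform
1 kHz grid for offline analysis. Linear interpolation was chosen over
polyphase/FFT resampling because it is exactly reproducible, introduces no
ringing at trial boundaries, and leaves content below 100 Hz essentially
untouched (the property suite checks < 2% relative RMS error for
sub-100 Hz sinusoids resampled 2148 → 1000 Hz; the highest band edge used
in coherence analysis is 100 Hz).

EDF support is a self-contained minimal codec (single data record,
per-channel physical ranges, 16-bit quantization — amplitudes are exact to
`(max − min)/65535` per channel). CSV + YAML sidecar is the lossless
fixture format, since EDF cannot represent all rate/duration combinations
exactly.

## The extensor ratio

Preprocessing: 4th-order Butterworth 15–450 Hz applied forward–backward
(zero phase), full-wave rectification, division by the per-muscle maximum-
grasp reference. The reference is the 95th percentile of a 250 ms moving
average of the rectified calibration signal, maximized over calibration
repeats; the percentile-of-smoothed estimator is robust to isolated
spikes but assumes the calibration segment is several times longer than
the 250 ms window. Per trial the normalized envelope is averaged over the
final 3 s of the 4 s hold, and

ER = mean_ext / (mean_ext + mean_flex).

`EMG_ext`/`EMG_flex` are single channels per muscle group, the ones with
the largest hold/rest RMS ratio — mirroring the online feedback-channel
rule; averaging both channels of a group is available by calling
`compute_er` on any other means. ER is scale-invariant, so the
normalization reference cancels whenever both groups share the same
amplitude scale; with per-muscle references it corrects for electrode-gain
differences instead. Both muscle groups silent raises an error rather than
returning 0/0.

The screening operation applies the enrollment rule — hold ≥ 30% of the
prerecorded maximum for 10 trials of 4 s — with an inclusive threshold
(≥, guarded by a 1e-12 float-accumulation epsilon) and an all-trials-pass
criterion, the strictest reading of the rule.

The game control signal is the regularized instantaneous ratio
`(ext + ε/2)/(ext + flex + ε)` (default ε = 0.02 fraction-of-maximum):
continuous everywhere, 0.5 at rest, converging to the raw ratio when
activity dominates ε.

## Corticomuscular coherence

EEG: 4th-order zero-phase Butterworth 5–100 Hz → bad-channel removal →
common-average re-reference over retained channels → per-channel z-score.
The per-sample cross-channel mean is exactly zero after the re-reference;
per-channel z-scoring afterwards necessarily breaks that identity, which
is why the re-referenced intermediate is exposed (`zscore=False`).

Bad channels: excess kurtosis per channel, z-scored across the montage
with median/MAD (robust) scaling, threshold z > 5, plus flatlines. A
non-robust z-score is algebraically bounded by (n−1)/√n across n channels
— below 5 for any montage under 27 channels — so a single artifactual
channel would mask itself; the robust scaling restores the intended rule.
On all-Gaussian montages the false-flag rate is a few percent (checked
over 100 seeds).

EMG for coherence: magnitude of the analytic (Hilbert) signal of the
bandpassed EMG, z-scored. The envelope reading is the default because the
cortical drive in the generator (and plausibly in practice) modulates EMG
amplitude; the real part of the analytic signal is exposed as
`hilbert_mode="analytic_real"` for the narrowband-oscillation reading.

Coherence: Welch magnitude-squared coherence, Hann window, 128 ms segments
(128 samples at 1 kHz, 7.8125 Hz resolution), 75% overlap, computed over
the concatenated hold epochs only — coherence during contraction is the
quantity of interest, and rest epochs would dilute it. Concatenating
epochs introduces a handful of discontinuous window positions; with 12 × 4 s
holds (≈ 375 windows) their effect is negligible.

Confidence level: `1 − α^(1/(L−1))` with α = 0.05. The adjusted segment
count L defaults to the number of *equivalent independent* segments,
`floor(N/W)`, because the formula assumes independent segments. This
choice is conservative: for Hann windows at 75% overlap the
variance-equivalent segment count is roughly twice `floor(N/W)`, so the
measured null exceedance is well below α (the raw overlapped count, also
exposed via `segment_count="overlapped"`, understates the threshold and is
anticonservative — measured ≈ 22% null exceedance). Consumers needing
exact calibration should treat the confidence level as an upper bound on
the false-positive rate.

Band summary: per-bin Fisher scores `atanh(sqrt(coh))·sqrt(2L)`
(approximately standard normal under independence, since the Fisher
transform of coherence has variance ≈ 1/(2L)), Stouffer-combined over the
12–30 Hz bins; with 128 ms windows the band contains the 15.6 and 23.4 Hz
bins. The per-hemisphere score pools the in-band bins of both muscles of
the task's group into one Stouffer combination (one number per hemisphere
is required by the laterality index; per-muscle summaries then averaging
is the main alternative and differs only by bin weighting). The band peak
is taken on raw coherence with lowest-frequency tie-break. Coherence is
clipped to 1 − 1e-12 before `atanh` so self-coherence cannot produce an
infinity.

Electrode fallback: if C3/C4 was removed as bad, the neighbour priority is
C3 → CP1, FC1, CP5, FC5 and C4 → CP2, FC2, CP6, FC6 (centro-parietal
first, closest to the hand knob); deterministic and exhausts to a montage
error.

Laterality: `(ipsi − contra)/(ipsi + contra)` on the Stouffer band scores;
positive = ipsilesional dominance; antisymmetric under hemisphere swap and
bounded in [−1, 1] whenever both scores are nonnegative.

## Group statistics

Paired t (two-sided, df = n − 1) via `scipy.stats.ttest_rel`; all-equal
differences with nonzero mean are flagged as infinite-t rather than
erroring. Pearson r with p from the exact t transform (df = n − 2).
BH step-up adjustment via statsmodels, cross-checked in the tests against
a brute-force implementation of the definition. SIS subscales (items 1–5)
are normalized with the instrument's standard transformation
`(mean item − 1)/4 × 100`; Function is the unweighted mean of normalized
ADL and Hand Function. Correlation matrices form one BH family per matrix
per timepoint, and the family name is recorded in every cell so the
correction is auditable. Paired tests across outcome domains are
deliberately unadjusted (treated as independent domain-specific
hypotheses). Missing data are handled complete-case per test and reported
explicitly.

## Synthetic data: what it emulates, and what a green test establishes

The generator reproduces the recording protocol — 12 trials of 4 s hold +
6 s rest (2 s lead-in), EMG at 2148 Hz, EEG at 500 Hz, tracking target
15% — with known ground truth:

* **EMG**: Gaussian carrier bandpassed 20–450 Hz (so the 15–450 Hz
  analysis filter passes it essentially unchanged), multiplied by an
  amplitude envelope `baseline + level × gate(t)` with 100 ms cosine
  ramps. Default levels 0.45 (extensor) / 0.15 (flexor) give a programmed
  ER of 0.75; the resting baseline of 0.02 biases recovered ER toward 0.5
  by ≈ 0.015, well inside the ±0.05 recovery band. Per-muscle gain
  multipliers (1.0/0.8 within each group) make the feedback-channel
  selection identifiable.
* **Calibration**: two 3 s bursts at envelope 1.0 — the amplitude scale
  levels are programmed against — so the max-grasp estimator recovers the
  same normalization constant for every channel.
* **EEG–EMG coupling**: one unit-variance narrowband Gaussian source
  (2 Hz bandwidth around 20 Hz; a pure sine would make neighbouring-bin
  coherence estimates degenerate), added to each hemisphere's channels
  with that hemisphere's gain and a *focal spatial profile* (loading 1.0
  on C3/C4, 0.3 on neighbours), plus white sensor noise (SD 1). The focal
  profile is essential, not cosmetic: with uniform loading the
  common-average reference subtracts the montage-mean source and leaves
  equal-magnitude source content in both hemispheres, making laterality
  unidentifiable in principle. The same source modulates the EMG hold
  envelope as `1 + 0.4·s(t)` (clipped at zero), so the Hilbert envelope
  recovers it. The per-bin coherence ceiling `g²σs²/(g²σs² + σn²/c)`
  (c = source PSD concentration) further reduced by the envelope-
  extraction SNR is approximate; only monotonicity in the gain is exact,
  and tests/acceptance rely on monotonicity, sign and a ±0.15 symmetry
  band rather than the closed form.
* **Artifacts**: chosen channels replaced by sparse high-amplitude spike
  trains (huge kurtosis) or flatlines.
* **Clinical tables**: per-measure Gaussian pre scores and paired
  differences, with programmed pairwise change-score correlations imposed
  through a Cholesky factor (non-positive-definite structures are
  rejected). Defaults mirror a 9-participant cohort with the published
  pre-training means/SDs and zero effects.

Not emulated: motor-unit physiology, volume-conduction head geometry,
1/f EEG background, spasticity/co-contraction dynamics, missing-data
patterns, floor/ceiling effects of the clinical instruments. A green
parameter-recovery test therefore establishes that the *analysis chain is
correct and unbiased under the stated signal model*, not that it is robust
to every pathology of real recordings.

All generators are pure functions of (config, seed); a master seed spawns
independent substreams per component via `numpy.random.default_rng` seed
sequences.

## Reference values in the acceptance suite

The worked-example suite re-derives two-sided p-values from published test
statistics of a nine-participant pre/post design (df = 8 paired, df = 7
for correlations). Printed statistics are rounded to 2 dp, so each check
is rounding-aware: the printed p (±0.0005) must intersect the p-interval
implied by the statistic's ±0.005. Two reference cells are internally
inconsistent under any statistic in their rounding interval (t = 3.20 with
p printed 0.012, exact 0.0126; t = 0.99 with p printed 0.348, exact
0.3512 — the source evidently computed p from unrounded statistics); for
those two the suite pins the exactly computed value. Several published
correlation p-values are multiplicity-adjusted with an unrecoverable
family and are excluded from the worked examples; the one raw-consistent
cell (r = 0.37 → 0.326) and the two §-level correlations (r = 0.76 →
0.018, r = 0.28 → 0.472) are included.

## Known limitations

* The confidence level is conservative under the default segment count
  (see above); no exact effective-degrees-of-freedom correction for
  overlapped Hann windows is implemented.
* The EDF codec covers only the subset this package writes; arbitrary
  third-party EDF files (multi-record with unusual headers, EDF+
  annotations) are out of scope.
* Laterality uses Stouffer scores clamped at zero; in the (measure-zero)
  case of exactly zero coherence everywhere it raises rather than
  returning 0.
* With 128 ms windows the beta band contains only two Fourier bins; band
  statistics are correspondingly coarse. Window length is configurable
  where finer resolution is needed.
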