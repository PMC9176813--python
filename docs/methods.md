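# Methods

`prosodyml` implements an utterance-level prosody phenotyping pipeline:
rhythm- and intonation-relevant acoustic features extracted from fixed
20-utterance narrative samples per speaker, classified by a repeated nested
cross-validated linear SVM with permutation significance, run per language
(English, Cantonese), on the combined corpus, and as a language-decoding
probe. Because clinical narrative recordings cannot be redistributed, the
package ships a synthetic cohort generator that reproduces the statistical
structure the analysis assumes; everything below documents both the model
and the choices behind it.

## The analysis unit

The atomic unit is the **utterance**: one mono waveform (16 kHz in all
synthetic material), at least 0.2 s long — one full cycle of the lowest
rhythm frequency of interest (2 Hz) needs 0.5 s of context, and the 0.2 s
floor is where the envelope band analysis stops being meaningful. Each
**speaker** contributes exactly 20 utterances; the fixed count is enforced
at validation (never padded or truncated) because both feature-vector
dimensionality contracts depend on it: 20 × 432 = **8640** rhythm features
and 20 × 20 = **400** intonation features per speaker.

## Rhythm features (432 per utterance)

The temporal envelope is the magnitude of the analytic (Hilbert) signal,
low-passed with a zero-phase 4th-order Butterworth at 20 Hz (zero-phase so
rhythm timing is not skewed by group delay) and resampled to 100 Hz. Three
blocks describe it:

* **ENV (64)** — Hann-windowed power spectrum of the mean-removed envelope,
  integrated into 64 × 0.25 Hz bins over 0–16 Hz, log₁₀ with a 1e-12 floor
  so silence is well defined. The 0.25 Hz bin width resolves the
  perceptually critical 2–8 Hz syllable-rate band finely.
* **IMF (48)** — empirical mode decomposition of the envelope by classical
  sifting: natural-cubic-spline envelopes of maxima/minima (outermost
  extrema mirrored past the ends), a Cauchy-type stop at normalized squared
  difference < 0.2, at most 6 modes (a ≤3 s envelope at 100 Hz cannot
  support more meaningful ones). Eight statistics per mode — log energy,
  energy fraction, mean/SD of instantaneous amplitude, mean/SD of
  instantaneous frequency (analytic phase derivative), dominant spectral
  frequency, zero-crossing rate — padded with zeros when the decomposition
  ends early. The telescoping construction makes `Σ IMF + residual`
  reconstruct the input to float precision, which the suite verifies.
* **TMS (320)** — a 16-band acoustic filterbank over 80–7600 Hz; per band,
  the Hilbert envelope (obtained by complex demodulation of the band's
  spectrum at reduced rate, then resampled to 100 Hz), mean-removed, its
  power spectrum integrated into 20 × 1 Hz modulation bins over 0–20 Hz.

Two TMS design choices deserve explanation, since both depart from the more
common log-spaced, globally-normalized construction:

* **Linear band spacing.** Log-spaced bands are narrow at the bottom
  (~25 Hz near 80 Hz); such a band holds at most one voice harmonic, so its
  *content* — present/absent, sweeping in and out with the pitch contour —
  is a proxy for f0, not for rhythm. With 16 linear bands each ~470 Hz
  wide, every band below the voiced spectral ceiling aggregates several
  harmonics for any adult voice, adjacent-harmonic beats (≥ 60 Hz) fall far
  above the 0–20 Hz modulation range, and the per-band modulation spectrum
  reflects amplitude dynamics only. This keeps the rhythm representation
  blind to pitch, which the acceptance suite checks directly (a pure f0
  group effect must leave rhythm classification at chance).
* **Per-band normalization.** Each band's 20 modulation bins are normalized
  to mass 1/16 (bands with zero energy stay zero). Global normalization
  would preserve the distribution of energy *across* acoustic bands — i.e.
  the spectral envelope, which tracks voice pitch and vocal-tract shape —
  inside a feature set meant to describe rhythm. Row normalization keeps
  the stated invariants (total mass 1, gain invariance) while reducing the
  feature to per-band modulation *shape*.

## Intonation features (20 per utterance)

f0 is tracked per 40 ms Hann-windowed frame (10 ms hop) by normalized
autocorrelation, compensated by the window's own autocorrelation. A frame is
voiced iff the best peak in the period range [1/400 s, 1/60 s] reaches 0.45
and the frame RMS reaches 1e-4. Among peaks within 95 % of the best, the
shortest period wins — strongly periodic frames have equally tall peaks at
integer multiples of the true period, and this rule suppresses octave-down
errors. The winning lag is refined by parabolic interpolation; on synthetic
harmonic complexes the tracker's bias is below 1 % across 80–350 Hz.

Each utterance's contour is the voiced span (first to last voiced frame)
with unvoiced gaps linearly interpolated, resampled at 20 equidistant time
points. Contours stay in Hz and are *not* per-speaker normalized: speaker
pitch level is part of the signal the classifier models. Utterances with
voiced fraction below 0.1 raise an error naming the utterance rather than
being silently imputed, which would corrupt the 400-feature contract
invisibly.

## Classification

For a speakers × features matrix with binary labels, each repetition of the
cross-validation runs 10 stratified outer folds (stratified because cohorts
of ~48 would otherwise risk single-class folds). Inside each training fold,
in order: per-feature standardization (SD floor 1e-8); PCA keeping the
smallest number of components reaching 95 % of training variance (capped at
n−1, computed exactly from the training Gram matrix); a 5-fold inner grid
search over C ∈ {1e-3 … 1e2} scored by AUC of pooled inner-fold decision
values; a linear SVM (L2-regularized squared hinge, the liblinear default
objective, solved by a deterministic primal Newton method that the test
suite cross-checks against scikit-learn's `LinearSVC` to ~1e-6) refit at
the chosen C; and a sigmoid (Platt) calibrator fit on the inner-fold
held-out decision values with **classes weighted to equal mass**. The
balance matters: an unbalanced calibrator's intercept encodes the training
fold's class base rate, which under stratified cross-validation of a finite
cohort is *anti*-correlated with the test fold's composition (a test fold
rich in positives comes from a training set poor in them), so whole test
folds get shifted the wrong way and the pooled null AUC is biased downward
by several points. Ties in the C grid go to the **largest** tying C:
ties arise in near-separable folds, where heavy regularization shrinks
decision values toward zero and makes the pooled cross-fold probabilities
incomparable.

No statistic of a held-out speaker influences any fitted parameter; the
suite spot-checks this by corrupting one speaker's features and verifying
that scores of speakers sharing its test fold are bit-identical.

Each repetition scores every speaker once (by the fold that excludes it);
AUC is rank-based (Mann–Whitney, midrank ties) on the pooled probabilities.
A classification is summarized by the **median-AUC repetition** (whose
accuracy/sensitivity/specificity are reported with it) plus a confusion
matrix aggregated over all repetitions — both readings are exported since
either may be wanted. Repetition counts are forced odd so the median
repetition is unique. Desk-scale defaults are 101 repetitions and 200
permutations; full-scale runs (5001/5001) are a config/CLI flag away.

**Permutation significance.** The observed statistic is the median AUC over
repetitions; each permutation shuffles labels once and runs a single
nested-CV repetition, giving n_perm exchangeable null AUCs;
p = (b+1)/(n_perm+1) with b the count of null AUCs ≥ observed. Running one
repetition per permutation (rather than a full repeated run) is the
standard cost-feasible construction; since the observed median is less
dispersed than a single-repetition draw, the test is slightly conservative
under the null, which the calibration tests confirm empirically.

## The synthetic cohort generator

The generator's job is to produce two-group, two-language cohorts whose
group differences live *either* in envelope statistics (rhythm) *or* in f0
trajectories (intonation), with the two channels independently
controllable — this separation is what the rhythm-vs-intonation contrast of
the study design requires, and it drives every design choice below.

Each utterance (duration uniform 1.5–3 s) is a concatenation of syllable
events. Inter-onset intervals are gamma distributed — strictly positive
with mean 1/(4.5 Hz + rate_shift) and directly controllable CV (0.25 +
cv_shift); at least 10 % of each interval is left silent. Stress-timed
profiles (English default) alternate strong/weak syllables, scaling weak
durations and amplitudes by (1 − 0.4); the interval sequence is rescaled by
1/(1 − 0.4/2) so that the configured base rate remains the *mean* syllable
rate in both timing modes (otherwise rate and timing typology would be
confounded). Syllable-timed profiles (Cantonese default) have no
alternation.

Each syllable is a raised-cosine-windowed harmonic complex (1/k roll-off)
plus aspiration noise at −18 dB, speech-shaped (flat to 500 Hz, −6 dB/oct
above). Three choices keep the rhythm channel blind to f0:

* the harmonic series ends at a **fixed 3500 Hz ceiling** (k_max = 3500/f0)
  rather than at a fixed partial count — a cutoff at k·f0 would itself mark
  the pitch;
* every speaker carries fixed **vocal-tract latents** — spectral tilt,
  three resonance bumps, a separate colouring (tilt + bumps + a low-
  frequency floor gain) applied to the noise alone, and a breathiness
  factor — so between-speaker variation in per-band energy and
  harmonic-to-noise ratio dominates anything the pitch placement
  contributes, as vocal-tract differences do in real cohorts;
* the vocal-tract filter is applied **per syllable, RMS-preserving**, so
  pitch movement through a resonance colours the spectrum without
  modulating the planned amplitude envelope.

f0 trajectories live on an independent seeded stream per utterance (as do
rhythm draws and noise draws), so effects injected into one channel cannot
reach the other through shared randomness. Intonation-mode profiles use a
declination from +E/2 to −E/2 semitones across the spoken span (E = 4 st ×
speaker jitter × f0_range_scale) plus a smooth 3-component sinusoidal
wiggle in normalized time — smooth rather than per-syllable noise so
contour roughness does not depend on how many syllables the rhythm channel
drew; anchoring to the spoken span (not the file duration) removes a
residual coupling between syllable rate and the contour's endpoint. Tone-
mode profiles draw each syllable's (start, end) pitch target uniformly from
a six-shape inventory patterned on Cantonese level/rising/falling tones,
scaled by E/2, with a gentle downdrift. Speaker f0 medians default to
120 Hz (M) / 210 Hz (F), gender alternating within each group; group
effects add f0_median_shift (Hz) and scale the excursion.

Admissible ranges are enforced: syllable rates in [1, 10] Hz, f0 in
[60, 400] Hz; violating effect combinations raise before any audio is
rendered. Waveforms are peak-normalized to 0.9.

**What the generator does not emulate:** phonetic segments, lexical
content, formant dynamics tied to vowels, pauses with hesitation structure,
recording-channel variation, or any correlation between rhythm and
intonation channels (real speech has plenty). Passing the acceptance suite
therefore shows that the *pipeline* recovers the kinds of group differences
it targets and stays calibrated under the null — not that the effect sizes
or AUC values transfer to clinical recordings.

## Study drivers

Model 1 classifies diagnosis per language (4 cells: EN/YUE × rhythm/
intonation); Model 2 on the combined corpus (2 cells), with language kept
as metadata only — the language probe (classifying EN vs YUE from rhythm
features, diagnostic groups pooled) demonstrates that language *is*
decodable from these features, which is exactly why it must never enter the
Model 2 feature matrix. Every cell's CV seed derives from the corpus's own
language label, so swapping the two corpus arguments permutes cells without
changing any cell's values. Reports export a six-row summary table (median
AUC, ACC, SENS, SPEC, p per cell), per-cell observed and null AUC
distributions (boxplot data), aggregated confusion matrices, and a
config+seed JSON sufficient to reproduce the run bit for bit.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the system checks at 24+24
speakers per cohort, 20 utterances each, 11 CV repetitions and 99
permutations per classification; the null-calibration block uses 20
independent cohorts in the suite and 8 in the script. These sizes were
chosen once as the smallest at which the qualitative pattern (effects
recovered at AUC ≥ 0.85, null centered at 0.5, permutation false-positive
rate at its nominal level) is stable; the library defaults (101
repetitions, 200 permutations) and the 5001/5001 full scale remain
available through `CVConfig`/`StudyConfig`.

## Known limitations

* The EMD boundary treatment (mirrored extrema) and sift threshold follow
  the classical recipe; modes of very short envelopes (< 1.5 s) are few and
  the higher-mode statistics are frequently zero-padded.
* The f0 tracker has no dedicated octave-jump repair beyond the
  shortest-near-maximal-period rule and parabolic refinement; creaky or
  subharmonic voice qualities are outside the generator's range and
  untested.
* Pooled out-of-fold probabilities are only approximately comparable across
  folds (fold-specific calibrators); the rank-based AUC absorbs monotone
  within-fold distortions but not cross-fold offsets. This shows up as
  mild conservatism, not optimism.
* With 48-speaker cohorts, single-cell AUC estimates carry sampling noise
  of several points; the acceptance bands are set accordingly.
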