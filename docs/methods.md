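# Methods

This note documents the models, parameter choices, and numerical
conventions behind `phrasetrack`, and what the synthetic-data study
does and does not establish.

## Scientific setting

Listeners hearing a melody track not only low-level acoustics (the
amplitude envelope, the beat) but higher-order structure: phrases,
whose endings are cued by a lengthened final note and an enlarged
melodic interval, with no inserted silence. The package implements a
complete desk-scale analogue of an EEG + behavior experiment on phrase
tracking: it generates the stimuli, simulates the recordings with known
ground truth, and recovers the phrase-tracking markers with the same
analysis chain one would apply to real data.

Two numbers anchor the stimulus design. At 74.4 beats per minute the
beat rate is 1.24 Hz and the quaver (double-beat) rate is 2.48 Hz;
regular melodies use 8-beat phrases, so a boundary occurs every
8 x 60/74.4 = 6.45 s (~6.5 s). Irregular melodies draw phrase lengths
from 3-30 beats (excluding the regular lengths 4, 8, 12), resampled
until the melody mean lies in 8.5-10.5 beats, emulating material whose
phrases average ~9.5 beats.

## Stimulus generator (`melody`, `acoustics`)

Melodies tile each phrase exactly with durations from {0.5, 1, 2, 4}
beats. The quaver granularity keeps the half-beat shuffle exact and
reflects material dominated by notes shorter than the beat. Boundary
cues are explicit: the final note of each phrase is at least
`cue_duration_factor` (default 2.0) times the median interior duration,
and the melodic interval into it is at least `cue_interval_semitones`
(default 5). Interior notes occasionally (default `distractor_rate`
0.15) carry long durations or large leaps too, so a boundary cannot be
read off any single local event. Pitches walk a C-major scale-degree
set over roughly two octaves; mode (major/minor) is not modeled because
it plays no role in any computation here.

The shuffled control permutes the note material on the half-beat grid.
Because every note duration is a multiple of the 0.5-beat chunk, a
permutation of whole notes is exactly a permutation of half-beat
chunks that preserves the duration histogram and pitch multiset; the
shuffled melody keeps the source melody's boundary positions as
pseudo-boundaries, which serve as the chance-level ground truth.

Audio is rendered at 16 kHz with a four-harmonic decaying tone (1/k
harmonic roll-off, 0.6 s decay constant, 10 ms cosine onset ramp) —
a deliberately simple keyboard-like timbre; the analysis depends only
on the amplitude envelope, not on timbral realism. The broadband
envelope comes from a 32-band gammatone filterbank spanning 50-4000 Hz
on ERB-spaced centers (4th-order IIR filters), per-band analytic-signal
magnitudes averaged across bands and resampled to 100 Hz. Band
averaging by arithmetic mean preserves linear amplitude scaling; the
analytic-signal envelope is exact for the narrowband filter outputs.

## EEG forward model (`eeg_sim`)

Per subject, a stimulus-locked source is

    source(t) = g * (kernel ⊛ envelope)(t)
              + a * sum_b  exp(-(t - t_b - L)^2 / 2w^2) * sin(2*pi*f*(t - t_b - L))

with kernel a biphasic response over lags 0-400 ms (peak 60 ms, trough
150 ms, peak-normalized), and one Gaussian-windowed sinusoidal burst
per phrase boundary t_b: frequency f = 2.48 Hz, latency L = 50 ms,
width w = 0.3 s, amplitude a. The burst model makes the paper-style
marker ("an increase in narrow-band EEG power near boundaries") an
explicit, recoverable ground truth with three interpretable parameters.
A fraction `shared_fraction` (default 1) of the source is common to all
subjects; the rest is subject-specific 1/f noise of matched variance.
Channel data are a positive random mixing vector (uniform 0.5-1.5)
times the source plus per-channel 1/f noise scaled so the
channel-averaged variance ratio equals `snr_db` (default runs use
-3 dB). 16 channels suffice to make PCA/MCCA nontrivial; no head
geometry is modeled, and no ocular artifacts are simulated (hence no
ICA stage — a pass-through hook exists in the pipeline design).

The behavior generator emits a press for each boundary with probability
`hit_rate` (defaults: regular 0.8, irregular 0.75, shuffled 0.15) at
the boundary time plus Gaussian jitter (SD 0.25 s), plus Poisson false
alarms (2/min). These rates were chosen once to produce the
qualitative pattern real listeners show — structured conditions far
above the shuffled baseline, modest inter-rater agreement — and are not
fit to any quantitative target.

**What the generator does not emulate:** realistic scalp topographies,
artifacts, inter-subject latency differences, or any nonlinearity
between envelope and response. Passing tests therefore demonstrate
that the analysis chain recovers what it is designed to recover under
its own assumptions, not that it would behave identically on real EEG.

## Preprocessing (`preprocess`)

Band-pass 0.5-35 Hz, Butterworth order 5, applied forward and backward
(zero phase). Epochs span 3 s before melody onset to 2 s after offset;
average re-referencing subtracts the per-sample channel mean.

MCCA is the two-stage-PCA formulation: a per-subject PCA retains
`n_pcs_per_subject` (default 10) score series; a second PCA across the
subjects-concatenated scores extracts `n_shared` (default 5) components
shared across listeners of the identical stimulus; each subject's
contribution to the shared subspace is projected back and the single
component explaining the most variance in that subject's own data is
kept, at unit variance. Stage-1 scores are not whitened per-PC;
instead each subject is scaled to unit total variance so subjects weigh
equally while the variance ordering of components survives into stage
2 — full whitening makes stage 2 degenerate whenever subjects' data
coincide, because every direction then carries identical (unit)
variance. Component sign is fixed by requiring nonnegative correlation
with the stimulus envelope, removing PCA's sign indeterminacy
reproducibly. The retained-PC counts are free parameters; tests probe
sensitivity at -5 dB SNR, where the shared source is recovered at
|r| >= 0.9 per subject.

## TRF core (`trf`)

The forward TRF solves ridge least squares on the lagged design matrix
with an unpenalized intercept, w = (X'X + λI)^(-1) X'y on
column-centered data, dropping rows without full lag coverage
(valid-sample convention). Negative lags mean the response precedes
the feature: with lags -200..+500 ms at 100 Hz, lag index 0 is -0.2 s
and multiplies the feature two samples into the response's future.
Features are z-scored before lagging (zero-variance features are mapped
to zeros), so weights are in standardized units. Statistics restricted
to -100..+400 ms are a pure slice of the fitted lag axis.

`r_squared` is the squared Pearson correlation between prediction and
observation — symmetric and sign-invariant, matching the prediction-
quality convention of forward-model toolboxes. Regularization
selection uses contiguous-block k-fold cross-validation scored by the
held-out coefficient of determination (1 - SS_res/SS_tot) rather than
the squared correlation: the determination coefficient penalizes
amplitude error, so heavy shrinkage correctly wins when the response
is pure noise, while a near-noiseless system still selects the grid
minimum. Ties resolve to the smaller λ. The default grid is 13
log-spaced points over 10^-6..10^6.

`phrase_stats.BoundaryModel` caches the covariate blocks of the normal
equations and assembles the boundary blocks from the impulse positions
in O(K x lags) per refit; results are identical (to machine precision)
to the dense `fit_trf` path, which a test asserts.

## Spectral measures (`spectral`)

Cerebral-acoustic coherence is magnitude-squared coherence between the
denoised neural series and the stimulus envelope, both at 100 Hz, via
Welch cross-spectra with 1024-point Hanning segments and 512-point
overlap, after trimming 1 s from each end. The 0.1-20 Hz grid with
exact 0.05 Hz steps is obtained by zero-padding segments to 2000 points
(100 Hz / 2000 = 0.05 Hz); the native 1024-point resolution
(~0.0977 Hz) cannot land on that grid. Values are clamped to [0, 1].

Narrow-band power envelopes use complex Morlet wavelets: 3 cycles up to
2.48 Hz, increasing linearly in frequency to 10 cycles at 35 Hz. Power
is the squared magnitude of the convolution, at 100 Hz. Samples within
half a wavelet of an epoch edge are flagged and excluded downstream.
Baseline correction subtracts mean power over a pre-stimulus window,
default -2.0..-0.5 s relative to melody onset.

## Phrase-tracking marker (`phrase_stats`)

The boundary TRF regresses the baseline-corrected 2.48 Hz power
envelope on three impulse trains jointly over lags -3..+3 s: a unit
impulse at each phrase boundary, z-scored note duration at each note
onset, and z-scored pitch at each onset. The covariates absorb
responses evoked by local acoustic events, so the boundary profile
isolates structure-specific modulation — a test verifies that bumps
placed at *every* long note (boundary or not) are absorbed by the
duration covariate and do not produce a supra-threshold boundary
profile.

Summary indices: the RMS of the boundary profile over the window one
beat before to one beat after the boundary (+-0.806 s at 74.4 bpm; the
window is expressed in beats so other tempi remain analyzable), and the
peak latency (lag of maximum weight in that window; ties resolve to the
smallest |lag|, negative first).

The permutation null redraws the boundary onsets uniformly over the
melody's actual note onsets — count preserved, >= 1 s minimum spacing,
within-melody — refits the full model 100 times, and takes the 95th
percentile of the null statistic as the significance threshold. Both
model R² and window RMS are recorded; R² is the thresholded statistic
by default and RMS serves the condition contrasts. One practical
finding is baked into the defaults: when the predictor span ends
exactly at the final boundary, that boundary sits on the valid-row edge
of the lagged design and inflates observed R² relative to permuted
onsets; epoched data with a 2 s post-roll (which the pipeline always
uses) removes the bias, and the calibration tests verify a 5% type-I
rate under that convention.

The controls are (a) a random-onset profile (full covariate model, one
random draw), and (b) the identical fit on the 1 Hz power envelope,
which shows frequency specificity. In the simulator-based symmetry
check, the "injected at 1 Hz" condition uses a 1.0 s burst width
(>= one cycle under the Gaussian envelope — a 0.3 s burst at 1 Hz is
not narrowband) and a proportionally larger amplitude to clear the
higher 1/f noise floor at 1 Hz.

Cluster-based permutation tests against zero use per-lag one-sample
t-values, a two-tailed p < 0.05 cluster-forming threshold (not stated
by convention; diagnostics can rerun at 0.01), contiguous same-sign
runs, summed-t cluster mass, and a max-cluster-mass null from 1000
random per-subject sign flips; cluster p is the fraction of null
masses at least as large as the observed mass. Group contrasts on RMS
use paired t-tests with Bonferroni correction.

A small-sample caveat: with only one or two melodies per condition and
a fully shared simulated source, every subject's profile contains the
same stimulus-driven residue, and the one-sample cluster test can flag
that residue even in the shuffled condition. This is a property of the
desk-scale design (few melodies, `shared_fraction` = 1), not of the
test, whose family-wise error is calibrated at 5% on proper nulls in
the acceptance suite.

## Behavioral scoring (`behavior`)

Presses snap to beat bins (floor(t x tempo/60)); multiple presses in a
bin collapse to one. The three-beat tolerance window is interpreted as
the boundary beat +-1; matching is greedy nearest-first one-to-one, so
a press cannot satisfy two adjacent boundaries. F is the harmonic mean
of precision and recall with zero-denominator cases defined as 0.
Shuffled melodies are scored against their source's boundaries.
`chance_f_score` gives the closed-form expectation for independent
random marks at density p (disjoint windows): E[F] ≈ 2B(1-(1-p)^w) /
(pT + B); Monte Carlo agrees within 0.02.

Krippendorff's alpha is computed at nominal level from the coincidence
matrix with pairwise deletion of missing entries. The implementation
follows the general definition, under which alpha is negative for
systematic disagreement — the occasional informal claim that it ranges
from 0 to 1 is not enforced. Units are the beat bins of each melody,
raters are participants; per-condition values average over melodies.

## Problem sizes and defaults

Default pipeline runs use 6 subjects, 16 channels, 500 Hz, two
presentations per melody averaged at the epoch level, 5 x 8-beat
regular phrases and 4 irregular phrases per melody, modulation
amplitudes regular 1.0 / irregular 0.7 / shuffled 0.0 at -3 dB SNR.
The calibration suites run at reduced sizes chosen for tight
statistical contracts at desk scale: permutation-null calibration uses
6-phrase melodies, +-0.6 s lags and a +-0.7-beat RMS window (the
contract — a 5% exceedance rate — is size-free); cluster calibration
uses 10 subjects x 121 lags; the amplitude-recovery sweep uses
single-subject recordings with +-1.0 s lags and reports the Spearman
correlation of the 20-seed mean RMS curve over a 5-point amplitude
sweep. The acceptance script runs the full chain at 6 subjects x 2
melodies per condition with +-1.5 s boundary lags (the +-0.806 s RMS
window sits well inside) and 100-permutation nulls.

## Known limitations

- The boundary cues are deterministic in kind (always a long final
  note and a leap); real material varies cue strength continuously.
- The forward model is linear and stationary; no adaptation, no
  attention effects, no latency jitter across subjects.
- R² values are in-sample prediction quality (as is conventional for
  these forward models), not held-out generalization, except where the
  cross-validation routine is used.
- The exact regularization protocol behind the envelope TRF is a
  declared substitute (block CV as described above), and whether
  coherence is computed on the MCCA component or channel-averaged data
  is configurable with the MCCA component as default.
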