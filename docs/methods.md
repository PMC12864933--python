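# Methods

`sleepprint` asks a specific question of two-night sleep-EEG cohorts: when a
classifier separates insomnia severity groups from band-power spectra, is it
reading *insomnia*, or is it reading *people*?  The package provides every
stage needed to pose and answer that question on synthetic cohorts with known
ground truth, and to run the identical analysis on user-supplied recordings.

## The synthetic cohort model

Each subject owns a trait **spectral fingerprint**: an aperiodic backbone

    log10 P(f) = b − log10(k + f^χ)

with offset `b` (log10 µV²/Hz), knee `k ≥ 0` and exponent `χ > 0`, plus
Gaussian oscillatory peaks `(center, height, SD)` added in log10 space,
per-channel multiplicative gains, and per-stage modulation.  NREM (N2, N3)
raises the offset by 0.4 and the exponent by 0.3 over the REM baseline —
the stage contrast magnitudes reported for adult sleep EEG — so stage
structure is recoverable by the spectral decomposition.

Signals are synthesized by **spectral shaping**: complex-Gaussian rfft
coefficients with expected power equal to the target PSD, inverted per
30-s epoch.  The expected Welch spectrum of the output therefore *equals*
the target by construction, which is what makes planted-parameter recovery
a meaningful test.  This synthesis method is a design choice of the
package: it trades realism of waveform morphology (no transients, no
nonstationarity within an epoch) for exact spectral control.

Hypnograms are first-order Markov chains over {W, N1, N2, N3, R} with one
transition matrix per ISI severity group (GSC / MI / MSI).  The default
matrices encode the fragmentation gradient reported for insomnia —
increasing wake continuity, decreasing N2/N3 continuity, more N2↔N3
shuttling with severity — while the default *spectral* group effect is
zero: severity never moves the spectrum, individuals do.  That null is the
scientific point the downstream analyses must reproduce.

Key generator parameters (defaults):

| parameter | default | rationale |
|---|---|---|
| offset mean / SD | 1.2 / 0.4 log10 µV²/Hz | between-subject spread 0.4 as reported; absolute level set so clean epochs score well under the 5 µV rejection threshold (the montage's gain is arbitrary — only log-power contrasts matter downstream) |
| knee mean / SD | 10 / 3 | knee-mode spectra typical of scalp sleep EEG |
| exponent mean / SD | 2.0 / 0.2 | REM baseline; matches reported medians and spreads |
| night drift (offset, exponent SD) | 0.10, 0.06 | free parameter; chosen so a model trained on Night 1 generalizes imperfectly to Night 2 (accuracy intermediate between same-night and held-out-subject regimes), the qualitative regime the cross-night results imply; far below the between-subject spread |
| epochs per night | 960 | 8 h of 30-s epochs (the standard chain length) |
| sampling rate | 200 Hz | desk-scale; Welch windows are specified in seconds so the 0.25 Hz resolution is unchanged |
| artifact probability / amplitude | 0.02 / 20 µV | rare square transients at 25 Hz; at a 200 Hz working rate the transient's mean adjacent-sample difference is amplitude/2 |
| line noise | 50 Hz, 2 µV | removed by the notch and by periodogram interpolation |

What the generator does **not** emulate: ultradian sleep-cycle structure
(dynamics are first-order), EOG/EMG/ECG channels, volume-conduction channel
correlations (channels are independent draws sharing one spectrum), and
waveform-level artifacts such as electrode pops with realistic shapes.
Passing tests therefore demonstrate that the *analysis chain* recovers what
was planted — not that real EEG contains such structure.

## Preprocessing

Filtering is a zero-phase Hamming windowed-sinc FIR band-pass, 0.5–100 Hz
with −6 dB points at 0.25 and 112.5 Hz, plus a 50 Hz notch (delegated to
MNE's FIR routines).  The orchestrated pipeline skips the upper band edge
when the data rate cannot support it (e.g. 200 Hz synthetic data, which is
band-limited by construction); calling the filter directly on such data
raises an error naming the required minimum rate.

Artifact rejection scores each 30-s epoch by the per-channel mean absolute
difference of adjacent samples at a 200 Hz working rate, takes the maximum
over channels, and rejects epochs scoring above 5 µV.  When the native rate
exceeds the working rate, the signal is band-limited (0.5 Hz to at most
145 Hz, capped below the working Nyquist) and polyphase-resampled first; at
the native rate the differences are taken directly — a low-pass there would
destroy exactly the high-frequency steps the rule exists to catch.  The
per-channel maximum is used because one bad channel suffices to corrupt an
epoch's 180-feature row.

## Band-power features

Welch PSD per epoch: 4-s Hann windows, 50 % overlap, 0.25 Hz resolution,
mean over segments.  Nine bands — delta 0.5–3, theta 4–7, alpha 8–12.5,
low-sigma 9–12.5, high-sigma 12.5–16, low-beta 16–24, high-beta 25–35,
low-gamma 35–48, high-gamma 52–100 Hz — with inclusive edges (the
alpha/low-sigma overlap is intentional; the 3–4 and 48–52 Hz gaps are
honored, the latter guarding against notch residue).  A band feature is the
natural log of the mean PSD over the band's bins, floored at 1e-12 µV²/Hz.
Columns are channel-major, band-minor (`Fp1_delta … Cz_high_gamma`, 180
features at 20 channels).  Wake and N1 epochs are excluded; analysis rows
are labeled NREM (N2+N3) or REM.  The relative-power variant logs each
band's share of the 0.5–100 Hz bin-sum, so disjoint-band shares sum to ≤ 1.

## Hypnogram statistics

Sleep variables use single-epoch sleep onset (first epoch of any sleep
stage); TST counts non-wake epochs; WASO counts wake between onset and the
final sleep epoch; stage percentages are of TST; bouts are maximal
same-stage runs.  Transition matrices truncate each night at 960 epochs
(shorter nights used in full, nothing padded — padding would fabricate
transitions), pool counts within participant without crossing night
boundaries, and row-normalize; zero-count rows are NaN.  Group comparisons:
one-way ANOVA with η² = SS_between/SS_total; when p < 0.05, pairwise
Wilcoxon rank-sum (exact for n ≤ 20 without ties, tie-corrected normal
approximation otherwise) with small-sample-corrected Hedges' g.  Pairwise
p-values are reported raw — no multiplicity correction, deliberately, and
flagged here.

## Classification regimes

XGBoost multiclass trees: learning rate 0.3, gamma 0, max depth 10, L1
penalty 0, `auto` tree method; 300 boosting rounds with early stopping on a
10 % carve-out of the training rows (round count is a package choice; the
optional 10-fold CV refinement searches {100, 300} trees × depth {6, 10} on
training folds only).  The three regimes:

* **intra-individual** — stratified (subject × class) random 80/20 epoch
  split over both nights pooled;
* **night-to-night** — train Night 1, test Night 2; the split *and* the
  model are deterministic, so metric SDs over repetitions are exactly 0;
* **subject-wise** — 80/20 split of subject ids, epochs follow their
  subject; a leakage assertion checks id-disjointness every repetition.

Metrics: accuracy and macro precision/recall/F1 (classes absent from a test
set are excluded from macro averages with a warning), mean ± SD over
repetitions, summed confusion matrices.  Attribution uses XGBoost's exact
tree-path decomposition (`pred_contribs`): per-row contributions plus base
value reproduce the model margin to float precision; importance is the mean
absolute contribution over ≤ 1000 sampled rows and all classes, and band
shares count top-10 slots per broad band family (beta = low+high beta,
gamma = low+high gamma).

For chance-level checks on subject-wise splits, binomial intervals are
computed at the level of independent units — held-out *subjects* pooled
over repetitions, not epochs — because whole-subject holdout makes epochs
within a subject maximally dependent.

## Embeddings and the similarity matrix

PCA is the exact top-2 principal projection; t-SNE (perplexity 30,
Euclidean, learning rate auto, ≤ 1000 iterations) is initialized from that
projection scaled to the conventional 1e-4 spread, with the seed part of
the public interface.  Because t-SNE layouts are not canonical, the test
surface is cluster validity (silhouette against known labels), never pixel
positions.

The similarity matrix selects half of each subject's epochs at random
(stratified by night, split alternately into two sets), computes all
pairwise Euclidean distances in feature space, min-max normalizes globally
(diagonal included, so zero distance maps to exactly 1 and the largest
observed distance to 0), and takes similarity = 1 − normalized distance.
`block_contrast` replaces visual inspection: mean within- minus
between-block similarity, by subject and by ISI group, with permutation
p-values (epoch→subject labels shuffled for the subject contrast; group
labels shuffled over whole subjects for the group contrast; 1000
permutations, +1-corrected one-sided p).

## Periodic/aperiodic decomposition

The iterative pipeline: (1) log-linear interpolation across the 50 ± 2 Hz
mains band; (2) robust aperiodic fit — nonlinear least squares of
`b − log10(k + f^χ)` (knee mode; fixed mode pins k = 0) on 0.5–100 Hz,
then a refit restricted to points at or below the first fit (clipped
flattened values under the 2.5th percentile threshold), masking peak
regions; (3) iterative Gaussian extraction on the flattened spectrum —
global maximum, stop below max(0.10, 2.0 × residual SD), half-height width
seeds the SD, fit-and-subtract, at most 6 peaks; (4) joint multi-Gaussian
refit, dropping peaks whose bandwidth (2 × SD, bounded 0.5–15 Hz) leaves
bounds, whose height falls under 0.10, or whose center sits within one SD
of a grid edge (backbone misfit masquerading as a peak); (5) aperiodic
refit on the de-peaked spectrum, with each peak's core (± 2 SD around its
center) additionally masked so residual tail misfit cannot tilt the
backbone.  Steps 3–5 repeat until the exponent settles (≤ 4 cycles): a
single pass leaves a peak-tail bias in (b, χ) on multi-peak knee spectra.  R² is the squared correlation of the full model
with the (interpolated) input over the fit range; fits under 0.99 are
flagged excluded, never discarded.  Reporting summaries restrict to
0.5–45 Hz.

`fit_joint_model` is the in-package cross-check: a single simultaneous
bounded least-squares fit of backbone plus all peaks, with the peak count
selected by BIC over seeds taken from smoothed-residual maxima.  It shares
no code path with the iterative pipeline, so agreement between the two on
random synthetic spectra validates both.

**Identifiability limits.** Two caveats are inherent, not bugs.  Heavily
overlapping Gaussians (centers closer than their widths) admit equally good
merge-or-split decompositions, so peak-count agreement between two correct
fitters is not a meaningful contract there; the random-spectrum cross-check
suite draws peak SDs in 0.8–2.0 Hz with centers ≥ 4 Hz apart.  And a small
peak riding the knee bend (center below ~8 Hz over a pronounced knee) is
absorbed into the backbone by the greedy pipeline whenever its apparent
height undercuts the 0.10 detection floor, while a global model-selection
fit can recover it; the suite therefore plants peaks at ≥ 8 Hz (alpha and
up), and decompositions of strong-knee spectra with small low-frequency
peaks should be read with that ambiguity in mind.

## Numerical and degenerate-input choices

Power floor 1e-12 µV²/Hz before logs; tie-breaks in classification by fixed
sorted class order (argmax takes the first maximum); all-wake hypnograms
report TST 0 with SOL missing and a warning; subjects losing every epoch of
a stage are dropped from that stage's analyses with a logged warning;
single-class training data yield a constant predictor with a warning;
non-stochastic transition rows, non-positive exponents and out-of-range
probabilities are configuration errors raised before any computation.
Windowed-sinc filters are idempotent only to passband-ripple accuracy
(~0.2–0.7 % for Hamming); the contract is stated in attenuation and phase
terms.

## Problem sizes

The shipped test and reproduction runs use desk-scale cohorts chosen as the
package's default study conditions: 6 subjects per ISI group × 2 nights ×
120 epochs/night × 20 channels at 200 Hz for the classification and
similarity analyses (reduced repetitions: 10); 10,000-step chains for
transition recovery; 50 random spectra for the decomposition cross-check;
100 repetitions for attribution rank stability.  All sizes are parameters
of the public API and scale up unchanged.
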