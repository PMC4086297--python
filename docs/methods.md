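# Methods

This note records the model, the committed parameter choices, and what the
synthetic benchmarks do and do not establish.

## Problem setting and assumptions

The tracker operates downstream of spike sorting: its inputs are, per
session (day) and per electrode channel, spike-sorted units — each an
`l × m` matrix of sampled spike waveforms (microvolts) plus `l` spike times
(seconds). It assumes sorting quality is fixed and out of scope, that units
on different channels are never the same neuron (no cross-channel
assignment), and that two units co-recorded on one channel on one day are
different neurons (this is what makes negative training pairs free). Session
indices are treated as the unit of elapsed time; recording days need not be
consecutive calendar days, so the stability window counts *sessions*.

## Feature extraction

Average waveforms are smoothed with a Gaussian kernel (`sigma` = 1 sample at
30 kHz by default, reflection boundaries, mass-conserving) before *all*
feature computation, including the Pearson measure. Smoothing suppresses
the high-frequency residue of averaging over a short recording interval;
sigma is deliberately small so genuine shape differences survive.

The ISIH uses 1 ms bins on [0, 1 s) plus one overflow bin — millisecond
resolution is conventional for cortical ISIs and the overflow bin conserves
probability mass. Empty bins are floored at `1e-10` and the histogram
renormalised, so the logarithmic measures (KLD, BD) are always defined; for
histograms with ≥ 100 counts per occupied bin the floor perturbs every
measure by far less than the day-to-day variability being measured (tested).
Interval binning uses `floor(isi/width)` with a `1e-9` relative tolerance so
intervals that sit exactly on a bin edge land deterministically in the
half-open bin to their right.

Two waveform measures are asymmetric (PH, PT normalise by their second
argument); the convention throughout is that the *stored profile instance*
is the reference. Peak matching is specified only loosely in the
literature it derives from, so this implementation commits to: local extrema
of either sign of the mean-removed waveform, prominence-gated at 10% of the
peak-to-peak amplitude; peak weights proportional to absolute mean-removed
amplitude, normalised per waveform; closeness factors
`exp(−[(Δt/τ_t)² + (Δa/τ_a)²])` with `τ_t = m/8` samples and
`τ_a = 0.25 × ptp(target)`; asymmetric similarity = Σ weight × best
closeness; symmetric similarity = geometric mean; dissimilarity = 1 − that.
Mean removal makes PM invariant to common baseline offsets. Ties in
argmax/argmin (PT) break to the earliest index; indices are 0-based, which
cancels in all differences.

## Classifiers

All four classifiers consume the same dissimilarity vectors on their raw
scales (no standardisation) and expose a signed score, positive = match:

- **SVM**: soft-margin RBF, kernel sigma = √(number of features), slack
  C = 1. Score = signed distance to the decision plane.
- **RVM-style**: sparse kernel logistic model — L1-regularised logistic
  regression over the same RBF basis, one basis function per training
  vector. The L1 penalty plays the role of the Bayesian relevance pruning;
  its strength is set weak (C = 100) because with sigma = √n the kernel
  features vary little over the [0, 1]-scale dissimilarities and a strong
  penalty collapses the fit to the intercept — in particular it must be able
  to fit a tight cluster of near-identical true-positive vectors at the
  origin. Score = log-odds. The stand-in is recorded in the model metadata.
- **MAP**: class priors from training frequencies; class-conditional joint
  densities by multivariate Gaussian KDE (Scott's rule). Score = posterior
  log ratio. A KDE cannot be estimated for a class with zero variance, so
  fully degenerate training data raises an error.
- **NB**: per-feature 1-D KDEs, no priors (uniform). Score = summed
  per-feature log likelihood ratio.

Training is deterministic given the seed; models persist via joblib with
kind, feature set, fitted state and a training-set digest.

## Tracking

FMD scans a profile's in-window instances newest-first and stops at the
first classifier match (at most 7 comparisons); MMD evaluates all in-window
instances and keeps the match with the maximum score — by construction it
never costs fewer classifier calls than FMD. The stability window is 7
sessions: a profile unseen longer is dropped and never compared again
(states reduce to active/dropped; an "inactive but comparable" middle state
would be redundant, since only in-window instances are compared anyway).

The membership matrix is refined to a one-to-one assignment by depth-first
back-tracking over units, with branch-and-bound pruning on achievable
cardinality. Optimality is lexicographic: (1) maximum number of units
attached to existing profiles, (2) maximum total score. Residual exact ties
(score sums within 1e-12) break toward the lexicographically smallest sorted
list of (profile id, unit label) pairs, making results order-independent and
reproducible. Matrices are small (a handful of profiles and units per
channel), so exhaustive search is exact and cheap. Profile IDs are monotone
per channel and never reused. Channels are tracked independently; an error
on one channel (e.g. a degenerate flat waveform) is reported and leaves the
others untouched.

## Evaluation metrics

*Classification accuracy*: over all units on day x (for every tracked day
after the first), a unit whose true identity was also recorded on day x−1
is correct iff it was assigned to the profile holding that identity's
day-(x−1) instance; a unit whose identity is genuinely new is correct iff it
received a new profile. The second clause is a committed extension — without
it the denominator is undefined for appearing units. The metric is invariant
to profile relabelling.

*Percent correct profiles*: a reference profile counts only when some
tracked profile contains exactly the same (day, unit) instance set over the
evaluated days — no partial credit, no optimal relabelling. It is strictly
harsher than the day-to-day metric: one broken link disqualifies a whole
profile.

*Sliding validation* preserves session order: window k covers sessions
k … k+9 (default plan: 15 sessions, 6 windows, 5 train + 5 test); each
window trains on its leading block and tracks its trailing block, and
windows are summarised as mean ± SD.

## Synthetic scenarios

The generator emulates the statistics that matter to the tracker, not the
biophysics: biphasic templates (negative trough then positive peak, two
Gaussian lobes) with 300–1200 µV peak-to-peak and 0.27–0.53 ms trough-to-peak
at 30 kHz; gamma ISIs (shape 1.5–6) above a 1.5 ms refractory period, rates
1.5–8 Hz; per-day multiplicative log-normal amplitude steps (default sigma
0.05), bounded lobe centre/width jitter (0.02), log-normal rate steps (0.1),
and 20 µV white noise per waveform sample; permanent dropout (0.02/day) and
new-unit appearance (0.02/day, capped at 4 units/channel). Templates on a
channel are redrawn until pairwise peak-matching distance exceeds 0.1.
Default scale: 32 channels, 1–4 units each, 15 sessions of 900 s; a
"paper-like" preset (96 channels, 1–3 units, 6 sessions) produces training
sets on the order of 900 positives and 600 negatives. All randomness flows
from one master seed through named substreams (templates, drift, spikes,
noise, labels), so runs are bit-reproducible and stages independently
perturbable.

What the simulator does *not* emulate — and hence what passing benchmarks do
not establish about real data: spike-sorting errors and cluster overlap,
bursting/adaptation and behaviour-locked rate changes, correlated noise
across channels, electrode micro-motion that swaps a unit between channels,
and waveform changes that are not smooth day-to-day drift. Synthetic units
are also more cleanly separated in feature space than real neighbouring
units can be, so absolute accuracy figures here are upper bounds on
real-data performance, not predictions of it.

## Benchmarks and numerical choices

`scripts/acceptance.py` reports, for the default scenario (training on the
first five sessions, RVM-style classifier, waveform feature set): day-to-day
accuracy and exact-profile percentage for both FMD and MMD over the ten test
sessions (~600 decisions, ~74 reference profiles), the held-out ROC area on
a milder-drift scenario (amplitude sigma 0.03, where the training set is
separable), and a chance level from 100 label shuffles.

The chance control destroys label information on both sides: each shuffle
trains on permuted training labels and computes the AUC of the held-out
vectors against permuted held-out labels, giving a tight estimate centred on
0.5. (Scoring shuffle-trained models against the *true* held-out labels is
degenerate in this clean synthetic geometry: almost any fitted score is
monotone in distance-from-origin, so single-shuffle AUCs pile up near 0 and
1 — symmetric about 0.5, but with ~0.46 SD, which makes a 100-shuffle mean
an unstable estimator of chance.)

Problem sizes throughout the test suite are chosen as the smallest scales at
which the property under test is meaningful (e.g. 30 sessions for lifecycle
audits, 200 random matrices for assignment optimality, full 15-session
default scale for the drift-recovery benchmark); degenerate inputs (flat
waveforms, single-spike units, empty channels, single-class ROC inputs)
raise descriptive errors rather than propagating NaNs.
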