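# spiketrack

Automated tracking of spike-sorted single units across chronic recording
sessions.

Chronically implanted microelectrode arrays — the signal source for
brain–machine interfaces and longitudinal population-coding studies — do not
record a stable picture of the same neurons day after day. Electrode
micro-motion and tissue changes drift spike amplitudes and shapes, units
vanish, new ones appear. Anyone who wants to say *"this is the same neuron I
recorded yesterday"* either asks a human expert to eyeball average waveforms
every morning, or automates the decision. `spiketrack` automates it: at the
start of each session it compares every newly sorted unit against a
per-channel database of stored unit *profiles* and decides, unit by unit,
"new instance of a known profile" or "new unit".

## The method

For each channel and session, every spike-sorted unit is reduced to a
snapshot: its smoothed average waveform
`W̄ₓ = [Σᵢ Wₓᵢ(1)/l, …, Σᵢ Wₓᵢ(m)/l]` and its normalised inter-spike-interval
histogram (ISIH) `Hₓ`. A unit/profile-instance pair is described by a vector
of dissimilarities:

**Waveform measures** — Pearson-correlation dissimilarity `1 − r`;
normalised peak-to-peak height difference
`PH(W̄ₓ, W̄ᵧ) = |(ptp(W̄ᵧ) − ptp(W̄ₓ)) / ptp(W̄ᵧ)|`; normalised peak-to-peak
transition-time difference `PT` (the same form on the signed
`argmax − argmin` sample intervals); and a peak-matching distance `PM`
(amplitude-weighted peaks, Gaussian closeness factors, geometric mean of the
two asymmetric similarities).

**ISIH measures** — symmetrised Kullback–Leibler divergence
`[D(Hₓ‖Hᵧ) + D(Hᵧ‖Hₓ)]/2`; Bhattacharyya distance `−ln Σᵢ √(Hₓ[i]·Hᵧ[i])`;
Kolmogorov–Smirnov statistic `maxᵢ |Fₓ[i] − Fᵧ[i]|`; and the earth mover's
distance computed by the running-carry recursion over bins (equal to
`Σᵢ |Fₓ[i] − Fᵧ[i]|`).

Four *feature sets* select which measures enter the vector (set 1: all
eight; set 2: PH, PT, PM, KLD, BD, KS; set 3: ISIH only; set 4: waveform
only). A binary **match classifier** — SVM, RVM-style sparse kernel
logistic, MAP with KDE class densities, or naive Bayes — is trained on
vectors from expert-matched (here: simulator-truth) cross-day pairs (true
positives) and from pairs of units co-recorded on one channel on one day,
which are necessarily different neurons (true negatives). Its signed score
is the distance to the decision boundary.

Tracking a session then runs, per channel: build the profile × unit
dissimilarity matrix (choosing each profile's comparison instance by **FMD**,
first match scanning newest-first, or **MMD**, the match with maximum score
over all instances in a 7-session stability window); threshold it into a
membership matrix; resolve conflicts by an exhaustive **back-tracking
assignment** that maximises first the number of units attached to existing
profiles and then the total score, one profile per unit; append matched
units, open new profiles for the rest, and drop profiles unseen for more
than the stability window.

Because real chronic primate recordings of this kind are not shareable, the
package ships a simulator (`spiketrack.synthetic`) that generates
multi-day, multi-channel scenarios with biphasic spike templates, gamma ISI
statistics, day-to-day amplitude/shape/rate drift, spike noise, unit dropout
and appearance — with ground-truth identities, so every stage is testable
end to end.

## Worked example

`examples/04_track_across_days.py` simulates ten 5-minute sessions on a
10-channel array with realistic drift and dropout, trains the classifier on
the first four sessions, then tracks the remaining six:

```
session 4:  23 units,   0 reattached to stored profiles, 23 new profiles
session 5:  22 units,  22 reattached to stored profiles,  0 new profiles
session 6:  22 units,  22 reattached to stored profiles,  0 new profiles
session 7:  22 units,  21 reattached to stored profiles,  1 new profiles
session 8:  22 units,  22 reattached to stored profiles,  0 new profiles
session 9:  22 units,  22 reattached to stored profiles,  0 new profiles

day-to-day classification accuracy: 100.00%
profiles tracked exactly end-to-end: 100.00%
```

The first tracked session seeds the database (everything is new); from then
on units reattach to their profiles, and the one genuinely new unit on
session 7 correctly opens a fresh profile. *Classification accuracy* scores
every day-to-day link against ground truth; *correct profiles* is stricter —
a profile counts only if its entire multi-day instance set is exact.

The other examples cover the waveform measures, the ISIH measures,
classifier training + ROC with a label-shuffle chance control, and the
calendar-ordered sliding validation protocol. A thin CLI wraps the same
pipeline (`spiketrack simulate | train | track | evaluate | validate | roc`);
sessions, truth tables, reports and profile stores are plain CSV/JSON.

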