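"""Train a match/non-match classifier on a simulated scenario and plot ROC.

Simulates a small drifting array, builds labelled dissimilarity vectors
(positives: same unit on consecutive days; negatives: different units
co-recorded on one channel), trains the RVM-style classifier on the first
half and reports held-out ROC area plus a label-shuffled chance estimate.
"""

import numpy as np

from spiketrack.classifiers import TrainingSet, roc_curve, train
from spiketrack.synthetic import ScenarioConfig, generate_scenario, make_labeled_vectors

cfg = ScenarioConfig(channels=10, days=8, duration=300.0, seed=3)
sessions, truth = generate_scenario(cfg)

tr = make_labeled_vectors(sessions[:4], truth, feature_set_id=4, days=[0, 1, 2, 3])
te = make_labeled_vectors(sessions[4:], truth, feature_set_id=4, days=[4, 5, 6, 7])
print(f"training vectors: {len(tr.positives)} positives, {len(tr.negatives)} negatives")

model = train(tr, "RVM", seed=0)
X = np.vstack([te.negatives, te.positives])
y = np.r_[np.zeros(len(te.negatives)), np.ones(len(te.positives))]
*_, auc = roc_curve(model, X, y)
print(f"held-out ROC area: {auc:.4f}  (1.0 = perfect match/non-match ranking)")

rng = np.random.default_rng(0)
Xtr = np.vstack([tr.negatives, tr.positives])
ytr = np.r_[np.zeros(len(tr.negatives)), np.ones(len(tr.positives))]
aucs = []
for _ in range(20):
    ys = rng.permutation(ytr)
    sh = train(TrainingSet(Xtr[ys == 1], Xtr[ys == 0], 4), "RVM", seed=0)
    *_, a = roc_curve(sh, X, rng.permutation(y))
    aucs.append(a)
print(f"label-shuffled chance AUC: {np.mean(aucs):.3f}  (should sit near 0.5)")
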