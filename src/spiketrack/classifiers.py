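"""Match/non-match classifiers over unit-pair dissimilarity vectors.

The tracking decision — "are these two single units, recorded on the same
channel on different days, the same neuron?" — is made by a binary classifier
trained on labelled dissimilarity vectors:

* true positives: vectors from cross-day pairs of the *same* unit;
* true negatives: vectors from pairs of units co-recorded on the same channel
  on the same day (simultaneously recorded units are necessarily different).

Four classifier families are provided, all exposing a signed match score
whose sign encodes the decision (positive = match) and whose magnitude is
monotone in confidence:

``SVM``  soft-margin RBF support vector machine (kernel sigma = sqrt(n
         features), slack parameter C = 1); score is the signed distance to
         the decision plane.
``RVM``  sparse Bayesian-style kernel logistic model, realised as an
         L1-regularised logistic regression over the same RBF kernel basis
         (recorded in the model metadata); score is the log-odds of a match.
``MAP``  maximum a posteriori rule with class priors from training
         frequencies and class-conditional joint densities by multivariate
         Gaussian KDE (Scott's rule); score is the posterior log ratio.
``NB``   naive Bayes with per-feature 1-D KDE conditionals and no priors;
         score is the summed per-feature log likelihood ratio.

Feature sets index which dissimilarities enter the vector:

* Set 1: PC, PH, PT, PM, KLD, BD, KS, EMD
* Set 2: PH, PT, PM, KLD, BD, KS
* Set 3: KLD, BD, KS
* Set 4: PH, PT, PM
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import joblib
import numpy as np
from scipy.stats import gaussian_kde
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVC

from .isih import IsihBinning

__all__ = [
    "FEATURE_SETS",
    "WAVEFORM_FEATURES",
    "ISIH_FEATURES",
    "MATCH",
    "NON_MATCH",
    "DissimilarityVector",
    "TrainingSet",
    "ClassifierModel",
    "build_training_set",
    "train",
    "classify",
    "roc_curve",
    "save_model",
    "load_model",
]

FEATURE_SETS: dict[int, tuple[str, ...]] = {
    1: ("PC", "PH", "PT", "PM", "KLD", "BD", "KS", "EMD"),
    2: ("PH", "PT", "PM", "KLD", "BD", "KS"),
    3: ("KLD", "BD", "KS"),
    4: ("PH", "PT", "PM"),
}
WAVEFORM_FEATURES = ("PC", "PH", "PT", "PM")
ISIH_FEATURES = ("KLD", "BD", "KS", "EMD")

MATCH = "match"
NON_MATCH = "non-match"

CLASSIFIER_KINDS = ("SVM", "RVM", "MAP", "NB")


@dataclass(frozen=True)
class DissimilarityVector:
    """Ordered pairwise dissimilarities for one feature set."""

    values: np.ndarray
    feature_set_id: int

    def __post_init__(self) -> None:
        if self.feature_set_id not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set_id}")
        v = np.asarray(self.values, dtype=float)
        names = FEATURE_SETS[self.feature_set_id]
        if v.shape != (len(names),):
            raise ValueError(
                f"feature set {self.feature_set_id} expects {len(names)} values "
                f"({', '.join(names)}); got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("dissimilarity values must be finite and >= 0")
        object.__setattr__(self, "values", v)

    @property
    def names(self) -> tuple[str, ...]:
        return FEATURE_SETS[self.feature_set_id]


@dataclass
class TrainingSet:
    """Labelled dissimilarity vectors: positives (matches) and negatives."""

    positives: np.ndarray
    negatives: np.ndarray
    feature_set_id: int

    def __post_init__(self) -> None:
        n = len(FEATURE_SETS[self.feature_set_id])
        self.positives = np.atleast_2d(np.asarray(self.positives, dtype=float))
        self.negatives = np.atleast_2d(np.asarray(self.negatives, dtype=float))
        if self.positives.size == 0 or self.negatives.size == 0:
            raise ValueError("untrainable set: both classes must be non-empty")
        if self.positives.shape[1] != n or self.negatives.shape[1] != n:
            raise ValueError("vector width does not match the feature set")

    @classmethod
    def from_vectors(
        cls,
        positives: Sequence[DissimilarityVector],
        negatives: Sequence[DissimilarityVector],
    ) -> "TrainingSet":
        if not positives or not negatives:
            raise ValueError("untrainable set: both classes must be non-empty")
        fsid = positives[0].feature_set_id
        if any(v.feature_set_id != fsid for v in list(positives) + list(negatives)):
            raise ValueError("training vectors must share one feature set")
        return cls(
            np.stack([v.values for v in positives]),
            np.stack([v.values for v in negatives]),
            fsid,
        )

    @property
    def n_features(self) -> int:
        return len(FEATURE_SETS[self.feature_set_id])

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.positives).tobytes())
        h.update(np.ascontiguousarray(self.negatives).tobytes())
        h.update(str(self.feature_set_id).encode())
        return h.hexdigest()[:16]


class ClassifierModel:
    """A trained match/non-match rule with a signed match score.

    ``score(X) > 0`` if and only if the decision is a match; magnitude is
    monotone in the model's confidence (margin or log-odds).
    """

    kind: str
    feature_set_id: int

    def __init__(self, kind: str, feature_set_id: int, meta: dict | None = None):
        self.kind = kind
        self.feature_set_id = feature_set_id
        self.meta = dict(meta or {})

    def score(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def score_one(self, x: DissimilarityVector) -> float:
        if x.feature_set_id != self.feature_set_id:
            raise ValueError(
                f"feature-set mismatch: model uses set {self.feature_set_id}, "
                f"vector carries set {x.feature_set_id}"
            )
        return float(self.score(x.values[None, :])[0])


class _SvmModel(ClassifierModel):
    def __init__(self, svc: SVC, feature_set_id: int, meta: dict):
        super().__init__("SVM", feature_set_id, meta)
        self._svc = svc

    def score(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self._svc.decision_function(X), dtype=float)


class _RvmModel(ClassifierModel):
    """Sparse kernel logistic model over RBF basis functions.

    L1 regularisation drives most basis-function weights to zero, retaining a
    sparse set of "relevance" points, and the logistic link yields calibrated
    match probabilities; the score is the log-odds.
    """

    def __init__(self, centers, gamma, clf, feature_set_id: int, meta: dict):
        super().__init__("RVM", feature_set_id, meta)
        self._centers = centers
        self._gamma = gamma
        self._clf = clf

    def score(self, X: np.ndarray) -> np.ndarray:
        K = rbf_kernel(X, self._centers, gamma=self._gamma)
        return np.asarray(self._clf.decision_function(K), dtype=float)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.score(X)))


class _DensityModel(ClassifierModel):
    """Log-density-ratio rule shared by the MAP and NB classifiers.

    Holds one log-density callable per class (joint for MAP, factorised over
    features for NB) plus log priors; the score is
    ``log p(x|match) + log P(match) - log p(x|non-match) - log P(non-match)``.
    """

    def __init__(
        self,
        kind: str,
        logpdf_match: Callable[[np.ndarray], np.ndarray],
        logpdf_nonmatch: Callable[[np.ndarray], np.ndarray],
        log_prior_match: float,
        log_prior_nonmatch: float,
        feature_set_id: int,
        meta: dict | None = None,
    ):
        super().__init__(kind, feature_set_id, meta)
        self._lp1 = logpdf_match
        self._lp0 = logpdf_nonmatch
        self._log_prior1 = log_prior_match
        self._log_prior0 = log_prior_nonmatch

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (
            np.asarray(self._lp1(X), dtype=float)
            + self._log_prior1
            - np.asarray(self._lp0(X), dtype=float)
            - self._log_prior0
        )


def _check_not_degenerate(X: np.ndarray, label: str) -> None:
    if X.shape[0] < 2 or np.all(np.ptp(X, axis=0) == 0):
        raise ValueError(
            f"degenerate training data: the {label} class has no variability, "
            "its density cannot be estimated"
        )


class _JointKdeLogpdf:
    """Picklable joint-KDE log density (Gaussian kernel, Scott's rule)."""

    def __init__(self, X: np.ndarray):
        self._kde = gaussian_kde(X.T)

    def __call__(self, Q: np.ndarray) -> np.ndarray:
        return self._kde.logpdf(Q.T)


class _FactorisedKdeLogpdf:
    """Picklable per-feature 1-D KDE log density (naive-Bayes factorisation)."""

    def __init__(self, X: np.ndarray):
        self._kdes = [gaussian_kde(X[:, j]) for j in range(X.shape[1])]

    def __call__(self, Q: np.ndarray) -> np.ndarray:
        return np.sum([k.logpdf(Q[:, j]) for j, k in enumerate(self._kdes)], axis=0)


def train(ts: TrainingSet, kind: str, seed: int = 0) -> ClassifierModel:
    """Fit a match/non-match classifier of the requested kind.

    The RBF kernel sigma for SVM/RVM is the square root of the number of
    features (gamma = 1 / (2 n)); features are used on their raw scales.
    """
    kind = kind.upper()
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")
    n = ts.n_features
    X = np.vstack([ts.negatives, ts.positives])
    y = np.concatenate([np.zeros(len(ts.negatives)), np.ones(len(ts.positives))])
    gamma = 1.0 / (2.0 * n)  # kernel sigma = sqrt(n)
    meta = {"training_digest": ts.digest(), "n_pos": len(ts.positives), "n_neg": len(ts.negatives)}

    if kind == "SVM":
        svc = SVC(C=1.0, kernel="rbf", gamma=gamma, random_state=seed)
        svc.fit(X, y)
        return _SvmModel(svc, ts.feature_set_id, meta)

    if kind == "RVM":
        # weak L1 regularisation (C = 100): enough to sparsify the kernel
        # basis while letting tight match clusters be fit exactly, mimicking
        # the near-unregularised fit of Bayesian ARD
        K = rbf_kernel(X, X, gamma=gamma)
        clf = LogisticRegression(
            l1_ratio=1.0, C=100.0, solver="liblinear", random_state=seed, max_iter=2000
        )
        clf.fit(K, y)
        meta["implementation"] = "l1-regularised kernel logistic regression"
        return _RvmModel(X.copy(), gamma, clf, ts.feature_set_id, meta)

    _check_not_degenerate(ts.positives, "match")
    _check_not_degenerate(ts.negatives, "non-match")
    if kind == "MAP":
        n_pos, n_neg = len(ts.positives), len(ts.negatives)
        total = n_pos + n_neg
        return _DensityModel(
            "MAP",
            _JointKdeLogpdf(ts.positives),
            _JointKdeLogpdf(ts.negatives),
            float(np.log(n_pos / total)),
            float(np.log(n_neg / total)),
            ts.feature_set_id,
            meta,
        )

    # NB: per-feature conditionals, uniform (absent) priors
    return _DensityModel(
        "NB",
        _FactorisedKdeLogpdf(ts.positives),
        _FactorisedKdeLogpdf(ts.negatives),
        0.0,
        0.0,
        ts.feature_set_id,
        meta,
    )


def classify(model: ClassifierModel, x: DissimilarityVector) -> tuple[str, float]:
    """Binary match decision plus the signed match score."""
    s = model.score_one(x)
    return (MATCH if s > 0 else NON_MATCH), s


def roc_curve(model: ClassifierModel, vectors: np.ndarray, labels: np.ndarray):
    """ROC of the model's score on labelled vectors.

    Returns (thresholds, tpr, fpr, auc); the AUC is the trapezoid-rule area.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    scores = model.score(np.atleast_2d(np.asarray(vectors, dtype=float)))
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return thresholds, tpr, fpr, auc


def build_training_set(
    tracked_positives,
    same_day_units,
    feature_set_id: int,
    *,
    smoothing_sigma: float = 1.0,
    binning=None,
) -> TrainingSet:
    """Build labelled vectors from matched cross-day pairs and same-day units.

    ``tracked_positives`` is an iterable of (newer, older) SpikeUnit pairs
    known to be the same neuron on the same channel on distinct days — the
    older unit acts as the stored-profile reference.  ``same_day_units`` is an
    iterable of per-channel per-day unit lists; every unordered pair of
    co-recorded units contributes one negative vector.
    """
    # imported here: the tracker module provides snapshotting on top of the
    # feature modules and itself consumes this module's model interface
    from .tracker import TrackerConfig, pair_dissimilarity, snapshot

    cfg = TrackerConfig(
        feature_set_id=feature_set_id, smoothing_sigma=smoothing_sigma,
        binning=binning if binning is not None else IsihBinning(),
    )
    cache: dict[int, object] = {}

    def snap(unit):
        key = id(unit)
        if key not in cache:
            cache[key] = snapshot(unit, cfg)
        return cache[key]

    positives = []
    for newer, older in tracked_positives:
        if newer.channel_id != older.channel_id:
            raise ValueError("matched pair must come from one channel")
        if newer.day == older.day:
            raise ValueError("matched pair must come from distinct days")
        positives.append(pair_dissimilarity(snap(newer), snap(older), feature_set_id))

    negatives = []
    for units in same_day_units:
        if len(units) < 2:
            continue
        for a, b in combinations(units, 2):
            negatives.append(pair_dissimilarity(snap(a), snap(b), feature_set_id))

    if not positives or not negatives:
        raise ValueError("untrainable set: need at least one positive and one negative pair")
    return TrainingSet.from_vectors(positives, negatives)


def save_model(model: ClassifierModel, path) -> None:
    """Persist a trained model (kind, feature set, fitted state, digest)."""
    joblib.dump(model, path)


def load_model(path) -> ClassifierModel:
    model = joblib.load(path)
    if not isinstance(model, ClassifierModel):
        raise ValueError(f"{path} does not contain a spiketrack classifier model")
    return model
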