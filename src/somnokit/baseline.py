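"""Random-forest + HMM baseline sleep stager.

The comparison method and the free-living sleep/wake ("time in bed")
detector: hand-crafted per-epoch features feed a random forest, whose
per-epoch class probabilities are smoothed with a Viterbi decode under an
HMM fitted on the training labels.  Out-of-bag probabilities calibrate the
HMM emission model so the smoothing stage never sees resubstitution
(over-confident) predictions.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .features import extract_feature_matrix
from .hmm import HmmParams, fit_hmm, viterbi_smooth
from .types import MISSING, EpochArray


def _night_signals(night) -> np.ndarray:
    if isinstance(night, EpochArray):
        return night.signals
    return np.asarray(night)


def _night_wear(night) -> np.ndarray:
    if isinstance(night, EpochArray):
        return night.wear
    return np.ones(len(night), dtype=bool)


def train_rf(
    features: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit a seeded random forest with out-of-bag probability estimates."""
    labels = np.asarray(labels, dtype=object)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(np.asarray(features, dtype=float), labels.astype(str))
    return rf


class RandomForestHmmClassifier(ClassifierMixin, BaseEstimator):
    """Per-epoch random forest with HMM (Viterbi) smoothing.

    ``fit``/``predict`` operate on nights: lists whose elements are either
    ``(m_i, 900, 3)`` signal stacks or :class:`EpochArray` objects, with a
    matching list of per-epoch label arrays.  Labels may be 5-, 3- or
    2-class; the class set is inferred from the training labels.  At
    predict time, non-wear epochs of an ``EpochArray`` receive the missing
    marker and smoothing runs over the scored epochs only.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        smoothing: float = 1.0,
        smooth: bool = True,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.smoothing = smoothing
        self.smooth = smooth
        self.random_state = random_state

    def fit(self, nights: list, labels: list) -> "RandomForestHmmClassifier":
        if len(nights) == 0 or len(nights) != len(labels):
            raise ValueError("need equally many nights and label sequences")
        feats, labs, lengths = [], [], []
        for night, lab in zip(nights, labels):
            sig = _night_signals(night)
            lab = np.asarray(lab, dtype=object)
            if len(sig) != len(lab):
                raise ValueError("night and label lengths differ")
            feats.append(extract_feature_matrix(sig).to_numpy())
            labs.append(lab.astype(str))
            lengths.append(len(lab))
        X = np.vstack(feats)
        y = np.concatenate(labs)
        self.rf_ = train_rf(X, y, n_trees=self.n_estimators, seed=self.random_state)
        self.classes_ = tuple(self.rf_.classes_)
        oob = np.array(self.rf_.oob_decision_function_, dtype=float)
        bad = ~np.isfinite(oob).all(axis=1)
        if bad.any():  # rows never out-of-bag fall back to in-bag probabilities
            oob[bad] = self.rf_.predict_proba(X[bad])
        splits = np.cumsum(lengths)[:-1]
        self.hmm_ = fit_hmm(
            labs, np.split(oob, splits), self.classes_, smoothing=self.smoothing
        )
        return self

    def predict_proba(self, nights: list) -> list:
        """Raw (unsmoothed) per-epoch class probabilities per night."""
        out = []
        for night in nights:
            sig = _night_signals(night)
            if len(sig) == 0:
                out.append(np.zeros((0, len(self.classes_))))
                continue
            X = extract_feature_matrix(sig).to_numpy()
            out.append(self.rf_.predict_proba(X))
        return out

    def predict(self, nights: list, scheme: str | None = None) -> list:
        """Per-night label sequences (Viterbi-smoothed unless smooth=False).

        When the classifier was trained on five-class labels, ``scheme``
        collapses the decoded path to the three- or two-class space.
        """
        from .types import STAGES_5, collapse_labels

        preds = []
        for night, probs in zip(nights, self.predict_proba(nights)):
            wear = _night_wear(night)
            labels = np.full(len(wear), MISSING, dtype=object)
            if wear.any():
                p = probs[wear]
                if self.smooth:
                    labels[wear] = viterbi_smooth(p, self.hmm_)
                else:
                    labels[wear] = np.array(self.classes_, dtype=object)[p.argmax(axis=1)]
            if scheme is not None and scheme != "five":
                if set(self.classes_) != set(STAGES_5):
                    raise ValueError("collapsing requires a five-class classifier")
                labels = collapse_labels(labels, scheme)
            preds.append(labels)
        return preds
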