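"""Hidden-Markov smoothing of per-epoch classifier output.

A discrete HMM whose hidden states are the true sleep stages and whose
"emissions" are the classifier's per-epoch class probabilities.  The
transition matrix comes from bigram counts of reference label sequences,
the emission model is a calibration matrix P(classifier says j | truth i)
estimated from held-out (out-of-bag) predictions, and decoding is the
Viterbi maximum a-posteriori state path in the log domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PROB_FLOOR = 1e-6


@dataclass
class HmmParams:
    """Transition / emission-calibration / initial parameters in log space."""

    classes: tuple                  # ordered label set (k,)
    log_transition: np.ndarray      # (k, k)
    log_emission_calibration: np.ndarray  # (k, k): P(pred j | true i)
    log_initial: np.ndarray         # (k,)

    def __post_init__(self) -> None:
        k = len(self.classes)
        for name in ("log_transition", "log_emission_calibration", "log_initial"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
        if self.log_transition.shape != (k, k) or self.log_emission_calibration.shape != (k, k):
            raise ValueError("transition and emission matrices must be k x k")
        if self.log_initial.shape != (k,):
            raise ValueError("initial must have length k")
        for name in ("log_transition", "log_emission_calibration"):
            rows = np.exp(getattr(self, name)).sum(axis=1)
            if not np.allclose(rows, 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must normalise to 1")
        if not np.isclose(np.exp(self.log_initial).sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")


def _row_normalise_log(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    rows = counts.sum(axis=1, keepdims=True)
    probs = np.where(rows > 0, counts / np.where(rows > 0, rows, 1.0), 1.0 / counts.shape[1])
    return np.log(np.maximum(probs, 1e-300))


def fit_hmm(
    true_sequences: list,
    predicted_probabilities: list,
    classes: tuple,
    smoothing: float = 1.0,
) -> HmmParams:
    """Estimate HMM parameters from aligned truth/prediction sequences.

    * transition: row-normalised bigram counts of the true labels
      (plus ``smoothing`` pseudo-counts),
    * emission calibration: row-normalised confusion of argmax predictions
      against truth (plus ``smoothing``),
    * initial: empirical stage frequencies over all epochs.
    """
    if len(true_sequences) == 0 or len(true_sequences) != len(predicted_probabilities):
        raise ValueError("need equally many non-empty truth and prediction sequences")
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    trans = np.full((k, k), float(smoothing))
    emiss = np.full((k, k), float(smoothing))
    init = np.zeros(k)
    total = 0
    for labels, probs in zip(true_sequences, predicted_probabilities):
        labels = np.asarray(labels, dtype=object)
        probs = np.asarray(probs, dtype=float)
        if len(labels) == 0 or probs.shape != (len(labels), k):
            raise ValueError("each sequence needs labels (T,) and probabilities (T, k)")
        codes = np.array([idx[l] for l in labels])
        np.add.at(init, codes, 1)
        total += len(codes)
        np.add.at(trans, (codes[:-1], codes[1:]), 1)
        np.add.at(emiss, (codes, probs.argmax(axis=1)), 1)
    if total == 0:
        raise ValueError("empty input")
    return HmmParams(
        classes=tuple(classes),
        log_transition=_row_normalise_log(trans),
        log_emission_calibration=_row_normalise_log(emiss),
        log_initial=np.log(np.maximum(init / total, 1e-300)),
    )


def viterbi_smooth(scores: np.ndarray, params: HmmParams) -> np.ndarray:
    """Maximum a-posteriori state path for per-epoch class scores.

    ``scores`` is (T, k) classifier probabilities (floored at 1e-6 before
    logs).  The emission log-likelihood of hidden state i at time t is
    ``log sum_j P(pred j | true i) * score[t, j]``.  Returns the label
    path as an array of class names (empty input gives empty output).
    """
    scores = np.asarray(scores, dtype=float)
    k = len(params.classes)
    if scores.size == 0:
        return np.empty(0, dtype=object)
    if scores.ndim != 2 or scores.shape[1] != k:
        raise ValueError(f"scores must be (T, {k})")
    floored = np.maximum(scores, PROB_FLOOR)
    cal = np.exp(params.log_emission_calibration)  # (k_true, k_pred)
    log_e = np.log(np.maximum(floored @ cal.T, 1e-300))  # (T, k_true)
    T = len(scores)
    delta = params.log_initial + log_e[0]
    back = np.zeros((T, k), dtype=np.int64)
    A = params.log_transition
    for t in range(1, T):
        cand = delta[:, None] + A  # (from, to)
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + log_e[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(delta.argmax())
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return np.array(params.classes, dtype=object)[path]
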