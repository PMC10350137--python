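"""Deep sleep-staging network and its self-supervised pretraining.

The classifier encodes each 30-s epoch with a 1-D convolutional residual
network, models temporal dependencies across the whole night with a
bidirectional LSTM, and maps each epoch to five-class stage logits through
two fully-connected layers.  Training uses class-weighted cross-entropy on
whole-night sequences.  The encoder can be pretrained with multi-task
self-supervision: discriminating whether a window was time-reversed,
segment-permuted, or time-warped.

Five-class output collapses to three classes (wake / NREM / REM) or two
classes (wake / sleep) by summing probabilities before the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _autodiff as ad
from ._nn import LSTM, Adam, ConvEncoder, Dropout, Linear, Module
from .types import (
    MISSING,
    SAMPLES_PER_EPOCH,
    STAGES_3,
    STAGES_5,
    EpochArray,
    collapse_labels,
)

SSL_TASKS = ("reversal", "permutation", "time_warp")


# ---------------------------------------------------------------------------
# collapsing
# ---------------------------------------------------------------------------

def collapse_probs(probs: np.ndarray, scheme: str) -> np.ndarray:
    """Collapse (m, 5) stage probabilities by summation.

    Column order is (W, N1, N2, N3, R) in, (W, NREM, R) or (W, S) out.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 5:
        raise ValueError("expected (m, 5) probabilities")
    if scheme == "three":
        return np.column_stack([probs[:, 0], probs[:, 1:4].sum(axis=1), probs[:, 4]])
    if scheme == "two":
        return np.column_stack([probs[:, 0], probs[:, 1:].sum(axis=1)])
    if scheme == "five":
        return probs
    raise ValueError(f"unknown scheme {scheme!r}")


def collapse(obj: np.ndarray, scheme: str) -> np.ndarray:
    """Collapse labels (1-D) or probabilities (2-D) to a coarser scheme."""
    arr = np.asarray(obj)
    if arr.ndim == 2:
        return collapse_probs(arr, scheme)
    return collapse_labels(arr, scheme)


@dataclass
class StagePrediction:
    """Per-epoch five-class probabilities; NaN rows mark unscored epochs."""

    epoch_starts: np.ndarray
    probs: np.ndarray                      # (m, 5), NaN rows for non-wear
    classes: tuple = STAGES_5

    def collapse(self, scheme: str) -> np.ndarray:
        return collapse_probs(self.probs, scheme)

    def labels(self, scheme: str = "five") -> np.ndarray:
        """Collapse probabilities first, then argmax; missing stays missing."""
        from .types import stage_classes

        p = self.collapse(scheme)
        names = np.array(stage_classes(scheme), dtype=object)
        out = np.full(len(p), MISSING, dtype=object)
        ok = np.isfinite(p).all(axis=1)
        out[ok] = names[p[ok].argmax(axis=1)]
        return out


# ---------------------------------------------------------------------------
# self-supervised transformations
# ---------------------------------------------------------------------------

@dataclass
class SslTaskSpec:
    tasks: tuple = SSL_TASKS
    permutation_segments: int = 4
    warp_factor_range: tuple = (0.5, 2.0)
    apply_prob: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.tasks:
            raise ValueError("at least one self-supervision task must be enabled")
        bad = set(self.tasks) - set(SSL_TASKS)
        if bad:
            raise ValueError(f"unknown tasks: {sorted(bad)}")
        if not 0.0 < self.apply_prob < 1.0:
            raise ValueError("apply_prob must be in (0, 1)")
        if SAMPLES_PER_EPOCH % self.permutation_segments:
            raise ValueError("permutation_segments must divide 900")


def _time_warp(w: np.ndarray, factor: float) -> np.ndarray:
    n = len(w)
    L = max(2, int(round(n * factor)))
    src = np.linspace(0.0, 1.0, n)
    dst = np.linspace(0.0, 1.0, L)
    warped = np.column_stack([np.interp(dst, src, w[:, k]) for k in range(w.shape[1])])
    if L >= n:
        start = (L - n) // 2
        return warped[start : start + n]
    out = np.empty_like(w)
    out[:L] = warped
    out[L:] = warped[-1]
    return out


def ssl_transform(
    window: np.ndarray, spec: SslTaskSpec, rng: np.random.Generator | int
) -> tuple[np.ndarray, np.ndarray]:
    """Independently apply each enabled transformation with ``apply_prob``.

    Returns the transformed window and a 3-vector of 0/1 task labels in
    the fixed order (reversal, permutation, time_warp).
    """
    spec.validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    w = np.asarray(window, dtype=float).copy()
    if w.shape != (SAMPLES_PER_EPOCH, 3):
        raise ValueError(f"window must be ({SAMPLES_PER_EPOCH}, 3)")
    labels = np.zeros(3, dtype=np.int64)
    if "reversal" in spec.tasks and rng.random() < spec.apply_prob:
        w = w[::-1].copy()
        labels[0] = 1
    if "permutation" in spec.tasks and rng.random() < spec.apply_prob:
        nseg = spec.permutation_segments
        perm = rng.permutation(nseg)
        while (perm == np.arange(nseg)).all():
            perm = rng.permutation(nseg)
        segs = np.split(w, nseg)
        w = np.concatenate([segs[i] for i in perm])
        labels[1] = 1
    if "time_warp" in spec.tasks and rng.random() < spec.apply_prob:
        lo, hi = spec.warp_factor_range
        w = _time_warp(w, rng.uniform(lo, hi))
        labels[2] = 1
    return w, labels


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def _default_channels(blocks: int) -> tuple:
    return tuple(8 * (i + 1) for i in range(blocks + 1))


def paper_scale_config() -> dict:
    """Full-scale preset: 8 residual blocks (17 conv layers) and wide FC/LSTM."""
    return dict(
        encoder_blocks=8,
        channels=(64, 64, 128, 128, 256, 256, 512, 512, 512),
        kernel=7,
        lstm_hidden=128,
        fc_dims=(128, 5),
    )


class _SleepNetModel(Module):
    def __init__(self, channels, kernel, lstm_hidden, bidirectional, fc_dims, dropout, rng):
        self.encoder = ConvEncoder(channels, kernel, rng)
        self.lstm = LSTM(self.encoder.feat_dim, lstm_hidden, rng, bidirectional)
        self.fc1 = Linear(self.lstm.out_dim, fc_dims[0], rng)
        self.drop = Dropout(dropout, rng)
        self.fc2 = Linear(fc_dims[0], fc_dims[1], rng)

    def __call__(self, signals: np.ndarray) -> ad.Tensor:
        feats = self.encoder(ad.Tensor(signals))
        seq = self.lstm(feats)
        return self.fc2(self.drop(self.fc1(seq).relu()))


class SleepNetClassifier(ClassifierMixin, BaseEstimator):
    """Convolutional-recurrent five-class sleep stager.

    ``fit`` takes whole nights: a list of ``(m_i, 900, 3)`` epoch stacks
    (or :class:`EpochArray`) and a matching list of per-epoch five-class
    label arrays.  Each night is one sequence for the recurrent layer.
    ``predict_proba`` returns :class:`StagePrediction` objects whose
    probabilities can be collapsed to 3 or 2 classes.
    """

    def __init__(
        self,
        encoder_blocks: int = 4,
        channels: tuple | None = None,
        kernel: int = 9,
        lstm_hidden: int = 32,
        lstm_bidirectional: bool = True,
        fc_dims: tuple = (64, 5),
        dropout: float = 0.1,
        lr: float = 3e-3,
        epochs: int = 10,
        batch_nights: int = 1,
        seed: int = 0,
        encoder_init: list | None = None,
        freeze_encoder: bool = False,
    ):
        self.encoder_blocks = encoder_blocks
        self.channels = channels
        self.kernel = kernel
        self.lstm_hidden = lstm_hidden
        self.lstm_bidirectional = lstm_bidirectional
        self.fc_dims = fc_dims
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.batch_nights = batch_nights
        self.seed = seed
        self.encoder_init = encoder_init
        self.freeze_encoder = freeze_encoder

    # -- internals ----------------------------------------------------------

    def _build(self, rng: np.random.Generator) -> _SleepNetModel:
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        if len(self.fc_dims) != 2:
            raise ValueError("exactly two fully-connected layers")
        channels = self.channels or _default_channels(self.encoder_blocks)
        if len(channels) != self.encoder_blocks + 1:
            raise ValueError("channels must list stem + one width per block")
        model = _SleepNetModel(
            channels, self.kernel, self.lstm_hidden, self.lstm_bidirectional,
            self.fc_dims, self.dropout, rng,
        )
        if self.encoder_init is not None:
            model.encoder.load_state_dict(self.encoder_init)
        return model

    @staticmethod
    def _signals(night) -> np.ndarray:
        sig = night.signals if isinstance(night, EpochArray) else np.asarray(night)
        if sig.ndim != 3 or sig.shape[1:] != (SAMPLES_PER_EPOCH, 3):
            raise ValueError(f"night must be (m, {SAMPLES_PER_EPOCH}, 3)")
        return np.asarray(sig, dtype=np.float32)

    # -- estimator API --------------------------------------------------------

    def fit(self, nights: list, labels: list) -> "SleepNetClassifier":
        if len(nights) == 0 or len(nights) != len(labels):
            raise ValueError("need equally many nights and label sequences")
        stage_idx = {s: i for i, s in enumerate(STAGES_5)}
        sigs, targets = [], []
        for night, lab in zip(nights, labels):
            sig = self._signals(night)
            lab = np.asarray(lab, dtype=object)
            if len(sig) != len(lab):
                raise ValueError("night and label lengths differ")
            bad = set(lab) - set(STAGES_5)
            if bad:
                raise ValueError(f"labels outside the five-class space: {sorted(bad)}")
            sigs.append(sig)
            targets.append(np.array([stage_idx[l] for l in lab]))
        all_t = np.concatenate(targets)
        if len(np.unique(all_t)) < 2:
            raise ValueError("training labels contain a single class")
        counts = np.bincount(all_t, minlength=5).astype(float)
        weights = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
        weights = weights * (counts > 0).sum() / weights.sum()  # mean 1 over present classes
        rng = np.random.default_rng(self.seed)
        model = self._build(rng)
        params = model.params()
        if self.freeze_encoder:
            enc = set(map(id, model.encoder.params()))
            params = [p for p in params if id(p) not in enc]
        opt = Adam(params, lr=self.lr)
        self.history_ = []
        order = np.arange(len(sigs))
        for _ in range(self.epochs):
            rng.shuffle(order)
            total, nb = 0.0, 0
            for start in range(0, len(order), self.batch_nights):
                batch = order[start : start + self.batch_nights]
                opt.zero_grad()
                batch_loss = 0.0
                # backward per night: gradients accumulate, graphs are freed
                for j in batch:
                    logits = model(sigs[j])
                    loss = ad.softmax_cross_entropy(logits, targets[j], weights) * (
                        1.0 / len(batch)
                    )
                    loss.backward()
                    batch_loss += float(loss.data)
                opt.step()
                total += batch_loss
                nb += 1
            self.history_.append(total / max(nb, 1))
        # recompute normalisation statistics under the final weights
        model.reset_norm_stats()
        with ad.no_grad():
            for _ in range(3):
                for sig in sigs:
                    model(sig)
        model.eval()
        self.model_ = model
        self.classes_ = STAGES_5
        return self

    def predict_proba(self, nights: list) -> list:
        """One :class:`StagePrediction` per night; non-wear epochs are NaN."""
        out = []
        for night in nights:
            sig = self._signals(night)
            wear = night.wear if isinstance(night, EpochArray) else np.ones(len(sig), dtype=bool)
            starts = (
                night.epoch_starts
                if isinstance(night, EpochArray)
                else np.arange(len(sig)).astype("datetime64[s]")
            )
            probs = np.full((len(sig), 5), np.nan)
            if wear.any():
                with ad.no_grad():
                    logits = self.model_(sig[wear])
                probs[wear] = ad.softmax(logits.data, axis=1)
            out.append(StagePrediction(np.asarray(starts), probs))
        return out

    def predict(self, nights: list, scheme: str = "five") -> list:
        return [p.labels(scheme) for p in self.predict_proba(nights)]


def train_sleepnet(nights: list, labels: list, **config) -> SleepNetClassifier:
    """Convenience wrapper: build, fit and return a classifier."""
    return SleepNetClassifier(**config).fit(nights, labels)


def predict_stages(model: SleepNetClassifier, epochs: EpochArray) -> StagePrediction:
    """Score one night; non-wear epochs are emitted as missing (NaN rows)."""
    return model.predict_proba([epochs])[0]


# ---------------------------------------------------------------------------
# self-supervised pretraining
# ---------------------------------------------------------------------------

@dataclass
class SslPretrainResult:
    encoder_state: list                 # encoder weights after pretraining
    loss_history: list = field(default_factory=list)
    heads_state: list = field(default_factory=list)


def pretrain_ssl(
    windows: np.ndarray,
    spec: SslTaskSpec | None = None,
    encoder_blocks: int = 4,
    channels: tuple | None = None,
    kernel: int = 7,
    epochs: int = 5,
    batch_size: int = 64,
    lr: float = 1e-3,
    seed: int = 0,
) -> SslPretrainResult:
    """Pretrain a convolutional encoder by transformation discrimination.

    Each window is independently transformed per :func:`ssl_transform`; a
    per-task linear head on the encoder output predicts which of the
    enabled transformations were applied, and the summed binary
    cross-entropies are minimised with Adam.  Returns the encoder weights
    (usable as ``encoder_init`` of :class:`SleepNetClassifier`) plus the
    per-epoch loss history.
    """
    spec = spec or SslTaskSpec()
    spec.validate()
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 3 or windows.shape[1:] != (SAMPLES_PER_EPOCH, 3):
        raise ValueError(f"windows must be (n, {SAMPLES_PER_EPOCH}, 3)")
    rng = np.random.default_rng(seed)
    encoder = ConvEncoder(channels or _default_channels(encoder_blocks), kernel, rng)
    heads = {t: Linear(encoder.feat_dim, 1, rng) for t in SSL_TASKS if t in spec.tasks}
    params = encoder.params()
    for h in heads.values():
        params += h.params()
    opt = Adam(params, lr=lr)
    history = []
    n = len(windows)
    task_col = {t: i for i, t in enumerate(SSL_TASKS)}
    for _ in range(epochs):
        order = rng.permutation(n)
        total, nb = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            ws, ls = zip(*(ssl_transform(windows[i], spec, rng) for i in idx))
            x = np.stack(ws).astype(np.float32)
            y = np.stack(ls)
            opt.zero_grad()
            feats = encoder(ad.Tensor(x))
            loss = None
            for t, head in heads.items():
                term = ad.sigmoid_bce(head(feats), y[:, task_col[t]])
                loss = term if loss is None else loss + term
            loss.backward()
            opt.step()
            total += float(loss.data)
            nb += 1
        history.append(total / max(nb, 1))
    # recompute normalisation statistics under the final weights
    encoder.reset_norm_stats()
    with ad.no_grad():
        for _ in range(2):
            for start in range(0, n, batch_size):
                idx = np.arange(start, min(start + batch_size, n))
                ws = [ssl_transform(windows[i], spec, rng)[0] for i in idx]
                encoder(ad.Tensor(np.stack(ws).astype(np.float32)))
    encoder.eval()
    return SslPretrainResult(
        encoder_state=encoder.state_dict(),
        loss_history=history,
        heads_state=[h.state_dict() for h in heads.values()],
    )


def ssl_task_accuracy(
    result: SslPretrainResult,
    windows: np.ndarray,
    spec: SslTaskSpec | None = None,
    encoder_blocks: int = 4,
    channels: tuple | None = None,
    kernel: int = 7,
    seed: int = 1,
) -> dict:
    """Held-out detection accuracy of each enabled task."""
    spec = spec or SslTaskSpec()
    rng = np.random.default_rng(seed)
    build_rng = np.random.default_rng(0)
    encoder = ConvEncoder(channels or _default_channels(encoder_blocks), kernel, build_rng)
    heads = {t: Linear(encoder.feat_dim, 1, build_rng) for t in SSL_TASKS if t in spec.tasks}
    encoder.load_state_dict(result.encoder_state)
    for h, state in zip(heads.values(), result.heads_state):
        h.load_state_dict(state)
    encoder.eval()
    ws, ls = zip(*(ssl_transform(w, spec, rng) for w in np.asarray(windows, dtype=float)))
    x, y = np.stack(ws).astype(np.float32), np.stack(ls)
    task_col = {t: i for i, t in enumerate(SSL_TASKS)}
    with ad.no_grad():
        feats = encoder(ad.Tensor(x))
        acc = {}
        for t, head in heads.items():
            pred = (head(feats).data.ravel() > 0).astype(int)
            acc[t] = float((pred == y[:, task_col[t]]).mean())
    return acc
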