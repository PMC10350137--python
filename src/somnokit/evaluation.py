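"""Validation machinery: agreement metrics, CV harness, reliability.

Implements the statistics used to compare device-derived sleep staging
against a reference: confusion matrices, Cohen's kappa, macro-F1 and
balanced accuracy (both pooled epoch-to-epoch and as subject-wise
mean +/- sd), subject-wise k-fold cross-validation that never splits a
subject across folds, Bland-Altman limits of agreement for per-night sleep
parameters, ICC(2,1) absolute agreement, and the wear-time missingness
simulation that finds the minimum wear criterion keeping the weekly sleep
duration estimate reliable (ICC > 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import _PARAM_FIELDS, compute_params
from .types import MISSING
from .windows import longest_per_noon_interval, noon_interval_of


# ---------------------------------------------------------------------------
# confusion matrix and scalar metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    counts: np.ndarray          # (k, k), truth rows x prediction columns
    classes: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative k x k matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


def confusion(truth: np.ndarray, pred: np.ndarray, classes: tuple) -> ConfusionMatrix:
    """Count matrix of truth rows against prediction columns."""
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if len(truth) != len(pred):
        raise ValueError("truth and prediction lengths differ")
    idx = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(truth, pred):
        if t not in idx or p not in idx:
            raise ValueError(f"label outside classes: {t!r} / {p!r}")
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Unweighted Cohen's kappa: (p_o - p_e) / (1 - p_e)."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / n
    rows = cm.counts.sum(axis=1) / n
    cols = cm.counts.sum(axis=0) / n
    p_e = float(rows @ cols)
    if np.isclose(p_e, 1.0):
        return 1.0 if np.isclose(p_o, 1.0) else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _per_class(cm: ConfusionMatrix) -> pd.DataFrame:
    tp = np.diag(cm.counts).astype(float)
    support = cm.counts.sum(axis=1).astype(float)
    predicted = cm.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(support > 0, tp / np.maximum(support, 1), np.nan)
        precision = np.where(predicted > 0, tp / np.maximum(predicted, 1), np.nan)
    return pd.DataFrame(
        {"support": support, "predicted": predicted, "precision": precision, "recall": recall},
        index=list(cm.classes),
    )


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class F1 over classes present or predicted.

    A class absent from both truth and predictions is skipped; a class
    present (or predicted) with no true positives contributes F1 = 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tab = _per_class(cm)
    f1s = []
    for _, row in tab.iterrows():
        if row.support == 0 and row.predicted == 0:
            continue
        p = 0.0 if np.isnan(row.precision) else row.precision
        r = 0.0 if np.isnan(row.recall) else row.recall
        f1s.append(0.0 if p + r == 0 else 2 * p * r / (p + r))
    return float(np.mean(f1s))


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean per-class recall over classes present in the truth."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tab = _per_class(cm)
    recalls = tab.recall[tab.support > 0]
    return float(recalls.mean())


# ---------------------------------------------------------------------------
# Bland-Altman and ICC
# ---------------------------------------------------------------------------

def bland_altman(device: np.ndarray, reference: np.ndarray) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement of paired device - reference values.

    LoA = bias +/- 1.96 * sd(differences, n-1 denominator).
    """
    device = np.asarray(device, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if device.shape != reference.shape or device.ndim != 1:
        raise ValueError("device and reference must be equal-length vectors")
    if len(device) < 2:
        raise ValueError("need at least two pairs")
    d = device - reference
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def icc(degraded: np.ndarray, complete: np.ndarray) -> float:
    """ICC(2,1): two-way mixed-effects, absolute agreement, single measure.

    ``degraded`` and ``complete`` are paired measurements of the same
    quantity across subjects.  Identical vectors define ICC = 1; zero
    variance with unequal pairs is an error.
    """
    x = np.asarray(degraded, dtype=float)
    y = np.asarray(complete, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors of >= 2 subjects")
    if np.allclose(x, y):
        return 1.0
    data = np.column_stack([x, y])            # n subjects x k=2 raters
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if np.isclose(denom, 0.0):
        raise ValueError("zero variance: ICC undefined for unequal constant pairs")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# subject-wise cross-validation
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    scheme: str
    metrics: dict                      # name -> {subject_mean, subject_sd, pooled}
    confusion: ConfusionMatrix
    per_subject: pd.DataFrame          # subject, kappa, macro_f1, balanced_accuracy
    per_class: pd.DataFrame
    bland_altman: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "metrics": self.metrics,
            "confusion": self.confusion.to_frame().to_dict(),
            "bland_altman": self.bland_altman,
        }


def _subject_metrics(truth: np.ndarray, pred: np.ndarray, classes: tuple) -> dict:
    cm = confusion(truth, pred, classes)
    single_class = (cm.counts.sum(axis=1) > 0).sum() < 2
    return {
        "kappa": np.nan if single_class else cohen_kappa(cm),
        "macro_f1": macro_f1(cm),
        "balanced_accuracy": balanced_accuracy(cm),
    }


def agreement_report(
    truths: list, preds: list, subjects: list, classes: tuple, scheme: str = "three"
) -> AgreementReport:
    """Subject-wise and pooled agreement between label sequences.

    ``truths``/``preds`` are per-night label arrays (missing-marker epochs
    are dropped pairwise); ``subjects`` assigns each night to a subject.
    """
    by_subject: dict = {}
    all_t, all_p = [], []
    for t, p, s in zip(truths, preds, subjects):
        t = np.asarray(t, dtype=object)
        p = np.asarray(p, dtype=object)
        ok = (t != MISSING) & (p != MISSING)
        by_subject.setdefault(s, ([], []))
        by_subject[s][0].append(t[ok])
        by_subject[s][1].append(p[ok])
        all_t.append(t[ok])
        all_p.append(p[ok])
    rows = []
    for s, (ts, ps) in by_subject.items():
        m = _subject_metrics(np.concatenate(ts), np.concatenate(ps), classes)
        rows.append({"subject": s, **m})
    per_subject = pd.DataFrame(rows)
    pooled_cm = confusion(np.concatenate(all_t), np.concatenate(all_p), classes)
    metrics = {}
    pooled_vals = {
        "kappa": cohen_kappa(pooled_cm),
        "macro_f1": macro_f1(pooled_cm),
        "balanced_accuracy": balanced_accuracy(pooled_cm),
    }
    for name in ("kappa", "macro_f1", "balanced_accuracy"):
        vals = per_subject[name].dropna()
        metrics[name] = {
            "subject_mean": float(vals.mean()) if len(vals) else np.nan,
            "subject_sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            "pooled": pooled_vals[name],
        }
    return AgreementReport(scheme, metrics, pooled_cm, per_subject, _per_class(pooled_cm))


def subject_folds(subjects: list, k: int = 5, seed: int = 0) -> list:
    """Partition unique subjects into k shuffled folds."""
    uniq = sorted(set(subjects))
    if len(uniq) < k:
        raise ValueError(f"need at least {k} subjects for {k}-fold CV")
    rng = np.random.default_rng(seed)
    order = list(uniq)
    rng.shuffle(order)
    return [set(order[i::k]) for i in range(k)]


def subjectwise_cv(
    nights: list,
    labels: list,
    subjects: list,
    model_factory,
    k: int = 5,
    seed: int = 0,
    scheme: str = "three",
) -> AgreementReport:
    """Subject-wise k-fold cross-validation of a night-level classifier.

    ``model_factory()`` must return an unfitted classifier with
    ``fit(nights, labels)`` and ``predict(nights, scheme)``.  Folds
    partition subjects; every night of a subject is scored exactly once,
    by a model that never saw that subject.  Training labels are passed
    through unchanged (five-class); evaluation happens in ``scheme``.
    """
    from .types import collapse_labels

    folds = subject_folds(subjects, k=k, seed=seed)
    truths_out, preds_out, subjects_out = [], [], []
    subjects = list(subjects)
    for fold in folds:
        train_idx = [i for i, s in enumerate(subjects) if s not in fold]
        test_idx = [i for i, s in enumerate(subjects) if s in fold]
        model = model_factory()
        model.fit([nights[i] for i in train_idx], [labels[i] for i in train_idx])
        preds = model.predict([nights[i] for i in test_idx], scheme)
        for i, p in zip(test_idx, preds):
            truths_out.append(collapse_labels(np.asarray(labels[i], dtype=object), scheme))
            preds_out.append(p)
            subjects_out.append(subjects[i])
    from .types import stage_classes

    return agreement_report(truths_out, preds_out, subjects_out, stage_classes(scheme), scheme)


def stratified_report(per_subject: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-group mean +/- sd and n of subject-wise metrics.

    ``groups`` maps subject -> group label.  Groups of size one report a
    missing sd; empty groups are simply absent.
    """
    df = per_subject.copy()
    df["group"] = df["subject"].map(groups)
    out = []
    metric_cols = [c for c in df.columns if c not in ("subject", "group")]
    for g, sub in df.groupby("group", dropna=False):
        row = {"group": g, "n": len(sub)}
        for c in metric_cols:
            vals = sub[c].dropna()
            row[f"{c}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{c}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        out.append(row)
    return pd.DataFrame(out)


def sleep_parameter_agreement(
    windows: list, pred_labels: list, true_labels: list, epoch_starts: list
) -> dict:
    """Bland-Altman (bias, LoA) per sleep parameter across nights.

    Each element is one night: a time-in-bed window plus predicted and
    reference three-class label sequences on the same epoch grid.
    """
    device: dict = {f: [] for f in _PARAM_FIELDS}
    reference: dict = {f: [] for f in _PARAM_FIELDS}
    for w, pl, tl, es in zip(windows, pred_labels, true_labels, epoch_starts):
        p_dev = compute_params(w, pl, es)
        p_ref = compute_params(w, tl, es)
        for f in _PARAM_FIELDS:
            device[f].append(getattr(p_dev, f))
            reference[f].append(getattr(p_ref, f))
    out = {}
    for f in _PARAM_FIELDS:
        d = np.asarray(device[f], dtype=float)
        r = np.asarray(reference[f], dtype=float)
        ok = np.isfinite(d) & np.isfinite(r)
        if ok.sum() >= 2:
            out[f] = bland_altman(d[ok], r[ok])
    return out


# ---------------------------------------------------------------------------
# wear-time missingness simulation
# ---------------------------------------------------------------------------

@dataclass
class IccGrid:
    hours_grid: tuple
    days_grid: tuple
    values: np.ndarray              # (len(hours), len(days)) mean ICC
    minimal_criterion: tuple | None  # (hours, days) minimising hours*days with ICC > 0.75

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.hours_grid), columns=list(self.days_grid)
        )


def _daily_durations(result) -> dict:
    """Truth overnight sleep minutes per noon-to-noon day of one subject."""
    hyp3 = result.hypnogram.collapse("three")
    overnight = [w for w in result.truth_windows]
    chosen = longest_per_noon_interval(overnight)
    starts = hyp3.epoch_starts
    sleep = np.isin(hyp3.stages, ("NREM", "R"))
    out = {}
    for day, w in chosen.items():
        inside = (starts >= w.start) & (starts < w.end)
        out[day] = (0.5 * sleep[inside].sum(), w)
    return out


def wear_missingness_sim(
    subjects: list,
    hours_grid: tuple = (16, 18, 20, 22, 24),
    days_grid: tuple = (1, 3, 5, 7),
    reps: int = 5,
    seed: int = 0,
    threshold: float = 0.75,
) -> IccGrid:
    """Reliability of weekly sleep duration under random missing wear.

    ``subjects`` are complete 7-day free-living simulations (label truth).
    For each (h, d) cell and repetition: keep ``d`` random days per
    subject, censor each kept day to ``h`` hours of wear by deleting one
    contiguous block of 24 - h hours at a random offset, recompute the
    weekly mean overnight sleep duration, and take the ICC against the
    complete-data weekly means across subjects.  Cell values average over
    repetitions; the minimal criterion is the cell with ICC above the
    threshold minimising total required wear (h * d, ties to fewer days).
    """
    if max(hours_grid) > 24 or max(days_grid) > 7:
        raise ValueError("grid exceeds 24 h/day or 7 days")
    if min(hours_grid) <= 0 or min(days_grid) < 1:
        raise ValueError("grid values must be positive")
    rng = np.random.default_rng(seed)
    per_subject = [_daily_durations(s) for s in subjects]
    complete = np.array([np.mean([v[0] for v in d.values()]) for d in per_subject])
    # precompute epoch grids and sleep masks once per subject
    cache = []
    for subj in subjects:
        hyp3 = subj.hypnogram.collapse("three")
        cache.append((hyp3.epoch_starts, np.isin(hyp3.stages, ("NREM", "R"))))
    values = np.zeros((len(hours_grid), len(days_grid)))
    for ih, h in enumerate(hours_grid):
        for id_, d in enumerate(days_grid):
            iccs = []
            for _ in range(reps):
                degraded = []
                for (starts, sleep), days in zip(cache, per_subject):
                    keys = sorted(days.keys())
                    keep = rng.choice(len(keys), size=min(d, len(keys)), replace=False)
                    vals = []
                    for ki in keep:
                        dur, w = days[keys[ki]]
                        if h >= 24:
                            vals.append(dur)
                            continue
                        day_start = keys[ki].astype("datetime64[ns]") + np.timedelta64(12, "h")
                        gap_len = np.timedelta64(int(round((24 - h) * 3600)), "s")
                        off = rng.uniform(0, h * 3600.0)
                        g0 = day_start + np.timedelta64(int(off), "s")
                        g1 = g0 + gap_len
                        inside = (starts >= w.start) & (starts < w.end)
                        worn = ~((starts >= g0) & (starts < g1))
                        vals.append(0.5 * (sleep & inside & worn).sum())
                    degraded.append(np.mean(vals) if vals else np.nan)
                degraded = np.asarray(degraded)
                ok = np.isfinite(degraded)
                if ok.sum() >= 2:
                    iccs.append(icc(degraded[ok], complete[ok]))
            values[ih, id_] = float(np.mean(iccs)) if iccs else np.nan
    minimal = None
    candidates = [
        (h * d, d, h)
        for ih, h in enumerate(hours_grid)
        for id_, d in enumerate(days_grid)
        if values[ih, id_] > threshold
    ]
    if candidates:
        _, d, h = min(candidates)
        minimal = (h, d)
    return IccGrid(tuple(hours_grid), tuple(days_grid), values, minimal)
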