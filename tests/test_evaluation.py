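"""Agreement metrics, Bland-Altman, ICC and the CV / wear-sim harnesses."""

import numpy as np
import pandas as pd
import pytest

from somnokit import FreeLivingScenario, simulate_freeliving
from somnokit.evaluation import (
    ConfusionMatrix,
    agreement_report,
    balanced_accuracy,
    bland_altman,
    cohen_kappa,
    confusion,
    icc,
    macro_f1,
    stratified_report,
    subject_folds,
    subjectwise_cv,
    wear_missingness_sim,
)


class TestConfusion:
    def test_perfect_two_class(self):
        truth = np.array(["A"] * 60 + ["B"] * 40, dtype=object)
        cm = confusion(truth, truth, ("A", "B"))
        assert np.array_equal(cm.counts, [[60, 0], [0, 40]])

    def test_degenerate_prediction(self):
        truth = np.array(["A"] * 100, dtype=object)
        pred = np.array(["B"] * 100, dtype=object)
        cm = confusion(truth, pred, ("A", "B"))
        assert np.array_equal(cm.counts, [[0, 100], [0, 0]])

    def test_row_sums_are_class_counts(self):
        rng = np.random.default_rng(0)
        truth = rng.choice(["A", "B", "C"], size=50).astype(object)
        pred = rng.choice(["A", "B", "C"], size=50).astype(object)
        cm = confusion(truth, pred, ("A", "B", "C"))
        for i, c in enumerate(("A", "B", "C")):
            assert cm.counts[i].sum() == (truth == c).sum()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array(["A"]), np.array(["Z"]), ("A", "B"))


class TestScalarMetrics:
    def test_kappa_values(self):
        assert cohen_kappa(ConfusionMatrix([[50, 0], [0, 50]], ("A", "B"))) == 1.0
        assert cohen_kappa(ConfusionMatrix([[45, 5], [15, 35]], ("A", "B"))) == pytest.approx(0.6)
        assert cohen_kappa(ConfusionMatrix([[30, 30], [20, 20]], ("A", "B"))) == pytest.approx(0.0)

    def test_kappa_degenerate_marginals(self):
        assert cohen_kappa(ConfusionMatrix([[10, 0], [0, 0]], ("A", "B"))) == 1.0
        assert cohen_kappa(ConfusionMatrix([[0, 10], [0, 0]], ("A", "B"))) == 0.0

    def test_macro_f1_hand_value(self):
        cm = ConfusionMatrix([[45, 5], [15, 35]], ("A", "B"))
        f1_a = 2 * (45 / 60) * (45 / 50) / (45 / 60 + 45 / 50)
        f1_b = 2 * (35 / 40) * (35 / 50) / (35 / 40 + 35 / 50)
        assert macro_f1(cm) == pytest.approx(0.5 * (f1_a + f1_b))
        assert macro_f1(cm) == pytest.approx(0.798, abs=5e-4)

    def test_balanced_accuracy_mean_recall(self):
        cm = ConfusionMatrix([[40, 0], [20, 20]], ("A", "B"))
        assert balanced_accuracy(cm) == pytest.approx(0.75)

    def test_perfect_matrix(self):
        cm = ConfusionMatrix([[30, 0, 0], [0, 20, 0], [0, 0, 10]], ("A", "B", "C"))
        assert macro_f1(cm) == 1.0 and balanced_accuracy(cm) == 1.0

    def test_absent_unpredicted_class_skipped(self):
        cm = ConfusionMatrix([[30, 0, 0], [5, 25, 0], [0, 0, 0]], ("A", "B", "C"))
        f1_a = 2 * (30 / 35) * 1.0 / (30 / 35 + 1.0)
        f1_b = 2 * 1.0 * (25 / 30) / (1.0 + 25 / 30)
        assert macro_f1(cm) == pytest.approx(0.5 * (f1_a + f1_b))

    def test_agrees_with_sklearn(self):
        from sklearn import metrics as skm

        rng = np.random.default_rng(3)
        truth = rng.choice(["A", "B", "C"], size=500)
        pred = rng.choice(["A", "B", "C"], size=500)
        cm = confusion(truth.astype(object), pred.astype(object), ("A", "B", "C"))
        assert cohen_kappa(cm) == pytest.approx(skm.cohen_kappa_score(truth, pred))
        assert macro_f1(cm) == pytest.approx(skm.f1_score(truth, pred, average="macro"))
        assert balanced_accuracy(cm) == pytest.approx(skm.balanced_accuracy_score(truth, pred))


class TestBlandAltman:
    def test_identical_pairs(self):
        assert bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0, 0.0)

    def test_symmetric_differences(self):
        bias, lo, hi = bland_altman([0.0, 10.0, 20.0], [10.0, 10.0, 10.0])
        assert bias == pytest.approx(0.0)
        assert lo == pytest.approx(-19.6)
        assert hi == pytest.approx(19.6)

    def test_offset_differences(self):
        bias, lo, hi = bland_altman([40.0, 50.0, 60.0], [10.0, 10.0, 10.0])
        assert bias == pytest.approx(40.0)
        assert lo == pytest.approx(20.4)
        assert hi == pytest.approx(59.6)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestIcc:
    def test_identical_is_one(self):
        x = np.arange(10.0)
        assert icc(x, x) == 1.0

    def test_heavy_noise_attenuates(self):
        rng = np.random.default_rng(1)
        complete = rng.normal(400, 10, size=200)  # small between-subject spread
        degraded = complete + rng.normal(0, 100, size=200)
        assert icc(degraded, complete) < 0.3

    def test_tiny_noise_is_near_one(self):
        rng = np.random.default_rng(2)
        complete = rng.normal(400, 50, size=200)
        degraded = complete + rng.normal(0, 0.5, size=200)
        assert icc(degraded, complete) > 0.99

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        complete = rng.normal(400, 40, size=50)
        degraded = complete + rng.normal(0, 25, size=50)
        mine = icc(degraded, complete)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(50), 2),
                "rater": np.tile(["a", "b"], 50),
                "score": np.column_stack([degraded, complete]).ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        ref_val = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert mine == pytest.approx(ref_val, abs=1e-9)


class _OracleModel:
    """Echoes stored truth labels: a perfect classifier for harness tests."""

    def __init__(self, lookup):
        self.lookup = lookup

    def fit(self, nights, labels):
        return self

    def predict(self, nights, scheme="three"):
        from somnokit.types import collapse_labels

        return [collapse_labels(self.lookup[id(n)], scheme) for n in nights]


class TestSubjectwiseCv:
    def test_folds_partition_subjects(self):
        subjects = [f"s{i}" for i in range(10) for _ in range(2)]
        folds = subject_folds(subjects, k=5, seed=0)
        seen = [s for f in folds for s in f]
        assert sorted(seen) == sorted(set(subjects))
        assert subject_folds(subjects, k=5, seed=0) == folds

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            subject_folds(["a", "b"], k=5)

    def test_oracle_predictor_scores_perfectly(self):
        rng = np.random.default_rng(4)
        nights, labels, subjects = [], [], []
        for s in range(6):
            lab = np.array(rng.choice(["W", "N2", "R"], size=50), dtype=object)
            night = np.zeros((50, 1))
            nights.append(night)
            labels.append(lab)
            subjects.append(f"s{s}")
        lookup = {id(n): l for n, l in zip(nights, labels)}
        report = subjectwise_cv(
            nights, labels, subjects, lambda: _OracleModel(lookup), k=3, seed=0
        )
        assert report.metrics["kappa"]["subject_mean"] == pytest.approx(1.0)
        assert report.metrics["kappa"]["subject_sd"] == pytest.approx(0.0)
        assert report.metrics["kappa"]["pooled"] == pytest.approx(1.0)

    def test_single_class_subject_kappa_missing(self):
        truths = [np.array(["W"] * 20, dtype=object), np.array(["W", "R"] * 10, dtype=object)]
        preds = [t.copy() for t in truths]
        report = agreement_report(truths, preds, ["a", "b"], ("W", "NREM", "R"))
        per = report.per_subject.set_index("subject")
        assert np.isnan(per.loc["a", "kappa"])
        assert per.loc["b", "kappa"] == 1.0


class TestStratifiedReport:
    @staticmethod
    def _per_subject():
        return pd.DataFrame(
            {"subject": ["a", "b", "c"], "kappa": [0.5, 0.7, 0.9], "macro_f1": [0.6, 0.8, 1.0]}
        )

    def test_single_group_equals_overall(self):
        groups = pd.Series({"a": "g", "b": "g", "c": "g"})
        out = stratified_report(self._per_subject(), groups)
        assert len(out) == 1
        assert out.iloc[0]["kappa_mean"] == pytest.approx(0.7)

    def test_singleton_group_sd_missing(self):
        groups = pd.Series({"a": "g1", "b": "g1", "c": "g2"})
        out = stratified_report(self._per_subject(), groups).set_index("group")
        assert np.isnan(out.loc["g2", "kappa_sd"])
        assert out.loc["g1", "n"] == 2


@pytest.fixture(scope="module")
def subjects():
    return [
        simulate_freeliving(
            FreeLivingScenario(n_days=7, wear_gap_rate=0.0, nap_probability=0.0, seed=100 + i),
            include_signal=False,
        )
        for i in range(12)
    ]


class TestWearSim:
    def test_full_wear_cell_is_one(self, subjects):
        grid = wear_missingness_sim(subjects, hours_grid=(24,), days_grid=(7,), reps=1, seed=0)
        assert grid.values[0, 0] == 1.0
        assert grid.minimal_criterion == (24, 7)

    def test_grid_validation(self, subjects):
        with pytest.raises(ValueError):
            wear_missingness_sim(subjects, hours_grid=(25,), days_grid=(7,))
        with pytest.raises(ValueError):
            wear_missingness_sim(subjects, hours_grid=(24,), days_grid=(8,))

    def test_more_wear_hours_cannot_hurt_on_average(self, subjects):
        grid = wear_missingness_sim(
            subjects, hours_grid=(16, 20, 24), days_grid=(7,), reps=4, seed=1
        )
        vals = grid.values[:, 0]
        assert vals[0] <= vals[1] + 0.05 and vals[1] <= vals[2] + 0.05
        assert vals[2] == 1.0
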