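"""Sleep stager: SSL transforms, collapsing, prediction contracts, capacity."""

import numpy as np
import pytest

from somnokit import SleepNetClassifier
from somnokit.sleepnet import (
    SslTaskSpec,
    collapse,
    collapse_probs,
    paper_scale_config,
    pretrain_ssl,
    ssl_transform,
)
from somnokit.types import MISSING, SAMPLES_PER_EPOCH, EpochArray, collapse_labels

TINY = dict(
    encoder_blocks=2, channels=(8, 12, 16), kernel=9, lstm_hidden=16,
    fc_dims=(32, 5), dropout=0.0, lr=3e-3, batch_nights=1,
)


class TestSslTransform:
    def test_no_task_applied_is_identity(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(SAMPLES_PER_EPOCH, 3))
        spec = SslTaskSpec(apply_prob=0.5)
        for seed in range(200):
            out, labels = ssl_transform(w, spec, seed)
            if labels.sum() == 0:
                assert np.array_equal(out, w)
                return
        pytest.fail("no all-zero draw in 200 seeds")

    def test_reversal_reverses_ramp(self):
        w = np.zeros((SAMPLES_PER_EPOCH, 3))
        w[:, 0] = np.arange(SAMPLES_PER_EPOCH)
        spec = SslTaskSpec(tasks=("reversal",))
        for seed in range(50):
            out, labels = ssl_transform(w, spec, seed)
            if labels[0]:
                assert (np.diff(out[:, 0]) < 0).all()
                return
        pytest.fail("reversal never applied in 50 seeds")

    def test_permutation_preserves_segment_multiset(self):
        rng = np.random.default_rng(1)
        spec = SslTaskSpec(tasks=("permutation",), permutation_segments=4)
        hits = 0
        for _ in range(1000):
            w = rng.normal(size=(SAMPLES_PER_EPOCH, 3))
            out, labels = ssl_transform(w, spec, rng)
            if not labels[1]:
                assert np.array_equal(out, w)
                continue
            hits += 1
            segs_in = sorted(map(lambda s: s.tobytes(), np.split(w, 4)))
            segs_out = sorted(map(lambda s: s.tobytes(), np.split(out, 4)))
            assert segs_in == segs_out
            assert not np.array_equal(out, w)  # non-identity shuffle guaranteed
        assert hits > 300

    def test_reversal_is_an_involution(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            w = rng.normal(size=(SAMPLES_PER_EPOCH, 3))
            assert np.array_equal(w[::-1][::-1], w)
            out, labels = ssl_transform(w, SslTaskSpec(tasks=("reversal",)), rng)
            if labels[0]:
                assert np.array_equal(out[::-1], w)

    def test_time_warp_keeps_shape(self):
        rng = np.random.default_rng(3)
        spec = SslTaskSpec(tasks=("time_warp",))
        for seed in range(20):
            out, _ = ssl_transform(rng.normal(size=(SAMPLES_PER_EPOCH, 3)), spec, seed)
            assert out.shape == (SAMPLES_PER_EPOCH, 3)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SslTaskSpec(tasks=()).validate()
        with pytest.raises(ValueError):
            SslTaskSpec(apply_prob=1.0).validate()
        with pytest.raises(ValueError):
            SslTaskSpec(permutation_segments=7).validate()


class TestCollapse:
    def test_label_collapse_rules(self):
        labels = np.array(["N3", "W", "R", "N1"], dtype=object)
        assert list(collapse(labels, "three")) == ["NREM", "W", "R", "NREM"]
        assert list(collapse(labels, "two")) == ["S", "W", "S", "S"]

    def test_probability_collapse_sums(self):
        p = np.array([[0.1, 0.2, 0.3, 0.1, 0.3]])
        np.testing.assert_allclose(collapse(p, "three"), [[0.1, 0.6, 0.3]])
        np.testing.assert_allclose(collapse(p, "two"), [[0.1, 0.9]])

    def test_probability_conservation_property(self):
        rng = np.random.default_rng(4)
        p = rng.dirichlet(np.ones(5), size=1000)
        for scheme in ("three", "two"):
            c = collapse_probs(p, scheme)
            np.testing.assert_allclose(c.sum(axis=1), 1.0, atol=1e-6)
            assert (c >= 0).all()

    def test_unknown_scheme_errors(self):
        with pytest.raises(ValueError):
            collapse_probs(np.full((1, 5), 0.2), "four")

    def test_all_wake_collapses_to_wake(self):
        labels = np.array(["W"] * 5, dtype=object)
        assert (collapse(labels, "three") == "W").all()
        assert (collapse(labels, "two") == "W").all()


class TestSleepNetClassifier:
    def test_prediction_contract(self, make_night):
        sig, lab = make_night(0, 60)
        clf = SleepNetClassifier(epochs=2, seed=0, **TINY)
        clf.fit([sig], [lab])
        pred = clf.predict_proba([sig])[0]
        np.testing.assert_allclose(pred.probs.sum(axis=1), 1.0, atol=1e-6)
        again = clf.predict_proba([sig])[0]
        assert np.array_equal(pred.probs, again.probs)

    def test_nonwear_epochs_missing(self, make_night):
        sig, lab = make_night(0, 60)
        clf = SleepNetClassifier(epochs=2, seed=0, **TINY)
        clf.fit([sig], [lab])
        starts = np.datetime64("2024-01-01T23:00:00", "ns") + np.arange(60) * np.timedelta64(30, "s")
        wear = np.ones(60, dtype=bool)
        wear[5:10] = False
        ea = EpochArray(starts, sig, wear)
        pred = clf.predict_proba([ea])[0]
        assert np.isnan(pred.probs[5:10]).all()
        labels = pred.labels("three")
        assert (labels[5:10] == MISSING).all()
        assert set(labels[10:]) <= {"W", "NREM", "R"}

    def test_label_validation(self, make_night):
        sig, lab = make_night(0, 60)
        bad = lab.copy()
        bad[0] = "REM"
        clf = SleepNetClassifier(epochs=1, seed=0, **TINY)
        with pytest.raises(ValueError):
            clf.fit([sig], [bad])
        with pytest.raises(ValueError):
            clf.fit([sig], [np.array(["N2"] * 60, dtype=object)])

    def test_single_night_overfit_capacity(self, make_night):
        """A scaled-down network can memorise one night almost perfectly."""
        sig, lab = make_night(1, 120)
        clf = SleepNetClassifier(epochs=50, seed=0, **TINY)
        clf.fit([sig], [lab])
        pred = clf.predict([sig], "five")[0]
        assert (pred == lab).mean() >= 0.95
        assert clf.history_[-1] < clf.history_[0]

    def test_paper_scale_preset_shape(self):
        cfg = paper_scale_config()
        assert cfg["encoder_blocks"] == 8
        assert len(cfg["channels"]) == 9
        clf = SleepNetClassifier(**cfg)
        model = clf._build(np.random.default_rng(0))
        # 17 convolutional layers: stem + 2 per residual block
        n_convs = 1 + 2 * cfg["encoder_blocks"]
        assert n_convs == 17

    def test_get_set_params_roundtrip(self):
        clf = SleepNetClassifier(lstm_hidden=7)
        params = clf.get_params()
        assert params["lstm_hidden"] == 7
        clf.set_params(lstm_hidden=9)
        assert clf.lstm_hidden == 9


class TestPretrainSsl:
    def test_loss_descends_and_errors(self, wake_windows):
        windows = wake_windows(0, 120)
        res = pretrain_ssl(
            windows, SslTaskSpec(seed=0), encoder_blocks=2, channels=(8, 12, 16),
            kernel=9, epochs=3, seed=0,
        )
        assert res.loss_history[-1] < res.loss_history[0]
        with pytest.raises(ValueError):
            pretrain_ssl(windows, SslTaskSpec(tasks=()))
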