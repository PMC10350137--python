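"""Generator behaviour: chain statistics, movement model, free living."""

import hashlib

import numpy as np
import pytest

from somnokit import (
    FreeLivingScenario,
    MovementProfile,
    StageDynamics,
    simulate_accel,
    simulate_freeliving,
    simulate_hypnogram,
)
from somnokit.preprocess import enmo_mg
from somnokit.synthetic import _BURST_TAU_S
from somnokit.types import STAGES_5, Hypnogram


def _pure_stage_hypnogram(stage: str, n: int) -> Hypnogram:
    starts = np.datetime64("2024-01-01T23:00:00") + np.arange(n) * np.timedelta64(30, "s")
    return Hypnogram(starts, np.array([stage] * n, dtype=object), "five")


class TestSimulateHypnogram:
    def test_absorbing_chain_stays_put(self):
        dyn = StageDynamics(
            transition_matrix=np.eye(5),
            initial_distribution=np.array([0, 0, 1.0, 0, 0]),
        )
        hyp = simulate_hypnogram(dyn, 100, seed=0)
        assert len(hyp) == 100
        assert (hyp.stages == "N2").all()

    def test_uniform_chain_reaches_uniform_marginals(self):
        dyn = StageDynamics(
            transition_matrix=np.full((5, 5), 0.2),
            initial_distribution=np.full(5, 0.2),
        )
        hyp = simulate_hypnogram(dyn, 50_000, seed=1)
        for s in STAGES_5:
            freq = (hyp.stages == s).mean()
            assert 0.19 <= freq <= 0.21

    def test_default_night_regression(self):
        hyp = simulate_hypnogram(StageDynamics.default(), 960, seed=7)
        for s in ("W", "N2", "R"):
            assert s in hyp.stages
        digest = hashlib.md5(",".join(hyp.stages).encode()).hexdigest()
        assert digest == "143cec3718d9e6bc3da2ac0209a8e6c6"

    def test_seed_determinism(self):
        dyn = StageDynamics.default()
        a = simulate_hypnogram(dyn, 500, seed=3)
        b = simulate_hypnogram(dyn, 500, seed=3)
        c = simulate_hypnogram(dyn, 500, seed=4)
        assert (a.stages == b.stages).all()
        assert (a.stages != c.stages).any()

    def test_invalid_transition_matrix_rejected(self):
        bad = np.full((5, 5), 0.3)
        with pytest.raises(ValueError):
            StageDynamics(transition_matrix=bad)
        with pytest.raises(ValueError):
            simulate_hypnogram(StageDynamics.default(), 0, seed=0)


class TestSimulateAccel:
    def test_no_movement_gives_pure_gravity(self):
        profile = {s: MovementProfile(0.0, 0.0, 0.0, 0.0) for s in STAGES_5}
        dyn = StageDynamics(movement_profile=profile)
        rec = simulate_accel(_pure_stage_hypnogram("N3", 20), dyn, 30, seed=0)
        mag = np.linalg.norm(rec.xyz, axis=1)
        assert np.abs(mag - 1.0).max() < 1e-6

    def test_wake_much_louder_than_deep_sleep(self):
        dyn = StageDynamics.default()
        w = simulate_accel(_pure_stage_hypnogram("W", 300), dyn, 30, seed=3)
        n3 = simulate_accel(_pure_stage_hypnogram("N3", 300), dyn, 30, seed=3)
        assert enmo_mg(w.xyz).mean() > 3 * enmo_mg(n3.xyz).mean()

    def test_stage_intensity_ordering_and_profile_monotonicity(self):
        """Mean ENMO orders W > N1 > (N2, R) > N3 and tracks the profile.

        The per-stage mean ENMO must have rank correlation 1 with the
        profile's predicted movement intensity (burst momentum plus the
        noise floor's contribution).
        """
        from scipy.stats import spearmanr

        dyn = StageDynamics.default()
        enmo = {}
        for s in STAGES_5:
            rec = simulate_accel(_pure_stage_hypnogram(s, 700), dyn, 30, seed=11)
            enmo[s] = enmo_mg(rec.xyz).mean()
        assert enmo["W"] > enmo["N1"]
        assert enmo["N1"] > max(enmo["N2"], enmo["R"])
        assert min(enmo["N2"], enmo["R"]) > enmo["N3"]
        predicted = []
        for s in STAGES_5:
            p = dyn.movement_profile[s]
            burst = p.burst_rate / 60.0 * p.burst_amplitude * _BURST_TAU_S
            predicted.append(burst + 0.4 * p.baseline_noise_sd)
        rho = spearmanr(predicted, [enmo[s] for s in STAGES_5]).statistic
        assert rho == pytest.approx(1.0)

    def test_duration_rate_and_determinism(self):
        dyn = StageDynamics.default()
        hyp = _pure_stage_hypnogram("N2", 10)
        rec = simulate_accel(hyp, dyn, 50, seed=5)
        assert len(rec) == 10 * 30 * 50
        assert rec.sample_hz == 50
        rec2 = simulate_accel(hyp, dyn, 50, seed=5)
        assert np.array_equal(rec.xyz, rec2.xyz)
        with pytest.raises(ValueError):
            simulate_accel(Hypnogram(np.empty(0, "datetime64[ns]"), np.empty(0, object), "five"), dyn)

    def test_zero_contrast_profiles_identical(self):
        dyn = StageDynamics.default(contrast=0.0)
        profiles = list(dyn.movement_profile.values())
        for p in profiles[1:]:
            assert p == profiles[0]


class TestFreeLiving:
    def test_deterministic_single_night(self):
        sc = FreeLivingScenario(
            n_days=1, bed_time_sd=0.0, rise_time_sd=0.0,
            nap_probability=0.0, wear_gap_rate=0.0, seed=0,
            weekday_weekend_shift=0.0,
        )
        res = simulate_freeliving(sc, include_signal=False)
        assert len(res.truth_windows) == 1
        w = res.truth_windows[0]
        assert w.start == np.datetime64("2024-01-01T23:00:00", "ns")
        assert w.end == np.datetime64("2024-01-02T07:00:00", "ns")
        assert res.missing_fraction == 0.0

    def test_week_has_one_overnight_window_per_interval(self):
        from somnokit.windows import noon_interval_of

        sc = FreeLivingScenario(n_days=7, nap_probability=0.0, wear_gap_rate=0.0, seed=11)
        res = simulate_freeliving(sc, include_signal=False)
        assert len(res.truth_windows) == 7
        intervals = {noon_interval_of(w.midpoint) for w in res.truth_windows}
        assert len(intervals) == 7
        assert len(res.diary) == 7

    def test_wear_gaps_remove_samples(self):
        sc = FreeLivingScenario(n_days=3, wear_gap_rate=2.0, seed=5, sample_hz=30)
        res = simulate_freeliving(sc, include_signal=True)
        assert 0.0 < res.missing_fraction < 0.5
        full = 3 * 24 * 3600 * 30
        assert len(res.recording) < full

    def test_no_gaps_means_no_missing_samples(self):
        sc = FreeLivingScenario(n_days=1, wear_gap_rate=0.0, seed=2, sample_hz=30)
        res = simulate_freeliving(sc, include_signal=True)
        assert res.missing_fraction == 0.0
        assert len(res.recording) == 24 * 3600 * 30

    def test_seed_determinism_bitwise(self):
        sc = FreeLivingScenario(n_days=2, seed=9)
        a = simulate_freeliving(sc, include_signal=True)
        b = simulate_freeliving(sc, include_signal=True)
        assert np.array_equal(a.recording.xyz, b.recording.xyz)
        assert (a.hypnogram.stages == b.hypnogram.stages).all()
        assert a.diary.equals(b.diary)

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            FreeLivingScenario(n_days=0).validate()
        with pytest.raises(ValueError):
            FreeLivingScenario(sample_hz=25).validate()
        with pytest.raises(ValueError):
            FreeLivingScenario(nap_probability=1.5).validate()

    def test_truth_windows_consistent_with_hypnogram(self):
        sc = FreeLivingScenario(n_days=2, nap_probability=0.0, wear_gap_rate=0.0, seed=4)
        res = simulate_freeliving(sc, include_signal=False)
        starts = res.hypnogram.epoch_starts
        in_bed = np.zeros(len(starts), dtype=bool)
        for w in res.truth_windows:
            in_bed |= (starts >= w.start) & (starts < w.end)
        # all non-wake epochs lie inside a truth window
        assert (res.hypnogram.stages[~in_bed] == "W").all()
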