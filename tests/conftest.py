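"""Shared fixtures: synthetic nights and recordings built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from somnokit import StageDynamics, simulate_accel, simulate_hypnogram
from somnokit.types import SAMPLES_PER_EPOCH, Hypnogram


@pytest.fixture(scope="session")
def dynamics() -> StageDynamics:
    return StageDynamics.default()


def _night(dynamics: StageDynamics, n_epochs: int, seed: int):
    """One synthetic night: (signals (m, 900, 3), five-class labels)."""
    hyp = simulate_hypnogram(dynamics, n_epochs, seed=seed)
    rec = simulate_accel(hyp, dynamics, sample_hz=30, seed=seed + 1000)
    return rec.xyz.reshape(n_epochs, SAMPLES_PER_EPOCH, 3), hyp.stages


def _dynamics_fingerprint(dyn: StageDynamics | None):
    if dyn is None:
        return None
    profile = tuple(
        (s, p.burst_rate, p.burst_amplitude, p.baseline_noise_sd, p.orientation_drift_sd)
        for s, p in sorted(dyn.movement_profile.items())
    )
    return (dyn.transition_matrix.tobytes(), dyn.initial_distribution.tobytes(), profile)


@pytest.fixture(scope="session")
def make_night(dynamics):
    cache: dict = {}

    def factory(seed: int, n_epochs: int = 240, dyn: StageDynamics | None = None):
        key = (seed, n_epochs, _dynamics_fingerprint(dyn))
        if key not in cache:
            cache[key] = _night(dyn or dynamics, n_epochs, seed)
        return cache[key]

    return factory


@pytest.fixture(scope="session")
def wake_windows(dynamics):
    """Movement-rich windows (daytime wake), for self-supervision tests."""
    cache: dict = {}

    def factory(seed: int, n_epochs: int = 240) -> np.ndarray:
        if (seed, n_epochs) not in cache:
            starts = np.datetime64("2024-01-01T12:00:00") + np.arange(n_epochs) * np.timedelta64(30, "s")
            hyp = Hypnogram(starts, np.array(["W"] * n_epochs, dtype=object), "five")
            rec = simulate_accel(hyp, dynamics, sample_hz=30, seed=seed + 1000)
            cache[(seed, n_epochs)] = rec.xyz.reshape(n_epochs, SAMPLES_PER_EPOCH, 3)
        return cache[(seed, n_epochs)]

    return factory


@pytest.fixture(scope="session")
def twenty_nights(make_night):
    """The default-contrast validation set: 20 nights of 240 epochs."""
    return [make_night(seed) for seed in range(20)]
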