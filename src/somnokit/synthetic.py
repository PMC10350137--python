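"""Synthetic accelerometry with known hypnograms.

The generator produces the two things a sleep-staging pipeline needs for
end-to-end testing without any real recordings:

* a five-stage (W, N1, N2, N3, R) hypnogram drawn from a first-order Markov
  chain at 30-s epoch resolution, with bout structure set by the chain's
  self-transition probabilities, and
* a tri-axial wrist acceleration trace whose movement statistics depend on
  the concurrent stage: sparse Poisson bursts (exponentially damped impulses
  in a random direction) on top of Gaussian sensor noise and a slow
  orientation random walk of the gravity vector.

Stage-dependent movement is the only signal the simulator encodes, which is
exactly the information a wrist-worn device has.  A single ``contrast``
knob interpolates every stage's movement profile toward the pooled mean, so
class separability can be dialled from "easy" (default) to "impossible"
(``contrast=0``) for sanity-checking classifiers against chance.

Free-living simulation adds multi-day structure: one overnight time-in-bed
interval per night (bed/rise times jittered around scenario means, shifted
on weekend nights), optional afternoon naps, and wear gaps inserted as
missing samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    EPOCH_S,
    STAGES_5,
    DeviceMeta,
    Hypnogram,
    RawRecording,
    SleepWindow,
)

_BURST_TAU_S = 0.25  # damping time constant of a movement impulse


@dataclass(frozen=True)
class MovementProfile:
    """Per-stage movement statistics of the wrist."""

    burst_rate: float            # bursts / minute, >= 0
    burst_amplitude: float       # g, mean impulse amplitude
    baseline_noise_sd: float     # g, Gaussian sensor + micro-movement noise
    orientation_drift_sd: float  # rad / epoch, random-walk rotation of gravity


# Defaults encode the qualitative ordering wake >> N1 > (N2 ~ REM) > N3 in
# movement intensity, with REM distinguished from N2 by many small twitches
# (muscle atonia with phasic activity) instead of few larger repositionings.
_DEFAULT_PROFILES = {
    "W": MovementProfile(12.0, 0.60, 0.030, 0.050),
    "N1": MovementProfile(4.0, 0.25, 0.022, 0.020),
    "N2": MovementProfile(1.2, 0.15, 0.017, 0.010),
    "N3": MovementProfile(0.3, 0.10, 0.014, 0.005),
    "R": MovementProfile(5.0, 0.04, 0.016, 0.005),
}

# Row-stochastic transition matrix over (W, N1, N2, N3, R) per 30-s epoch.
# Self-transition probabilities encode mean bout lengths of roughly
# W 2 min, N1 1 min, N2 10 min, N3 10 min, REM 10 min.
_DEFAULT_TRANSITIONS = np.array(
    [
        # W      N1     N2     N3     R
        [0.750, 0.200, 0.040, 0.000, 0.010],
        [0.080, 0.500, 0.400, 0.000, 0.020],
        [0.005, 0.005, 0.950, 0.025, 0.015],
        [0.010, 0.000, 0.040, 0.950, 0.000],
        [0.015, 0.005, 0.030, 0.000, 0.950],
    ]
)

_DEFAULT_INITIAL = np.array([0.9, 0.1, 0.0, 0.0, 0.0])


@dataclass
class StageDynamics:
    """Markov-chain stage dynamics plus per-stage movement profiles."""

    transition_matrix: np.ndarray = field(default_factory=lambda: _DEFAULT_TRANSITIONS.copy())
    initial_distribution: np.ndarray = field(default_factory=lambda: _DEFAULT_INITIAL.copy())
    movement_profile: dict = field(default_factory=lambda: dict(_DEFAULT_PROFILES))

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        self.validate()

    def validate(self) -> None:
        T, p0 = self.transition_matrix, self.initial_distribution
        if T.shape != (5, 5):
            raise ValueError("transition matrix must be 5x5 over (W, N1, N2, N3, R)")
        if (T < 0).any() or not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        if p0.shape != (5,) or (p0 < 0).any() or not np.isclose(p0.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must be a probability 5-vector")
        missing = set(STAGES_5) - set(self.movement_profile)
        if missing:
            raise ValueError(f"movement profile missing stages: {sorted(missing)}")
        for s, p in self.movement_profile.items():
            if p.burst_rate < 0 or p.burst_amplitude < 0 or p.baseline_noise_sd < 0:
                raise ValueError(f"negative movement parameter for stage {s}")

    @classmethod
    def default(cls, contrast: float = 1.0) -> "StageDynamics":
        """Default adult-night dynamics with a class-separability knob.

        ``contrast`` linearly interpolates every stage's movement profile
        between the pooled across-stage mean (0: stages are statistically
        identical, no classifier can beat chance) and the full default
        profile (1).  Values above 1 extrapolate to easier problems.
        """
        fields_ = ("burst_rate", "burst_amplitude", "baseline_noise_sd", "orientation_drift_sd")
        mean = {
            f: float(np.mean([getattr(p, f) for p in _DEFAULT_PROFILES.values()]))
            for f in fields_
        }
        profiles = {
            s: MovementProfile(
                **{
                    f: max(0.0, mean[f] + contrast * (getattr(p, f) - mean[f]))
                    for f in fields_
                }
            )
            for s, p in _DEFAULT_PROFILES.items()
        }
        return cls(movement_profile=profiles)


def simulate_hypnogram(
    dynamics: StageDynamics,
    n_epochs: int,
    seed: int,
    start_time=np.datetime64("2024-01-01T23:00:00"),
) -> Hypnogram:
    """Draw a five-class hypnogram of ``n_epochs`` 30-s epochs."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    dynamics.validate()
    rng = np.random.default_rng(seed)
    T = dynamics.transition_matrix
    cum = T.cumsum(axis=1)
    states = np.empty(n_epochs, dtype=np.int64)
    states[0] = rng.choice(5, p=dynamics.initial_distribution)
    u = rng.random(n_epochs - 1)
    for t in range(1, n_epochs):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")
    starts = np.datetime64(start_time, "ns") + np.arange(n_epochs) * np.timedelta64(EPOCH_S, "s")
    labels = np.array(STAGES_5, dtype=object)[states]
    return Hypnogram(starts, labels, "five")


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    ux, uy, uz = axis
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _stage_epoch_signal(
    n: int, hz: float, profile: MovementProfile, g_dir: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One epoch of acceleration: gravity + bursts + noise, shape (n, 3)."""
    sig = np.tile(g_dir, (n, 1))
    n_bursts = rng.poisson(profile.burst_rate * EPOCH_S / 60.0)
    for _ in range(n_bursts):
        s0 = rng.integers(0, n)
        amp = profile.burst_amplitude * rng.exponential(1.0)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        t = np.arange(n - s0) / hz
        sig[s0:] += amp * np.exp(-t / _BURST_TAU_S)[:, None] * direction
    if profile.baseline_noise_sd > 0:
        sig += rng.normal(0.0, profile.baseline_noise_sd, size=(n, 3))
    return sig


def simulate_accel(
    hypnogram: Hypnogram,
    dynamics: StageDynamics,
    sample_hz: float = 30,
    seed: int = 0,
) -> RawRecording:
    """Render a hypnogram into a tri-axial acceleration trace.

    Gravity contributes a slowly reorienting unit vector; each epoch adds
    stage-dependent Poisson movement bursts and Gaussian noise.
    """
    if len(hypnogram) == 0:
        raise ValueError("hypnogram is empty")
    if hypnogram.scheme != "five":
        raise ValueError("simulate_accel requires a five-class hypnogram")
    dynamics.validate()
    rng = np.random.default_rng(seed)
    n_ep = len(hypnogram)
    n_per = int(round(EPOCH_S * sample_hz))
    g_dir = np.array([0.15, -0.1, 1.0])
    g_dir /= np.linalg.norm(g_dir)
    out = np.empty((n_ep * n_per, 3))
    for i, stage in enumerate(hypnogram.stages):
        prof = dynamics.movement_profile[stage]
        if prof.orientation_drift_sd > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            g_dir = _rotation_matrix(axis, rng.normal(0.0, prof.orientation_drift_sd)) @ g_dir
        out[i * n_per : (i + 1) * n_per] = _stage_epoch_signal(n_per, sample_hz, prof, g_dir, rng)
    step = np.timedelta64(int(round(1e9 / sample_hz)), "ns")
    times = np.datetime64(hypnogram.epoch_starts[0], "ns") + np.arange(len(out)) * step
    return RawRecording(times, out, sample_hz)


@dataclass
class FreeLivingScenario:
    """Multi-day free-living schedule parameters."""

    n_days: int = 7
    bed_time_mean: str = "23:00"      # clock time
    bed_time_sd: float = 30.0         # minutes
    rise_time_mean: str = "07:00"
    rise_time_sd: float = 30.0
    nap_probability: float = 0.15     # per day
    wear_gap_rate: float = 0.5        # gaps / day
    sample_hz: float = 30
    seed: int = 0
    weekday_weekend_shift: float = 30.0  # minutes later on weekend nights

    def validate(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.sample_hz not in (30, 50, 100):
            raise ValueError("sample_hz must be one of 30, 50, 100")
        if not 0.0 <= self.nap_probability <= 1.0:
            raise ValueError("nap_probability must be in [0, 1]")
        if self.wear_gap_rate < 0:
            raise ValueError("wear_gap_rate must be >= 0")


@dataclass
class FreeLivingResult:
    recording: RawRecording | None
    hypnogram: Hypnogram            # five-class truth, every epoch of the span
    truth_windows: list             # list[SleepWindow], source="truth"
    diary: pd.DataFrame             # night, bed, rise (jittered diary entries)
    missing_fraction: float         # fraction of the sample grid lost to gaps


def _clock_minutes(clock: str) -> float:
    h, m = clock.split(":")
    return 60.0 * int(h) + float(m)


def subject_scenarios(
    n_subjects: int,
    seed: int,
    n_days: int = 7,
    wear_gap_rate: float = 0.0,
    nap_probability: float = 0.0,
) -> list[FreeLivingScenario]:
    """Per-subject scenarios with heterogeneous habitual sleep timing.

    Each subject draws a habitual bed time (N(23:00, 35 min)) and rise
    time (N(07:00, 45 min)) once; nights then jitter around those habits.
    The resulting between-subject spread of overnight sleep duration is
    about an hour, matching the population variability wrist-worn cohort
    studies report. That spread is what reliability (ICC) analyses
    measure against — a cohort of identical sleepers has no
    between-subject variance for missing data to attenuate.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_subjects):
        bed = 23 * 60 + int(np.clip(rng.normal(0, 35), -110, 55))
        rise = 7 * 60 + int(np.clip(rng.normal(0, 45), -120, 120))
        out.append(
            FreeLivingScenario(
                n_days=n_days,
                bed_time_mean=f"{bed // 60:02d}:{bed % 60:02d}",
                rise_time_mean=f"{rise // 60:02d}:{rise % 60:02d}",
                nap_probability=nap_probability,
                wear_gap_rate=wear_gap_rate,
                seed=int(rng.integers(2**31)),
            )
        )
    return out


def simulate_freeliving(
    scenario: FreeLivingScenario,
    dynamics: StageDynamics | None = None,
    include_signal: bool = True,
) -> FreeLivingResult:
    """Simulate ``n_days`` noon-to-noon days of free-living wear.

    The span runs from noon of day 0 (2024-01-01, a Monday) to noon of day
    ``n_days``; each noon-to-noon interval contains one overnight time-in-bed
    window and, with ``nap_probability``, one afternoon nap.  Out-of-bed
    epochs are wake; in-bed epochs follow the stage chain.  Wear gaps are
    removed from the returned trace (the truth hypnogram keeps its labels).
    Diary bed/rise entries are jittered N(0, 10 min) around truth.
    """
    scenario.validate()
    dynamics = dynamics or StageDynamics.default()
    rng = np.random.default_rng(scenario.seed)

    day0 = np.datetime64("2024-01-01T12:00:00", "ns")  # Monday noon
    minute = np.timedelta64(60_000_000_000, "ns")
    n_epochs = scenario.n_days * 24 * 120
    starts = day0 + np.arange(n_epochs) * np.timedelta64(EPOCH_S, "s")
    stages = np.full(n_epochs, "W", dtype=object)

    bed_m = _clock_minutes(scenario.bed_time_mean)
    rise_m = _clock_minutes(scenario.rise_time_mean)
    windows: list[SleepWindow] = []
    diary_rows = []
    cum = dynamics.transition_matrix.cumsum(axis=1)

    def _fill_chain(i0: int, i1: int) -> None:
        state = rng.choice(5, p=dynamics.initial_distribution)
        for t in range(i0, min(i1, n_epochs)):
            stages[t] = STAGES_5[state]
            state = int(np.searchsorted(cum[state], rng.random(), side="right"))

    for d in range(scenario.n_days):
        night_start_day = day0 + d * np.timedelta64(24, "h")  # noon of day d
        weekday = (np.datetime64("2024-01-01") + d * np.timedelta64(1, "D")).astype("datetime64[D]").astype(object).weekday()
        shift = scenario.weekday_weekend_shift if weekday >= 4 else 0.0  # Fri/Sat/Sun nights
        bed = night_start_day + (bed_m - 720 + shift + rng.normal(0, scenario.bed_time_sd)) * minute
        rise = night_start_day + (rise_m + 720 + shift + rng.normal(0, scenario.rise_time_sd)) * minute
        # snap to the epoch grid
        i_bed = int(np.round((bed - day0) / np.timedelta64(EPOCH_S, "s")))
        i_rise = int(np.round((rise - day0) / np.timedelta64(EPOCH_S, "s")))
        i_bed, i_rise = max(i_bed, 0), min(i_rise, n_epochs)
        _fill_chain(i_bed, i_rise)
        w_start = day0 + i_bed * np.timedelta64(EPOCH_S, "s")
        w_end = day0 + i_rise * np.timedelta64(EPOCH_S, "s")
        windows.append(SleepWindow(w_start, w_end, source="truth"))
        diary_rows.append(
            {
                "night": d,
                "bed": pd.Timestamp(w_start + rng.normal(0, 10) * minute),
                "rise": pd.Timestamp(w_end + rng.normal(0, 10) * minute),
            }
        )
        if rng.random() < scenario.nap_probability:
            nap_start = night_start_day + (120 + rng.normal(0, 30)) * minute  # ~14:00
            nap_len = max(30.0, rng.normal(45, 10))
            j0 = int(np.round((nap_start - day0) / np.timedelta64(EPOCH_S, "s")))
            j1 = j0 + int(round(nap_len * 2))
            j0, j1 = max(j0, 0), min(j1, n_epochs)
            if j1 > j0:
                _fill_chain(j0, j1)
                windows.append(
                    SleepWindow(
                        day0 + j0 * np.timedelta64(EPOCH_S, "s"),
                        day0 + j1 * np.timedelta64(EPOCH_S, "s"),
                        source="truth",
                    )
                )

    hyp = Hypnogram(starts, stages, "five")
    diary = pd.DataFrame(diary_rows)

    # wear gaps: contiguous stretches of missing samples
    n_gaps = rng.poisson(scenario.wear_gap_rate * scenario.n_days)
    gap_bounds = []
    for _ in range(n_gaps):
        g0 = day0 + rng.uniform(0, scenario.n_days * 24 * 60) * minute
        g_len = rng.uniform(20, 120)  # minutes
        gap_bounds.append((g0, g0 + g_len * minute))

    recording = None
    missing_fraction = 0.0
    if include_signal:
        recording = simulate_accel(
            hyp, dynamics, sample_hz=scenario.sample_hz, seed=int(rng.integers(2**31))
        )
        keep = np.ones(len(recording), dtype=bool)
        for g0, g1 in gap_bounds:
            keep &= ~((recording.times >= g0) & (recording.times < g1))
        missing_fraction = 1.0 - keep.mean()
        recording = RawRecording(
            recording.times[keep], recording.xyz[keep], scenario.sample_hz, DeviceMeta()
        )
    else:
        total = scenario.n_days * 24 * 60.0
        lost_min = 0.0
        for g0, g1 in gap_bounds:
            lo = max((g0 - day0) / minute, 0.0)
            hi = min((g1 - day0) / minute, total)
            lost_min += max(hi - lo, 0.0)
        missing_fraction = lost_min / total  # ignores gap overlap; upper bound

    return FreeLivingResult(recording, hyp, windows, diary, float(missing_fraction))
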