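"""Core containers shared across the toolkit.

Conventions
-----------
* All timestamps are timezone-naive local time (``numpy.datetime64[ns]``).
* A scoring epoch is 30 s of signal at 30 Hz: exactly 900 samples per axis.
* Stage labels are strings.  Five-class AASM labels are ``W, N1, N2, N3, R``;
  the three-class scheme collapses NREM to ``W, NREM, R``; the two-class
  scheme is wake vs sleep, ``W, S``.  ``?`` marks an epoch that was not
  scored (non-wear or missing signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPOCH_S: int = 30
TARGET_HZ: int = 30
SAMPLES_PER_EPOCH: int = EPOCH_S * TARGET_HZ  # 900

STAGES_5 = ("W", "N1", "N2", "N3", "R")
STAGES_3 = ("W", "NREM", "R")
STAGES_2 = ("W", "S")
MISSING = "?"

#: mapping from five-class label to its collapsed counterpart
_COLLAPSE_3 = {"W": "W", "N1": "NREM", "N2": "NREM", "N3": "NREM", "R": "R"}
_COLLAPSE_2 = {"W": "W", "N1": "S", "N2": "S", "N3": "S", "R": "S"}

SCHEMES = {"five": STAGES_5, "three": STAGES_3, "two": STAGES_2}


def stage_classes(scheme: str) -> tuple[str, ...]:
    """Return the ordered class tuple for a scheme name."""
    try:
        return SCHEMES[scheme]
    except KeyError:  # pragma: no cover - defensive
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {sorted(SCHEMES)}")


def collapse_labels(labels: np.ndarray, scheme: str) -> np.ndarray:
    """Collapse five-class stage labels to the three- or two-class scheme.

    NREM I/II/III merge into ``NREM`` (three-class); REM and NREM merge
    into ``S`` (two-class).  The missing marker passes through unchanged.
    """
    if scheme == "three":
        table = _COLLAPSE_3
    elif scheme == "two":
        table = _COLLAPSE_2
    elif scheme == "five":
        return np.asarray(labels, dtype=object).astype(str)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    out = np.array([table.get(l, MISSING) if l != MISSING else MISSING for l in labels], dtype=object)
    bad = [l for l in np.unique(np.asarray(labels, dtype=object)) if l not in table and l != MISSING]
    if bad:
        raise ValueError(f"labels outside the five-class space: {bad}")
    return out.astype(str)


@dataclass
class DeviceMeta:
    device_id: str = "synthetic"
    dominant_wrist: bool = True
    shift_worker: bool = False
    dst_crossover: bool = False


@dataclass
class RawRecording:
    """A timestamped tri-axial acceleration trace in gravitational units."""

    times: np.ndarray          # datetime64[ns], strictly increasing
    xyz: np.ndarray            # (n, 3) float, g
    sample_hz: float           # nominal sampling rate
    meta: DeviceMeta = field(default_factory=DeviceMeta)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if len(self.times) != len(self.xyz):
            raise ValueError("times and xyz lengths differ")
        if len(self.times) > 1 and not (np.diff(self.times.astype("int64")) > 0).all():
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration_s(self) -> float:
        if len(self.times) < 2:
            return 0.0
        return float((self.times[-1] - self.times[0]) / np.timedelta64(1, "s"))

    def to_csv(self, path) -> None:
        """Write as delimited text with header ``time,x,y,z`` (ISO-8601, g)."""
        df = pd.DataFrame(
            {
                "time": pd.DatetimeIndex(self.times).strftime("%Y-%m-%dT%H:%M:%S.%f"),
                "x": self.xyz[:, 0],
                "y": self.xyz[:, 1],
                "z": self.xyz[:, 2],
            }
        )
        df.to_csv(path, index=False, float_format="%.5f")


@dataclass
class Hypnogram:
    """Per-epoch stage labels aligned to 30-s epoch start times."""

    epoch_starts: np.ndarray   # datetime64[ns]
    stages: np.ndarray         # array of str labels
    scheme: str = "five"

    def __post_init__(self) -> None:
        self.epoch_starts = np.asarray(self.epoch_starts, dtype="datetime64[ns]")
        self.stages = np.asarray(self.stages, dtype=object).astype(str)
        if len(self.epoch_starts) != len(self.stages):
            raise ValueError("epoch_starts and stages lengths differ")
        valid = set(stage_classes(self.scheme)) | {MISSING}
        bad = set(np.unique(self.stages)) - valid
        if bad:
            raise ValueError(f"labels {sorted(bad)} invalid for scheme {self.scheme!r}")

    def __len__(self) -> int:
        return len(self.stages)

    def collapse(self, scheme: str) -> "Hypnogram":
        if self.scheme != "five":
            raise ValueError("can only collapse from the five-class scheme")
        return Hypnogram(self.epoch_starts, collapse_labels(self.stages, scheme), scheme)

    def to_csv(self, path) -> None:
        """Write as delimited text with header ``epoch_start,stage``."""
        pd.DataFrame(
            {
                "epoch_start": pd.DatetimeIndex(self.epoch_starts).strftime("%Y-%m-%dT%H:%M:%S"),
                "stage": self.stages,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scheme: str = "five") -> "Hypnogram":
        df = pd.read_csv(path)
        return cls(
            pd.to_datetime(df["epoch_start"]).to_numpy(),
            df["stage"].to_numpy(dtype=object),
            scheme,
        )


@dataclass
class EpochArray:
    """Fixed 30-s / 30-Hz epochs cut from a recording, with wear flags."""

    epoch_starts: np.ndarray       # (m,) datetime64[ns]
    signals: np.ndarray            # (m, 900, 3) float, g
    wear: np.ndarray               # (m,) bool

    def __post_init__(self) -> None:
        self.epoch_starts = np.asarray(self.epoch_starts, dtype="datetime64[ns]")
        self.signals = np.asarray(self.signals)
        self.wear = np.asarray(self.wear, dtype=bool)
        if self.signals.ndim != 3 or self.signals.shape[1:] != (SAMPLES_PER_EPOCH, 3):
            raise ValueError(f"signals must have shape (m, {SAMPLES_PER_EPOCH}, 3)")
        if not (len(self.epoch_starts) == len(self.signals) == len(self.wear)):
            raise ValueError("component lengths differ")

    def __len__(self) -> int:
        return len(self.epoch_starts)


@dataclass
class SleepWindow:
    """A time-in-bed interval (half-open, [start, end))."""

    start: np.datetime64
    end: np.datetime64
    source: str = "detected"        # {"detected", "truth"}
    merged_from: int = 1
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.start = np.datetime64(self.start, "ns")
        self.end = np.datetime64(self.end, "ns")
        if not self.start < self.end:
            raise ValueError("window start must precede end")

    @property
    def duration_min(self) -> float:
        return float((self.end - self.start) / np.timedelta64(1, "m"))

    @property
    def midpoint(self) -> np.datetime64:
        return self.start + (self.end - self.start) / 2
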