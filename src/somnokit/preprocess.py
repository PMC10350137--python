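"""Raw-trace preprocessing: resampling, clipping, epoching, non-wear, QC.

The processing chain mirrors the standard large-cohort accelerometer
pipeline: resample to 30 Hz, clip to +/-3 g, cut into consecutive 30-s
windows, flag prolonged stationary runs (per-axis sd < 13 mg for more than
60 min) as non-wear, and exclude recordings that cannot be parsed, show a
mean truncated ENMO above 200 mg over wear time, or look badly calibrated.

ENMO (Euclidean norm minus one) is ``max(||a|| - 1 g, 0)`` reported in mg.
Gaps longer than 5 s are never interpolated across: they split a recording
into contiguous segments that are epoched independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    EPOCH_S,
    SAMPLES_PER_EPOCH,
    TARGET_HZ,
    DeviceMeta,
    EpochArray,
    RawRecording,
)

MAX_GAP_S = 5.0          # gaps longer than this split segments
CLIP_G = 3.0
NONWEAR_SD_MG = 13.0
NONWEAR_MIN_RUN_MIN = 60.0
QC_ENMO_MG = 200.0
CALIB_TOL_MG = 30.0      # median stationary magnitude must be 1 g +/- this


class ParseError(ValueError):
    """Raised when a raw file cannot be parsed at all."""


@dataclass
class QCReport:
    parsed: bool = True
    mean_enmo_mg: float = float("nan")
    calibrated: bool = True
    excluded: bool = False
    reasons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.excluded = bool(self.reasons)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "parsed": self.parsed,
                    "mean_enmo_mg": None if np.isnan(self.mean_enmo_mg) else self.mean_enmo_mg,
                    "calibrated": self.calibrated,
                    "excluded": self.excluded,
                    "reasons": self.reasons,
                },
                fh,
                indent=2,
            )


def enmo_mg(xyz: np.ndarray) -> np.ndarray:
    """Per-sample truncated ENMO in mg: ``max(||a||2 - 1, 0) * 1000``."""
    xyz = np.asarray(xyz, dtype=float)
    return np.maximum(np.linalg.norm(xyz, axis=-1) - 1.0, 0.0) * 1000.0


def read_raw(path, format_hint: str = "csv") -> tuple[RawRecording, int]:
    """Read a delimited ``time,x,y,z`` file.

    Returns the recording and the number of malformed rows that were
    dropped.  Raises :class:`ParseError` if nothing usable can be read.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    required = {"time", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path} lacks columns {sorted(required - set(df.columns))}")
    n_in = len(df)
    times = pd.to_datetime(df["time"], errors="coerce")
    vals = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce")
    ok = times.notna() & vals.notna().all(axis=1)
    df, times, vals = df[ok], times[ok], vals[ok]
    n_dropped = n_in - int(ok.sum())
    if len(df) == 0:
        raise ParseError(f"{path} contains no valid samples")
    t = times.to_numpy(dtype="datetime64[ns]")
    order = np.argsort(t, kind="stable")
    t, v = t[order], vals.to_numpy(dtype=float)[order]
    keep = np.concatenate([[True], np.diff(t.astype("int64")) > 0])
    t, v = t[keep], v[keep]
    dt = np.diff(t.astype("int64")) / 1e9
    hz = 1.0 / np.median(dt) if len(dt) else float("nan")
    return RawRecording(t, v, hz, DeviceMeta()), n_dropped


def _segment_bounds(times: np.ndarray, max_gap_s: float = MAX_GAP_S) -> list[tuple[int, int]]:
    """Index ranges of contiguous segments (gaps > max_gap_s split)."""
    if len(times) == 0:
        return []
    dt = np.diff(times.astype("int64")) / 1e9
    cuts = np.flatnonzero(dt > max_gap_s) + 1
    bounds = np.concatenate([[0], cuts, [len(times)]])
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def resample_30hz(rec: RawRecording) -> RawRecording:
    """Resample onto a uniform 30 Hz grid by per-axis linear interpolation.

    The grid is anchored at the first timestamp of each contiguous segment;
    gaps longer than 5 s are not interpolated across.  Input already on a
    uniform 30 Hz grid is returned unchanged.
    """
    if len(rec) == 0:
        raise ValueError("empty recording")
    dt = np.diff(rec.times.astype("int64")) / 1e9
    if len(dt) == 0:
        return rec
    if np.all(np.abs(dt - 1.0 / TARGET_HZ) < 1e-4):
        return RawRecording(rec.times, rec.xyz, TARGET_HZ, rec.meta)
    out_t, out_v = [], []
    for a, b in _segment_bounds(rec.times):
        seg_t = rec.times[a:b]
        seg_v = rec.xyz[a:b]
        rel = (seg_t - seg_t[0]).astype("int64") / 1e9
        if rel[-1] <= 0:
            continue
        # tolerance absorbs ns-rounded timestamps just short of the grid
        n_out = int(np.floor(rel[-1] * TARGET_HZ + 1e-4)) + 1
        grid = np.arange(n_out) / TARGET_HZ
        vals = np.column_stack([np.interp(grid, rel, seg_v[:, k]) for k in range(3)])
        t0 = np.datetime64(seg_t[0], "ns")
        out_t.append(t0 + np.round(grid * 1e9).astype("int64").astype("timedelta64[ns]"))
        out_v.append(vals)
    if not out_t:
        raise ValueError("recording has no segment longer than one sample")
    return RawRecording(np.concatenate(out_t), np.vstack(out_v), TARGET_HZ, rec.meta)


def clip_3g(rec: RawRecording) -> RawRecording:
    """Clip acceleration to +/-3 g; in-range values are unchanged."""
    return RawRecording(rec.times, np.clip(rec.xyz, -CLIP_G, CLIP_G), rec.sample_hz, rec.meta)


def make_epochs(rec: RawRecording) -> EpochArray:
    """Cut a 30-Hz recording into consecutive 30-s epochs.

    Each contiguous segment yields ``floor(n / 900)`` epochs; trailing
    partial epochs are dropped.  A recording shorter than 30 s gives an
    empty array.  All wear flags start True.
    """
    if abs(rec.sample_hz - TARGET_HZ) > 0.5:
        raise ValueError("make_epochs expects a 30 Hz recording; call resample_30hz first")
    starts, sigs = [], []
    for a, b in _segment_bounds(rec.times, max_gap_s=1.5 / TARGET_HZ):
        n_ep = (b - a) // SAMPLES_PER_EPOCH
        seg_start = np.datetime64(rec.times[a], "ns")
        for k in range(n_ep):
            i = a + k * SAMPLES_PER_EPOCH
            # exact 30-s grid anchored at the segment start
            starts.append(seg_start + k * np.timedelta64(EPOCH_S, "s"))
            sigs.append(rec.xyz[i : i + SAMPLES_PER_EPOCH])
    if not starts:
        return EpochArray(
            np.empty(0, dtype="datetime64[ns]"),
            np.empty((0, SAMPLES_PER_EPOCH, 3)),
            np.empty(0, dtype=bool),
        )
    return EpochArray(np.array(starts), np.stack(sigs), np.ones(len(starts), dtype=bool))


def detect_nonwear(
    epochs: EpochArray,
    sd_thresh_mg: float = NONWEAR_SD_MG,
    min_run_min: float = NONWEAR_MIN_RUN_MIN,
) -> EpochArray:
    """Flag prolonged stationary runs as non-wear.

    An epoch is stationary iff the within-epoch sd of each axis is below
    ``sd_thresh_mg``.  Maximal runs of consecutive stationary epochs with
    total duration strictly greater than ``min_run_min`` are flagged
    non-wear; everything else is wear.  Runs do not extend across gaps.
    """
    m = len(epochs)
    wear = np.ones(m, dtype=bool)
    if m == 0:
        return EpochArray(epochs.epoch_starts, epochs.signals, wear)
    sd_mg = epochs.signals.std(axis=1) * 1000.0  # (m, 3)
    stationary = (sd_mg < sd_thresh_mg).all(axis=1)
    gaps = np.diff(epochs.epoch_starts.astype("int64")) / 1e9
    contiguous = np.concatenate([[False], np.abs(gaps - EPOCH_S) < 1e-6])
    i = 0
    while i < m:
        if not stationary[i]:
            i += 1
            continue
        j = i + 1
        while j < m and stationary[j] and contiguous[j]:
            j += 1
        if (j - i) * (EPOCH_S / 60.0) > min_run_min:
            wear[i:j] = False
        i = j
    return EpochArray(epochs.epoch_starts, epochs.signals, wear)


def qc_screen(rec: RawRecording | None, epochs: EpochArray | None, parsed: bool = True) -> QCReport:
    """Recording-level quality screen; reports, never raises.

    A recording is excluded if it could not be parsed, if its mean
    truncated ENMO over wear epochs exceeds 200 mg, or if the median
    vector magnitude over stationary epochs departs from 1 g by more
    than 30 mg (poor calibration).
    """
    if not parsed or epochs is None:
        return QCReport(parsed=False, reasons=["parse"])
    reasons: list[str] = []
    mean_enmo = float("nan")
    if len(epochs) and epochs.wear.any():
        mean_enmo = float(enmo_mg(epochs.signals[epochs.wear]).mean())
        if mean_enmo > QC_ENMO_MG:
            reasons.append("high_values")
    calibrated = True
    if len(epochs):
        sd_mg = epochs.signals.std(axis=1) * 1000.0
        stationary = (sd_mg < NONWEAR_SD_MG).all(axis=1)
        if stationary.any():
            med_mag = float(
                np.median(np.linalg.norm(epochs.signals[stationary], axis=-1)) * 1000.0
            )
            calibrated = abs(med_mag - 1000.0) <= CALIB_TOL_MG
            if not calibrated:
                reasons.append("calibration")
    return QCReport(parsed=True, mean_enmo_mg=mean_enmo, calibrated=calibrated, reasons=reasons)


def preprocess(
    rec: RawRecording,
    sd_thresh_mg: float = NONWEAR_SD_MG,
    nonwear_min: float = NONWEAR_MIN_RUN_MIN,
) -> tuple[EpochArray, QCReport]:
    """Full chain: resample -> clip -> epochs -> non-wear -> QC screen."""
    rec30 = clip_3g(resample_30hz(rec))
    epochs = detect_nonwear(make_epochs(rec30), sd_thresh_mg, nonwear_min)
    return epochs, qc_screen(rec30, epochs)
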