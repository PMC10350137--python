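"""Per-night sleep parameters, weekly summaries, and exposure categories.

Seven parameters are derived from a staged time-in-bed window (three-class
labels on 30-s epochs): total sleep duration (TST), sleep efficiency
(TST over time in bed), wake after sleep onset (WASO, from the first sleep
epoch to the end of the window), REM and NREM durations, and the REM/NREM
ratios as percentages of TST.  Weekly summaries average valid days only: a
week is valid with at least three days of >= 22 h wear including at least
one weekday and one weekend day.  Exposure categories follow the duration
bands short < 6 h, normal 6-7.9 h, long >= 8 h, and a configurable
low/high sleep-efficiency split (cohort median by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import EPOCH_S, MISSING, SleepWindow

MIN_VALID_DAYS = 3
MIN_WEAR_HOURS = 22.0


@dataclass
class SleepParameters:
    total_sleep_duration: float      # min
    sleep_efficiency: float          # %
    waso: float                      # min; NaN when the window has no sleep
    rem_duration: float              # min
    nrem_duration: float             # min
    rem_ratio: float                 # % of TST; NaN when TST == 0
    nrem_ratio: float                # %
    window: SleepWindow | None = None


def compute_params(
    window: SleepWindow, labels: np.ndarray, epoch_starts: np.ndarray
) -> SleepParameters:
    """Derive the seven parameters from three-class labels over a window.

    Sleep onset is the first sleep epoch inside the window; WASO counts
    wake epochs from onset to the window end.  Unscored (missing) epochs
    count as wake.  A window with no sleep epoch yields TST = 0, SE = 0
    and missing (NaN) WASO and ratios.
    """
    labels = np.asarray(labels, dtype=object)
    starts = np.asarray(epoch_starts, dtype="datetime64[ns]")
    inside = (starts >= window.start) & (starts < window.end)
    n_expected = int(round((window.end - window.start) / np.timedelta64(EPOCH_S, "s")))
    if inside.sum() < n_expected:
        raise ValueError("labels do not cover the window")
    lab = labels[inside]
    bad = set(lab) - {"W", "NREM", "R", MISSING}
    if bad:
        raise ValueError(f"expected three-class labels, got {sorted(bad)}")
    asleep = np.isin(lab, ("NREM", "R"))
    n_rem = int((lab == "R").sum())
    n_nrem = int((lab == "NREM").sum())
    tst = 0.5 * (n_rem + n_nrem)
    tib_min = n_expected * EPOCH_S / 60.0
    se = 100.0 * tst / tib_min if tib_min > 0 else 0.0
    if not asleep.any():
        return SleepParameters(0.0, 0.0, np.nan, 0.0, 0.0, np.nan, np.nan, window)
    onset = int(np.flatnonzero(asleep)[0])
    waso = 0.5 * int((~asleep[onset:]).sum())
    return SleepParameters(
        total_sleep_duration=tst,
        sleep_efficiency=se,
        waso=waso,
        rem_duration=0.5 * n_rem,
        nrem_duration=0.5 * n_nrem,
        rem_ratio=100.0 * n_rem / (n_rem + n_nrem),
        nrem_ratio=100.0 * n_nrem / (n_rem + n_nrem),
        window=window,
    )


@dataclass
class WeeklySummary:
    means: dict                      # parameter name -> mean over valid days
    n_valid_days: int
    wear_hours_per_day: float        # mean over all days with any wear
    includes_weekday: bool
    includes_weekend: bool
    valid: bool


_PARAM_FIELDS = (
    "total_sleep_duration", "sleep_efficiency", "waso",
    "rem_duration", "nrem_duration", "rem_ratio", "nrem_ratio",
)


def weekly_summary(
    daily: list[tuple],
    min_valid_days: int = MIN_VALID_DAYS,
    min_wear_hours: float = MIN_WEAR_HOURS,
) -> WeeklySummary:
    """Summarise one week of (day, params, wear_hours) triples.

    ``day`` is the noon-to-noon interval start date (anything
    ``pandas.Timestamp`` accepts); weekday/weekend comes from its civil
    calendar day.  Days with wear below the threshold or without
    parameters are not averaged.  The summary is valid iff there are at
    least ``min_valid_days`` valid days including at least one weekday
    and one weekend day.
    """
    rows = []
    wear_all = []
    for day, params, wear_hours in daily:
        ts = pd.Timestamp(day)
        wear_all.append(wear_hours)
        if params is None or wear_hours < min_wear_hours:
            continue
        rows.append((ts.weekday() >= 5, params))
    includes_weekday = any(not we for we, _ in rows)
    includes_weekend = any(we for we, _ in rows)
    n_valid = len(rows)
    valid = n_valid >= min_valid_days and includes_weekday and includes_weekend
    means = {}
    for f in _PARAM_FIELDS:
        vals = [getattr(p, f) for _, p in rows]
        vals = [v for v in vals if np.isfinite(v)]
        means[f] = float(np.mean(vals)) if vals else np.nan
    return WeeklySummary(
        means=means,
        n_valid_days=n_valid,
        wear_hours_per_day=float(np.mean(wear_all)) if wear_all else 0.0,
        includes_weekday=includes_weekday,
        includes_weekend=includes_weekend,
        valid=valid,
    )


def categorize_exposures(summary: WeeklySummary, efficiency_split: float) -> tuple[str, str]:
    """Map a valid weekly summary to (duration_class, efficiency_class).

    Duration bands on the weekly mean overnight sleep duration:
    short < 6 h, normal 6-7.9 h (i.e. < 8 h), long >= 8 h.  Efficiency is
    dichotomised at ``efficiency_split`` (typically the cohort median):
    low < split <= high.
    """
    if not summary.valid:
        raise ValueError("cannot categorise an invalid weekly summary")
    hours = summary.means["total_sleep_duration"] / 60.0
    if hours < 6.0:
        duration = "short"
    elif hours < 8.0:
        duration = "normal"
    else:
        duration = "long"
    efficiency = "low" if summary.means["sleep_efficiency"] < efficiency_split else "high"
    return duration, efficiency
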