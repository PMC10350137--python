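"""Free-living time-in-bed window logic.

From a smoothed per-epoch sleep/wake sequence: maximal sleep runs become
candidate time-in-bed windows (runs under 30 min are discarded), windows
within 60 min of one another are merged (gap included), and the longest
merged window per noon-to-noon interval — assigned by window midpoint —
is the overnight sleep-opportunity window.  Overnight sleep duration is
then 0.5 min per staged sleep epoch inside that window.
"""

from __future__ import annotations

import numpy as np

from .types import EPOCH_S, MISSING, SleepWindow

MIN_WINDOW_MIN = 30.0
MERGE_GAP_MIN = 60.0
LOW_CONFIDENCE_NONWEAR_FRAC = 0.20


def detect_time_in_bed(
    labels: np.ndarray,
    epoch_starts: np.ndarray,
    min_window_min: float = MIN_WINDOW_MIN,
) -> list[SleepWindow]:
    """Candidate windows: maximal runs of 'S' epochs at least 30 min long.

    ``labels`` is a two-class (W/S) sequence; the missing marker is treated
    as wake for run-finding.  Windows are half-open epoch-aligned
    intervals.
    """
    labels = np.asarray(labels, dtype=object)
    starts = np.asarray(epoch_starts, dtype="datetime64[ns]")
    if len(labels) != len(starts):
        raise ValueError("labels and epoch_starts lengths differ")
    sleep = labels == "S"
    out: list[SleepWindow] = []
    i = 0
    m = len(labels)
    while i < m:
        if not sleep[i]:
            i += 1
            continue
        j = i + 1
        while j < m and sleep[j]:
            j += 1
        dur_min = (j - i) * EPOCH_S / 60.0
        if dur_min >= min_window_min:
            out.append(
                SleepWindow(starts[i], starts[j - 1] + np.timedelta64(EPOCH_S, "s"))
            )
        i = j
    return out


def merge_windows(windows: list[SleepWindow], gap_max_min: float = MERGE_GAP_MIN) -> list[SleepWindow]:
    """Union consecutive windows whose gap is at most 60 min (gap included).

    Input windows must be non-overlapping; they are sorted by start.
    Idempotent: merging a merged list changes nothing.
    """
    if not windows:
        return []
    ws = sorted(windows, key=lambda w: (w.start, w.end))
    for a, b in zip(ws[:-1], ws[1:]):
        if b.start < a.end:
            raise ValueError("overlapping windows cannot be merged")
    out = [ws[0]]
    for w in ws[1:]:
        gap_min = (w.start - out[-1].end) / np.timedelta64(1, "m")
        if gap_min <= gap_max_min:
            prev = out[-1]
            out[-1] = SleepWindow(
                prev.start, max(prev.end, w.end), source=prev.source,
                merged_from=prev.merged_from + w.merged_from,
            )
        else:
            out.append(w)
    return out


def time_in_bed_windows(
    labels: np.ndarray,
    epoch_starts: np.ndarray,
    min_window_min: float = MIN_WINDOW_MIN,
    gap_max_min: float = MERGE_GAP_MIN,
) -> list[SleepWindow]:
    """End-to-end time-in-bed detection: find runs, merge, then filter.

    All sleep runs (however short) enter the 60-min merge, and the 30-min
    minimum length is applied to the *merged* windows.  Merging before
    filtering matters: brief within-night wake bouts fragment the night
    into short runs that a pre-merge length filter would discard,
    truncating the detected window at the first or last long sleep run.
    """
    runs = detect_time_in_bed(labels, epoch_starts, min_window_min=0.0)
    merged = merge_windows(runs, gap_max_min=gap_max_min)
    return [w for w in merged if w.duration_min >= min_window_min]


def noon_interval_of(t: np.datetime64) -> np.datetime64:
    """The date (as datetime64[D]) whose noon starts the interval holding t."""
    t = np.datetime64(t, "ns")
    day = t.astype("datetime64[D]")
    noon = day.astype("datetime64[ns]") + np.timedelta64(12, "h")
    if t < noon:
        day = day - np.timedelta64(1, "D")
    return day


def longest_per_noon_interval(windows: list[SleepWindow]) -> dict:
    """Longest merged window per noon-to-noon interval (by window midpoint).

    Returns a mapping from interval start date (datetime64[D], meaning
    [date 12:00, date+1 12:00)) to the selected window.  Ties go to the
    earlier start; intervals without windows are absent.
    """
    best: dict = {}
    for w in windows:
        key = noon_interval_of(w.midpoint)
        cur = best.get(key)
        if (
            cur is None
            or w.duration_min > cur.duration_min
            or (w.duration_min == cur.duration_min and w.start < cur.start)
        ):
            best[key] = w
    return best


def overnight_sleep_duration(
    window: SleepWindow, labels: np.ndarray, epoch_starts: np.ndarray
) -> float:
    """Minutes asleep (REM or NREM) within a staged window.

    ``labels`` is a three-class (W/NREM/R) sequence covering the window;
    a window epoch with no label raises; the missing marker (non-wear)
    counts as wake.  Each sleep epoch contributes 0.5 min.
    """
    labels = np.asarray(labels, dtype=object)
    starts = np.asarray(epoch_starts, dtype="datetime64[ns]")
    inside = (starts >= window.start) & (starts < window.end)
    n_expected = int(round((window.end - window.start) / np.timedelta64(EPOCH_S, "s")))
    if inside.sum() < n_expected:
        raise ValueError("labels do not cover the window")
    lab = labels[inside]
    return 0.5 * int(np.isin(lab, ("NREM", "R")).sum())


def flag_low_confidence(window: SleepWindow, labels: np.ndarray, epoch_starts: np.ndarray) -> SleepWindow:
    """Mark a window low-confidence if > 20% of its epochs are unscored."""
    labels = np.asarray(labels, dtype=object)
    starts = np.asarray(epoch_starts, dtype="datetime64[ns]")
    inside = (starts >= window.start) & (starts < window.end)
    if inside.sum() == 0:
        return window
    frac = float((labels[inside] == MISSING).mean())
    window.low_confidence = frac > LOW_CONFIDENCE_NONWEAR_FRAC
    return window
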