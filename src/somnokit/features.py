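"""Hand-crafted per-epoch features for the random-forest baseline.

Each 30-s / 30-Hz epoch maps to a fixed, named vector of time- and
frequency-domain statistics of the kind classical actigraphy sleep/wake
algorithms use: movement intensity (ENMO), posture (z-angle, roll, pitch),
inter-axis correlations, and the spectrum of the gravity-removed magnitude.
Extraction is deterministic and fully vectorised over epochs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import SAMPLES_PER_EPOCH, TARGET_HZ, EpochArray


def _central_moments(x: np.ndarray):
    d = x - x.mean(axis=1, keepdims=True)
    return (d**2).mean(axis=1), (d**3).mean(axis=1), (d**4).mean(axis=1)


def _skew(x: np.ndarray) -> np.ndarray:
    m2, m3, _ = _central_moments(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(m2 > 0, m3 / np.maximum(m2, 1e-30) ** 1.5, 0.0)


def _kurtosis(x: np.ndarray) -> np.ndarray:
    """Excess kurtosis; 0 for a constant signal."""
    m2, _, m4 = _central_moments(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(m2 > 0, m4 / np.maximum(m2, 1e-30) ** 2 - 3.0, 0.0)

FEATURE_NAMES = (
    "mean_x", "mean_y", "mean_z",
    "sd_x", "sd_y", "sd_z",
    "range_x", "range_y", "range_z",
    "enmo_mean", "enmo_sd", "enmo_mad",
    "corr_xy", "corr_xz", "corr_yz",
    "zangle_mean", "zangle_asd",
    "roll_mean", "roll_sd", "pitch_mean", "pitch_sd",
    "dom_freq", "dom_freq_power", "power_1_3hz", "spectral_entropy",
    "p2p_mag", "mag_kurtosis", "mag_skew",
)

_FREQ_BAND = (0.3, 15.0)  # Hz, search band for the dominant frequency


def _safe_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation along axis 1; 0 where either signal is constant."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    num = (ac * bc).sum(axis=1)
    out = np.zeros(len(a))
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def extract_feature_matrix(signals: np.ndarray) -> pd.DataFrame:
    """Feature matrix for a stack of epochs, shape (m, 900, 3) -> (m, 28)."""
    sig = np.asarray(signals, dtype=float)
    if sig.ndim != 3 or sig.shape[1:] != (SAMPLES_PER_EPOCH, 3):
        raise ValueError(f"expected (m, {SAMPLES_PER_EPOCH}, 3) signals")
    x, y, z = sig[:, :, 0], sig[:, :, 1], sig[:, :, 2]
    mag = np.linalg.norm(sig, axis=2)
    enmo = np.maximum(mag - 1.0, 0.0)

    deg = 180.0 / np.pi
    zangle = np.arctan2(z, np.sqrt(x**2 + y**2)) * deg
    roll = np.arctan2(y, z) * deg
    pitch = np.arctan2(-x, np.sqrt(y**2 + z**2)) * deg

    # spectrum: sum of per-axis PSDs of the mean-removed (gravity-free)
    # signals, Hann-windowed.  Summing axes keeps oscillations that are
    # orthogonal to gravity, which the magnitude alone cancels.
    win = np.hanning(SAMPLES_PER_EPOCH)
    centred = sig - sig.mean(axis=1, keepdims=True)
    psd = (np.abs(np.fft.rfft(centred * win[None, :, None], axis=1)) ** 2).sum(axis=2)
    freqs = np.fft.rfftfreq(SAMPLES_PER_EPOCH, d=1.0 / TARGET_HZ)
    band = (freqs >= _FREQ_BAND[0]) & (freqs <= _FREQ_BAND[1])
    pband = psd[:, band]
    fband = freqs[band]
    dom_idx = pband.argmax(axis=1)
    ptot = pband.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_norm = np.where(ptot[:, None] > 0, pband / np.maximum(ptot[:, None], 1e-300), 0.0)
        ent = -np.where(p_norm > 0, p_norm * np.log(p_norm), 0.0).sum(axis=1)
    p13 = psd[:, (freqs >= 1.0) & (freqs <= 3.0)].sum(axis=1)

    cols = {
        "mean_x": x.mean(axis=1), "mean_y": y.mean(axis=1), "mean_z": z.mean(axis=1),
        "sd_x": x.std(axis=1), "sd_y": y.std(axis=1), "sd_z": z.std(axis=1),
        "range_x": x.max(axis=1) - x.min(axis=1),
        "range_y": y.max(axis=1) - y.min(axis=1),
        "range_z": z.max(axis=1) - z.min(axis=1),
        "enmo_mean": enmo.mean(axis=1),
        "enmo_sd": enmo.std(axis=1),
        "enmo_mad": np.median(np.abs(enmo - np.median(enmo, axis=1, keepdims=True)), axis=1),
        "corr_xy": _safe_corr(x, y),
        "corr_xz": _safe_corr(x, z),
        "corr_yz": _safe_corr(y, z),
        "zangle_mean": zangle.mean(axis=1),
        "zangle_asd": np.abs(np.diff(zangle, axis=1)).mean(axis=1),
        "roll_mean": roll.mean(axis=1), "roll_sd": roll.std(axis=1),
        "pitch_mean": pitch.mean(axis=1), "pitch_sd": pitch.std(axis=1),
        "dom_freq": fband[dom_idx],
        "dom_freq_power": pband[np.arange(len(sig)), dom_idx],
        "power_1_3hz": p13,
        "spectral_entropy": ent,
        "p2p_mag": mag.max(axis=1) - mag.min(axis=1),
        "mag_kurtosis": _kurtosis(mag),
        "mag_skew": _skew(mag),
    }
    df = pd.DataFrame(cols, columns=list(FEATURE_NAMES))
    # constant epochs can make skew/kurtosis NaN; features must stay finite
    return df.replace([np.inf, -np.inf], np.nan).fillna(0.0)


def extract_features(epoch: np.ndarray) -> pd.Series:
    """Feature vector of a single (900, 3) epoch."""
    return extract_feature_matrix(np.asarray(epoch)[None]).iloc[0]


def features_for(epochs: EpochArray) -> pd.DataFrame:
    """Features for every epoch of an :class:`EpochArray` (wear or not)."""
    return extract_feature_matrix(epochs.signals)
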