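"""Deterministic EEG signal conditioning.

Fixed pipeline order: resample -> bandpass + notch filter -> average
reference -> (epoching happens at generation/import time) -> automatic
artifact rejection -> topographic interpolation of bad channels ->
baseline correction.  Manual inspection and ICA are out of scope; the
rejection log records that only the two automatic criteria were applied.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import ndimage, signal

from .synthgen import Epochs


@dataclass
class PreprocConfig:
    target_rate_hz: float = 256.0
    band_hz: tuple[float, float] = (0.5, 40.0)
    filter_order: int = 8            # final effective bandpass order
    notch_hz: tuple[float, float] = (48.0, 52.0)
    amplitude_criterion_uv: float = 200.0
    flatline_criterion_uv: float = 0.5
    flatline_duration_ms: float = 100.0
    baseline_window_s: tuple[float, float] = (-0.2, 0.0)

    def __post_init__(self):
        if self.band_hz[0] >= self.band_hz[1] or self.notch_hz[0] >= self.notch_hz[1]:
            raise ValueError("filter bands must be well-ordered")
        if self.baseline_window_s[0] >= self.baseline_window_s[1]:
            raise ValueError("baseline window must be well-ordered")
        if min(self.amplitude_criterion_uv, self.flatline_criterion_uv,
               self.flatline_duration_ms, self.target_rate_hz) <= 0:
            raise ValueError("criteria must be positive")


def resample(epochs: Epochs, target_rate_hz: float) -> Epochs:
    """Polyphase resampling to ``target_rate_hz`` (downsampling only)."""
    if target_rate_hz > epochs.sfreq:
        raise ValueError("upsampling is not supported")
    if target_rate_hz == epochs.sfreq:
        return epochs.copy()
    frac = Fraction(target_rate_hz / epochs.sfreq).limit_denominator(1000)
    data = signal.resample_poly(epochs.data, frac.numerator, frac.denominator, axis=-1)
    return replace(epochs, data=data, sfreq=epochs.sfreq * frac.numerator / frac.denominator)


def filter_band_notch(epochs: Epochs, cfg: PreprocConfig | None = None) -> Epochs:
    """Zero-phase Butterworth bandpass (0.5-40 Hz, 8th order) plus a
    narrow 48-52 Hz band-stop notch.

    The bandpass is designed as a 4-section Butterworth (8 poles) and
    applied forward-backward, so the stated order is the order of the
    designed filter; the zero-phase pass squares its magnitude response.
    """
    cfg = cfg or PreprocConfig()
    if epochs.sfreq <= 2.0 * cfg.band_hz[1]:
        raise ValueError("sampling rate too low for the requested bandpass")
    sos_band = signal.butter(cfg.filter_order // 2, cfg.band_hz, btype="bandpass",
                             fs=epochs.sfreq, output="sos")
    sos_notch = signal.butter(2, cfg.notch_hz, btype="bandstop",
                              fs=epochs.sfreq, output="sos")
    data = signal.sosfiltfilt(sos_band, epochs.data, axis=-1)
    data = signal.sosfiltfilt(sos_notch, data, axis=-1)
    return replace(epochs, data=data)


def rereference_average(epochs: Epochs) -> Epochs:
    """Common average reference: per-sample channel mean becomes zero."""
    if epochs.data.shape[1] < 2:
        raise ValueError("average reference needs at least two channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return replace(epochs, data=data)


def reject_artifacts(epochs: Epochs, cfg: PreprocConfig | None = None) -> tuple[Epochs, pd.DataFrame]:
    """Automatic epoch rejection.

    An epoch is dropped when any channel (a) exceeds +/-200 uV or
    (b) stays below 0.5 uV peak-to-peak over any 100 ms window
    (flatline).  A violation on one channel rejects the whole epoch.
    Returns the surviving epochs plus a per-trial log; an all-rejected
    input yields an Epochs object with zero trials.
    """
    cfg = cfg or PreprocConfig()
    data = epochs.data
    n_trials, _, n_times = data.shape
    w = max(int(round(cfg.flatline_duration_ms / 1000.0 * epochs.sfreq)), 2)
    amp_bad = np.abs(data).max(axis=2) > cfg.amplitude_criterion_uv  # (trials, ch)
    if n_times >= w:
        # peak-to-peak over every full sliding window of length w
        mx = ndimage.maximum_filter1d(data, size=w, axis=2, mode="nearest")
        mn = ndimage.minimum_filter1d(data, size=w, axis=2, mode="nearest")
        lo, hi = w // 2, n_times - (w - w // 2)  # centers of full windows
        ptp = (mx - mn)[:, :, lo : hi + 1]
        flat_bad = (ptp < cfg.flatline_criterion_uv).any(axis=2)
    else:
        flat_bad = np.zeros(amp_bad.shape, dtype=bool)
    rows = []
    keep = np.ones(n_trials, dtype=bool)
    for i in range(n_trials):
        if amp_bad[i].any():
            keep[i] = False
            ch = epochs.array.names[int(np.argmax(amp_bad[i]))]
            rows.append(dict(trial=i, reason="amplitude", channel=ch))
        elif flat_bad[i].any():
            keep[i] = False
            ch = epochs.array.names[int(np.argmax(flat_bad[i]))]
            rows.append(dict(trial=i, reason="flatline", channel=ch))
    log = pd.DataFrame(rows, columns=["trial", "reason", "channel"])
    log.attrs["note"] = "automatic criteria only; no manual inspection or ICA applied"
    return replace(epochs, data=data[keep]), log


def _legendre_g(cosang: np.ndarray, m: int = 4, n_terms: int = 20) -> np.ndarray:
    """Perrin spherical-spline kernel g(x) = sum (2n+1)/(n(n+1))^m P_n(x)."""
    n = np.arange(1, n_terms + 1)
    coef = np.zeros(n_terms + 1)
    coef[1:] = (2 * n + 1) / (n * (n + 1.0)) ** m / (4 * np.pi)
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coef)


def interpolate_channels(epochs: Epochs, bad_channels, reg: float = 1e-5) -> Epochs:
    """Spherical-spline topographic interpolation of bad channels from
    the remaining channels; good channels are untouched."""
    bad = list(bad_channels)
    if not bad:
        return epochs.copy()
    bad_idx = epochs.array.index(bad)
    good_idx = np.setdiff1d(np.arange(len(epochs.array)), bad_idx)
    if len(good_idx) == 0:
        raise ValueError("cannot interpolate: all channels are bad")
    pos = epochs.array.positions
    g_gg = _legendre_g(pos[good_idx] @ pos[good_idx].T)
    g_bg = _legendre_g(pos[bad_idx] @ pos[good_idx].T)
    ng = len(good_idx)
    # spline system with the usual constant-term constraint
    a = np.empty((ng + 1, ng + 1))
    a[:ng, :ng] = g_gg + reg * np.eye(ng)
    a[:ng, ng] = 1.0
    a[ng, :ng] = 1.0
    a[ng, ng] = 0.0
    data = epochs.data.copy()
    v = data[:, good_idx, :]                                 # (trials, ng, times)
    rhs = np.concatenate([v, np.zeros((v.shape[0], 1, v.shape[2]))], axis=1)
    sol = np.linalg.solve(a, rhs.transpose(1, 0, 2).reshape(ng + 1, -1))
    w, c0 = sol[:ng], sol[ng]
    interp = (g_bg @ w + c0).reshape(len(bad_idx), v.shape[0], v.shape[2])
    data[:, bad_idx, :] = interp.transpose(1, 0, 2)
    return replace(epochs, data=data)


def baseline_correct(epochs: Epochs, window_s: tuple[float, float] = (-0.2, 0.0)) -> Epochs:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    times = epochs.times
    if window_s[0] < times[0] - 1e-9 or window_s[1] > times[-1] + 1e-9:
        raise ValueError("baseline window outside epoch")
    mask = (times >= window_s[0]) & (times <= window_s[1])
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    data = epochs.data - epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=data)


def preprocess_epochs(
    epochs: Epochs,
    cfg: PreprocConfig | None = None,
    bad_channels=(),
) -> tuple[Epochs, pd.DataFrame]:
    """Run the full fixed-order pipeline on already-epoched data."""
    cfg = cfg or PreprocConfig()
    out = epochs
    if cfg.target_rate_hz < out.sfreq:
        out = resample(out, cfg.target_rate_hz)
    out = filter_band_notch(out, cfg)
    out = rereference_average(out)
    out, log = reject_artifacts(out, cfg)
    out = interpolate_channels(out, bad_channels)
    out = baseline_correct(out, cfg.baseline_window_s)
    return out, log


def load_brainvision_raw(vhdr_path):
    """Optional entry point for real recordings: read a BrainVision
    (.vhdr/.vmrk/.eeg) file and return (data_uv, sfreq, channel_names).
    Requires the optional ``mne`` dependency."""
    import mne  # optional dependency

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)
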