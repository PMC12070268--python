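"""Morlet wavelet time-frequency decomposition and band averaging.

Total (trial-averaged, non-phase-locked) power is computed by convolving
each trial with complex Morlet wavelets of a fixed number of cycles and
averaging |coefficient|^2 across trials.  Wavelets are normalised to
unit discrete energy, so white noise of variance s^2 yields an expected
power of s^2 at every frequency (flat spectrum check).

Band statistics average power over the canonical theta (4-7 Hz),
alpha (8-12 Hz) and beta (15-30 Hz) bands and over an analysis time
window (default 0-1 s post-stimulus).  Raw power enters the statistics;
no baseline normalisation or log transform is applied.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy.fft import next_fast_len

from .synthgen import Epochs

#: canonical frequency bands, Hz (inclusive)
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (15.0, 30.0),
}

DEFAULT_FREQS = np.arange(3.0, 31.0)
DEFAULT_TIME_WINDOW = (0.0, 1.0)


def band_limits(band) -> tuple[float, float]:
    if isinstance(band, str):
        try:
            return BANDS[band]
        except KeyError:
            raise ValueError(f"unknown band {band!r}") from None
    lo, hi = band
    if lo > hi:
        raise ValueError("band limits must be ordered")
    return float(lo), float(hi)


@dataclass
class TFR:
    """Trial-averaged time-frequency power for one subject x condition."""

    subject_id: str
    condition: str
    power: np.ndarray      # (channels, freqs, times), uV^2
    freqs: np.ndarray
    times: np.ndarray
    channel_names: list[str]
    n_trials: int

    def __post_init__(self):
        if (self.power < 0).any():
            raise ValueError("power must be non-negative")


@dataclass
class BandPower:
    """Band- and time-averaged power per channel (or voxel)."""

    subject_id: str
    condition: str
    band: tuple[float, float]
    values: np.ndarray     # (channels,) or (voxels,)
    channel_names: list[str] | None = None


def morlet_wavelet(freq_hz: float, sfreq: float, n_cycles: float = 7.0) -> np.ndarray:
    """Complex Morlet wavelet with unit discrete energy, truncated at
    +/-3 temporal standard deviations."""
    sigma_t = n_cycles / (2.0 * np.pi * freq_hz)
    half = int(math.ceil(3.0 * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * freq_hz * t)
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def morlet_tfr(
    epochs: Epochs,
    freqs: np.ndarray | None = None,
    n_cycles: float = 7.0,
) -> TFR:
    """Wavelet power decomposition of one subject x condition.

    Trials are zero-padded to the ceiling of the trial length in
    seconds before the FFT-based convolution, and the result is cropped
    back to the original time axis.  Raises if the epoch is shorter
    than the longest wavelet.
    """
    freqs = DEFAULT_FREQS if freqs is None else np.atleast_1d(np.asarray(freqs, float))
    data = epochs.data
    n_trials, n_ch, n_times = data.shape
    sfreq = epochs.sfreq
    # padding rule: ceiling of trial length (samples) / sampling rate, in seconds
    pad_samples = int(math.ceil(n_times / sfreq) * sfreq)
    wavelets = [morlet_wavelet(f, sfreq, n_cycles) for f in freqs]
    max_wav = max(len(w) for w in wavelets)
    if max_wav > n_times:
        raise ValueError(
            f"epoch ({n_times} samples) shorter than the {freqs[np.argmax([len(w) for w in wavelets])]:g} Hz "
            f"wavelet ({max_wav} samples)"
        )
    nfft = next_fast_len(pad_samples + max_wav - 1)
    # scipy.fft preserves single precision, which keeps large
    # simulation studies cheap; power is returned in float64
    spec = sp_fft.fft(data.astype(complex if data.dtype == np.float64 else np.complex64),
                      n=nfft, axis=-1)
    power = np.empty((n_ch, len(freqs), n_times))
    for k, w in enumerate(wavelets):
        half = (len(w) - 1) // 2
        wf = sp_fft.fft(np.asarray(w, dtype=spec.dtype), n=nfft)
        conv = sp_fft.ifft(spec * wf, axis=-1)[..., half : half + n_times]
        power[:, k, :] = np.mean(np.abs(conv) ** 2, axis=0, dtype=np.float64)
    return TFR(
        subject_id=epochs.subject_id, condition=epochs.condition,
        power=power, freqs=freqs, times=epochs.times,
        channel_names=list(epochs.array.names), n_trials=n_trials,
    )


def band_average(
    tfr: TFR,
    band,
    time_window: tuple[float, float] = DEFAULT_TIME_WINDOW,
) -> BandPower:
    """Arithmetic mean of power over the band's frequency bins and the
    analysis time window."""
    lo, hi = band_limits(band)
    fmask = (tfr.freqs >= lo) & (tfr.freqs <= hi)
    tmask = (tfr.times >= time_window[0]) & (tfr.times <= time_window[1])
    if not fmask.any():
        raise ValueError(f"no frequency bins inside band {lo}-{hi} Hz")
    if not tmask.any():
        raise ValueError("no samples inside the analysis time window")
    values = tfr.power[:, fmask, :][:, :, tmask].mean(axis=(1, 2))
    return BandPower(
        subject_id=tfr.subject_id, condition=tfr.condition,
        band=(lo, hi), values=values, channel_names=tfr.channel_names,
    )


def condition_contrast(bp_overlap: BandPower, bp_nonoverlap: BandPower) -> np.ndarray:
    """Overlap effect: elementwise overlapping minus non-overlapping."""
    if bp_overlap.channel_names != bp_nonoverlap.channel_names:
        raise ValueError("channel sets do not match")
    if bp_overlap.values.shape != bp_nonoverlap.values.shape:
        raise ValueError("value shapes do not match")
    return bp_overlap.values - bp_nonoverlap.values


def grand_average(items):
    """Unweighted mean across subjects of TFR power arrays or BandPower
    value vectors (inputs must share axes)."""
    items = list(items)
    if not items:
        raise ValueError("cannot average an empty collection")
    if isinstance(items[0], TFR):
        arrays = [x.power for x in items]
    elif isinstance(items[0], BandPower):
        arrays = [x.values for x in items]
    else:
        arrays = [np.asarray(x) for x in items]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("inputs have mismatched shapes")
    return np.mean(arrays, axis=0)
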