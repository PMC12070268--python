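"""Frequency-domain source reconstruction (DICS beamforming).

Condition-wise cross-spectral density (CSD) matrices are estimated in
the 0-1 s post-stimulus window with a single Hanning taper per trial
and averaged over trials and band frequencies.  A common spatial
filter is computed from the combined (trial-weighted) CSD of both
conditions,

    W_v = (L_v' C^-1 L_v)^+  L_v' C^-1,   C = Re(CSD) + lambda mean(diag) I,

with a 5% lambda regularisation by default, and applied to each
condition's CSD to obtain voxel power.  Orientation is handled by
taking the dominant eigenvalue of the 3x3 source CSD (scalar
beamformer output).  Condition contrasts are expressed as relative
power differences (P_over - P_non) / (P_over + P_non), bounded in
[-1, 1].
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.signal.windows import hann

from .synthgen import Epochs, SourceModel
from .timefreq import band_limits


@dataclass
class CSD:
    """Hermitian cross-spectral density matrix for one condition/band."""

    matrix: np.ndarray           # (n_ch, n_ch) complex Hermitian
    band: tuple[float, float]
    condition: str
    n_trials: int
    window_s: tuple[float, float]

    def __post_init__(self):
        m = np.asarray(self.matrix, complex)
        if not np.allclose(m, m.conj().T, atol=1e-10 * max(np.abs(m).max(), 1.0)):
            raise ValueError("CSD must be Hermitian")
        if (np.diag(m).real < -1e-12).any():
            raise ValueError("CSD diagonal must be non-negative")
        self.matrix = m


@dataclass
class SpatialFilterSet:
    """Per-voxel DICS filters (3 orientations x channels)."""

    weights: np.ndarray          # (n_vox, 3, n_ch)
    lambda_frac: float
    rank: int
    band: tuple[float, float]


@dataclass
class SourcePowerMap:
    values: np.ndarray           # (n_vox,) >= 0
    band: tuple[float, float]
    condition: str


@dataclass
class SourceContrastMap:
    """Relative contrast r = (P_over - P_non) / (P_over + P_non);
    voxels where both powers vanish carry NaN."""

    values: np.ndarray
    band: tuple[float, float]


def csd_multitaper(
    epochs: Epochs,
    band,
    window_s: tuple[float, float] = (0.0, 1.0),
) -> CSD:
    """Hanning-tapered CSD averaged over trials and band frequencies."""
    lo, hi = band_limits(band)
    times = epochs.times
    if window_s[0] < times[0] - 1e-9 or window_s[1] > times[-1] + 1e-9:
        raise ValueError("analysis window outside epoch")
    mask = (times >= window_s[0]) & (times <= window_s[1])
    x = epochs.data[:, :, mask]
    n = x.shape[2]
    if n < 2:
        raise ValueError("analysis window too short")
    x = x - x.mean(axis=2, keepdims=True)
    taper = hann(n, sym=False)
    spec = np.fft.rfft(x * taper, axis=2)
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.sfreq)
    bins = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if bins.size == 0:
        raise ValueError(f"no Fourier bins inside band {lo}-{hi} Hz")
    xb = spec[:, :, bins]
    scale = 1.0 / (np.sum(taper**2) * epochs.sfreq)
    csd = np.einsum("tcf,tdf->cd", xb, xb.conj()) * scale / (x.shape[0] * bins.size)
    return CSD(matrix=csd, band=(lo, hi), condition=epochs.condition,
               n_trials=x.shape[0], window_s=window_s)


def combine_csd(csds) -> CSD:
    """Trial-weighted average CSD across conditions (the 'appended
    conditions' CSD used to build the common filter)."""
    csds = list(csds)
    if not csds:
        raise ValueError("no CSDs to combine")
    band = csds[0].band
    if any(c.band != band for c in csds):
        raise ValueError("cannot combine CSDs across bands")
    total = sum(c.n_trials for c in csds)
    m = sum(c.matrix * (c.n_trials / total) for c in csds)
    return CSD(matrix=m, band=band, condition="combined", n_trials=total,
               window_s=csds[0].window_s)


def dics_common_filter(
    csd_combined: CSD,
    model: SourceModel,
    lambda_frac: float = 0.05,
    rank: int = 3,
) -> SpatialFilterSet:
    """Unit-gain DICS filters from the combined-condition CSD.

    ``rank`` is the number of leadfield orientations retained (3 keeps
    the full free-orientation leadfield, the standard choice for EEG);
    ``lambda_frac`` scales the diagonal loading as a fraction of the
    mean sensor power.
    """
    lead = model.leadfields
    if lead.shape[1] != csd_combined.matrix.shape[0]:
        raise ValueError("leadfields and CSD have different channel counts")
    c = csd_combined.matrix.real.copy()
    c += lambda_frac * float(np.mean(np.diag(c))) * np.eye(c.shape[0])
    try:
        cinv = linalg.pinvh(c)
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise ValueError("combined CSD is singular after regularization") from err
    if not (1 <= rank <= 3):
        raise ValueError("rank must be 1, 2 or 3")
    if rank < 3:
        # keep the strongest `rank` orientation components of each leadfield
        u, s, vt = np.linalg.svd(lead, full_matrices=False)
        lead = np.einsum("vcr,vr,vro->vco", u[:, :, :rank], s[:, :rank], vt[:, :rank, :])
    cl = np.einsum("cd,vdo->vco", cinv, lead)                # C^-1 L
    g = np.einsum("vco,vcp->vop", lead, cl)                  # L' C^-1 L
    ginv = np.linalg.pinv(g)
    weights = np.einsum("vop,vcp->voc", ginv, cl)            # (n_vox, 3, n_ch)
    if not np.isfinite(weights).all():
        raise ValueError("non-finite filter weights")
    return SpatialFilterSet(weights=weights, lambda_frac=lambda_frac,
                            rank=rank, band=csd_combined.band)


def source_power(filters: SpatialFilterSet, csd: CSD, normalize: str = "none") -> SourcePowerMap:
    """Per-voxel power w C w^H, orientation-combined by taking the
    dominant eigenvalue of the 3x3 source CSD.

    ``normalize="noise"`` divides by the projected white-noise power
    (neural activity index), removing the depth bias of unit-gain
    beamformer power; raw power (the default) is what enters the
    relative condition contrast, where the bias cancels.
    """
    w = filters.weights
    if w.shape[2] != csd.matrix.shape[0]:
        raise ValueError("filters and CSD have different channel counts")
    s = np.einsum("voc,cd,vpd->vop", w, csd.matrix, w.conj())
    s = (s + np.swapaxes(s.conj(), 1, 2)) / 2.0              # enforce Hermitian
    if normalize == "none":
        vals = np.linalg.eigvalsh(s)[:, -1].real
    elif normalize == "noise":
        noise = np.einsum("voc,vpc->vop", w, w.conj())       # w I w^H
        # generalized problem s x = lambda noise x via noise^-1/2 whitening
        ln = np.linalg.cholesky(noise)
        white = np.linalg.solve(ln, np.swapaxes(np.linalg.solve(ln, s).conj(), 1, 2))
        vals = np.linalg.eigvalsh(white)[:, -1].real
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return SourcePowerMap(values=np.maximum(vals, 0.0), band=csd.band,
                          condition=csd.condition)


def relative_contrast(p_over: SourcePowerMap, p_non: SourcePowerMap) -> SourceContrastMap:
    """Relative power contrast; NaN where both powers are zero."""
    a = np.asarray(p_over.values, float)
    b = np.asarray(p_non.values, float)
    if a.shape != b.shape:
        raise ValueError("voxel sets do not match")
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a - b) / np.where(denom > 0, denom, 1.0), np.nan)
    return SourceContrastMap(values=r, band=p_over.band)
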