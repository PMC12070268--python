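"""Synthetic Go/Nogo study generator.

The study this package analyses has no deposited raw data, so every
downstream stage (preprocessing, wavelet power, cluster permutation
statistics, beamforming, jackknife robustness, behavioural statistics)
is exercised on synthetic material with the statistical structure the
analysis assumes:

* a Go/Nogo task schedule with a 70:30 Go-to-Nogo ratio, two feature
  overlap conditions, and seven equally sized pseudorandomised blocks;
* trial-averaged behavioural outcomes (Go hit rates, Go reaction times,
  Nogo false-alarm rates) for two groups x two overlap conditions with
  a group-by-overlap interaction in the false-alarm rates;
* multichannel EEG epochs built from 1/f background noise plus
  non-phase-locked oscillatory bursts whose theta/alpha/beta amplitude
  differs by condition and group;
* a toy spherical source space with dipole leadfields and a geometric
  atlas parcellation, including reserved "non-labelled" and
  "cerebellar" labels for the masking logic.

All generators are deterministic given a seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

GROUPS = ("NT", "GTS")
CONDITIONS = ("non-overlapping", "overlapping")
TRIAL_TYPES = ("Go", "Nogo")

#: trial counts per overlap condition (70:30 Go-to-Nogo ratio)
N_GO_PER_CONDITION = 196
N_NOGO_PER_CONDITION = 84
STIMULUS_DURATION_MS = 450.0
RESPONSE_DEADLINE_MS = 1700.0
ITI_RANGE_MS = (700.0, 1100.0)

#: frequency range (Hz) that oscillatory effects may occupy
EFFECT_BAND_LIMITS = (3.0, 30.0)


# ---------------------------------------------------------------------------
# task schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    trial_type: str          # "Go" | "Nogo"
    overlap: str             # "non-overlapping" | "overlapping"
    block_index: int         # 1-based
    iti_ms: float

    def __post_init__(self):
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.overlap not in CONDITIONS:
            raise ValueError(f"unknown overlap condition {self.overlap!r}")


@dataclass
class TaskSchedule:
    trials: list[Trial]
    n_blocks: int
    stimulus_duration_ms: float = STIMULUS_DURATION_MS
    response_deadline_ms: float = RESPONSE_DEADLINE_MS

    def counts(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for t in self.trials:
            key = (t.trial_type, t.overlap)
            out[key] = out.get(key, 0) + 1
        return out


def make_task_schedule(seed: int, blocks: int = 7) -> TaskSchedule:
    """Pseudorandomised Go/Nogo schedule.

    Exactly 196 Go and 84 Nogo trials per overlap condition, split over
    `blocks` equally sized blocks with per-block trial-type proportions
    preserved; inter-trial intervals drawn uniformly from 700-1100 ms.
    """
    counts = {
        ("Go", CONDITIONS[0]): N_GO_PER_CONDITION,
        ("Go", CONDITIONS[1]): N_GO_PER_CONDITION,
        ("Nogo", CONDITIONS[0]): N_NOGO_PER_CONDITION,
        ("Nogo", CONDITIONS[1]): N_NOGO_PER_CONDITION,
    }
    for key, n in counts.items():
        if n % blocks:
            raise ValueError(
                f"trial count {n} for {key} not divisible by {blocks} blocks"
            )
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for b in range(1, blocks + 1):
        block_kinds: list[tuple[str, str]] = []
        for key, n in counts.items():
            block_kinds.extend([key] * (n // blocks))
        order = rng.permutation(len(block_kinds))
        itis = rng.uniform(*ITI_RANGE_MS, size=len(block_kinds))
        for j, k in enumerate(order):
            tt, ov = block_kinds[k]
            trials.append(Trial(tt, ov, b, float(itis[j])))
    return TaskSchedule(trials=trials, n_blocks=blocks)


# ---------------------------------------------------------------------------
# behavioural outcomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSpec:
    """Mean and SD of the three behavioural outcomes in one group x
    overlap cell.  Rates are generated from moment-matched Beta
    distributions so that the [0, 1] support is respected even for
    near-floor false-alarm cells; reaction times are Gaussian."""

    fa_rate: tuple[float, float]
    hit_rate: tuple[float, float]
    rt_ms: tuple[float, float]

    def validate(self) -> None:
        for name, (m, s) in (("fa_rate", self.fa_rate), ("hit_rate", self.hit_rate)):
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"{name} mean {m} outside [0, 1]")
            if s < 0:
                raise ValueError(f"{name} SD {s} negative")
        if self.rt_ms[0] <= 0 or self.rt_ms[1] < 0:
            raise ValueError("invalid reaction-time cell")


#: group x overlap cells reproducing the published behavioural means/SDs
DEFAULT_BEHAVIOR_CELLS: dict[tuple[str, str], CellSpec] = {
    ("GTS", "overlapping"): CellSpec(fa_rate=(0.35, 0.13), hit_rate=(0.97, 0.04), rt_ms=(498.0, 49.0)),
    ("GTS", "non-overlapping"): CellSpec(fa_rate=(0.02, 0.03), hit_rate=(0.98, 0.03), rt_ms=(490.0, 46.0)),
    ("NT", "overlapping"): CellSpec(fa_rate=(0.24, 0.08), hit_rate=(0.97, 0.04), rt_ms=(498.0, 49.0)),
    ("NT", "non-overlapping"): CellSpec(fa_rate=(0.01, 0.01), hit_rate=(0.98, 0.03), rt_ms=(490.0, 46.0)),
}


def _draw_rate(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Bounded rate draw: Beta matched to (mean, sd) by moments; falls
    back to a clipped normal when moment matching is infeasible."""
    if sd == 0.0:
        return np.full(size, mean)
    var = sd * sd
    if 0.0 < mean < 1.0 and var < mean * (1.0 - mean):
        nu = mean * (1.0 - mean) / var - 1.0
        return rng.beta(mean * nu, (1.0 - mean) * nu, size=size)
    return np.clip(rng.normal(mean, sd, size=size), 0.0, 1.0)


def simulate_behavior(
    n_per_group: int,
    cells: dict[tuple[str, str], CellSpec] | None = None,
    seed: int | None = None,
):
    """Trial-averaged behavioural table: one row per subject x overlap
    condition with columns subject, group, overlap, hit_rate, rt_ms,
    fa_rate.  Reaction times are correlated within subject (shared
    subject-level speed offset) so that the paired overlap contrast has
    realistic power."""
    import pandas as pd

    cells = dict(DEFAULT_BEHAVIOR_CELLS if cells is None else cells)
    for key in ((g, c) for g in GROUPS for c in CONDITIONS):
        if key not in cells:
            raise ValueError(f"missing cell specification for {key}")
        cells[key].validate()
    rng = np.random.default_rng(seed)
    rows = []
    for group in GROUPS:
        rt_subject = rng.normal(0.0, 25.0, size=n_per_group)  # shared speed offset, ms
        for cond in CONDITIONS:
            spec = cells[(group, cond)]
            fa = _draw_rate(rng, *spec.fa_rate, n_per_group)
            hit = _draw_rate(rng, *spec.hit_rate, n_per_group)
            resid_sd = math.sqrt(max(spec.rt_ms[1] ** 2 - 25.0**2, 1.0))
            rt = spec.rt_ms[0] + rt_subject + rng.normal(0.0, resid_sd, size=n_per_group)
            for i in range(n_per_group):
                rows.append(
                    dict(
                        subject=f"{group}{i + 1:02d}",
                        group=group,
                        overlap=cond,
                        hit_rate=float(hit[i]),
                        rt_ms=float(max(rt[i], 1.0)),
                        fa_rate=float(fa[i]),
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sensor array
# ---------------------------------------------------------------------------

@dataclass
class SensorArray:
    """EEG montage on the unit head sphere."""

    names: list[str]
    positions: np.ndarray  # (n, 3), unit norm

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.names) != len(self.positions):
            raise ValueError("names/positions length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel labels must be unique")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("sensor positions must lie on the unit sphere")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, names) -> np.ndarray:
        lut = {n: i for i, n in enumerate(self.names)}
        return np.array([lut[n] for n in names], dtype=int)


def _sph(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector from polar angle (from vertex) and azimuth
    (0 deg = front, positive = right)."""
    th = math.radians(polar_deg)
    az = math.radians(azimuth_deg)
    return np.array([math.sin(th) * math.sin(az), math.sin(th) * math.cos(az), math.cos(th)])


#: 10-10-style positions of the channels named in the sensor-level results,
#: so synthetic midfrontal theta effects can be seeded at those electrodes
NAMED_CHANNELS: dict[str, tuple[float, float]] = {
    "Cz": (0.0, 0.0),
    "FCz": (18.0, 0.0),
    "FC1": (25.0, -40.0),
    "FC2": (25.0, 40.0),
    "CP1": (25.0, -140.0),
    "CP2": (25.0, 140.0),
    "F2": (36.0, 18.0),
    "FC4": (42.0, 55.0),
}


def make_sensor_array(n_channels: int = 61, max_polar_deg: float = 115.0) -> SensorArray:
    """Equidistant spherical montage with the named electrodes present.

    The eight named 10-10 electrodes are placed at canonical positions
    and the remaining channels fill the head cap (polar angle up to
    ``max_polar_deg``) on a Fibonacci lattice, skipping lattice points
    that collide with a named electrode.  Deterministic.
    """
    if n_channels < len(NAMED_CHANNELS):
        raise ValueError(f"need at least {len(NAMED_CHANNELS)} channels")
    names = list(NAMED_CHANNELS)
    pos = [_sph(*NAMED_CHANNELS[n]) for n in names]
    n_fill = n_channels - len(names)
    # oversampled Fibonacci lattice on the spherical cap
    z_min = math.cos(math.radians(max_polar_deg))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    n_lattice = max(4 * n_fill, 64)
    accepted = 0
    for k in range(n_lattice):
        if accepted == n_fill:
            break
        z = 1.0 - (k + 0.5) * (1.0 - z_min) / n_lattice
        r = math.sqrt(max(1.0 - z * z, 0.0))
        phi = k * golden
        p = np.array([r * math.cos(phi), r * math.sin(phi), z])
        if min(np.linalg.norm(p - q) for q in pos) < 0.22:
            continue
        accepted += 1
        names.append(f"E{accepted:02d}")
        pos.append(p)
    if accepted < n_fill:
        raise RuntimeError("could not place requested number of channels")
    return SensorArray(names=names, positions=np.array(pos))


# ---------------------------------------------------------------------------
# EEG epochs
# ---------------------------------------------------------------------------

@dataclass
class Epochs:
    """Per-subject, per-condition epoched EEG in microvolts.

    data has shape (n_trials, n_channels, n_times); the time axis runs
    from ``tmin`` in steps of 1/sfreq and is symmetric around stimulus
    onset for the generator defaults (-2000..2000 ms).
    """

    subject_id: str
    group: str
    condition: str
    data: np.ndarray
    sfreq: float
    tmin: float
    array: SensorArray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (trials, channels, times)")
        if self.data.shape[1] != len(self.array):
            raise ValueError("channel axis does not match sensor array")

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sfreq

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "Epochs":
        return replace(self, data=self.data.copy())


@dataclass(frozen=True)
class BurstSpec:
    """A band-limited oscillatory burst: Gaussian-windowed sinusoid with
    uniform random phase per trial (non-phase-locked), added at the
    seeded channels with a group/condition dependent amplitude (uV)."""

    band: str
    center_hz: float
    t0_s: float
    sigma_s: float
    channels: tuple[str, ...]
    amplitude: dict[tuple[str, str], float]  # (group, condition) -> uV

    def validate(self) -> None:
        lo, hi = EFFECT_BAND_LIMITS
        if not lo <= self.center_hz <= hi:
            raise ValueError(
                f"burst frequency {self.center_hz} Hz outside {lo}-{hi} Hz"
            )
        for key, a in self.amplitude.items():
            if a < 0:
                raise ValueError(f"negative amplitude for {key}")


@dataclass
class EffectSpec:
    """Full recipe for a synthetic EEG study: background spectrum, burst
    effects, and sampling scale.  The defaults are the desk-scale study
    used throughout the test-suite (12 subjects/group, 40 trials per
    condition, 32 channels at 256 Hz)."""

    bursts: list[BurstSpec] = field(default_factory=list)
    n_subjects: int = 12
    n_trials: int = 40
    sfreq: float = 256.0
    tmin: float = -2.0
    tmax: float = 2.0
    background_exponent: float = 1.0
    noise_scale_uv: float = 10.0   # RMS of the 1/f background
    subject_gain_sd: float = 0.15  # multiplicative between-subject burst gain
    groups: tuple[str, ...] = GROUPS
    conditions: tuple[str, ...] = CONDITIONS
    dtype: str = "float64"         # float32 keeps large simulation studies cheap

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("need at least one subject and one trial")
        if self.tmax <= self.tmin:
            raise ValueError("empty epoch window")
        for b in self.bursts:
            b.validate()

    def null(self) -> "EffectSpec":
        """Copy with every burst amplitude set to zero (conditions
        exchangeable by construction)."""
        bursts = [
            replace(b, amplitude={k: 0.0 for k in b.amplitude})
            for b in self.bursts
        ]
        return replace(self, bursts=bursts)


def default_effect_spec(**overrides) -> EffectSpec:
    """Study conditions emulating the reported sensor-level pattern:
    a midfrontal theta increase and broad alpha/beta decreases for
    overlapping relative to non-overlapping Nogo trials, with a stronger
    theta and weaker alpha modulation in the GTS group and no beta
    modulation in GTS."""
    midfrontal = ("Cz", "FCz", "FC1", "FC2")
    extended = ("Cz", "FCz", "FC1", "FC2", "CP1", "CP2", "F2", "FC4")
    bursts = [
        BurstSpec(
            band="theta", center_hz=5.5, t0_s=0.45, sigma_s=0.18, channels=extended,
            amplitude={
                ("NT", "non-overlapping"): 3.0, ("NT", "overlapping"): 5.0,
                ("GTS", "non-overlapping"): 3.0, ("GTS", "overlapping"): 5.6,
            },
        ),
        BurstSpec(
            band="alpha", center_hz=10.0, t0_s=0.60, sigma_s=0.22, channels=(),  # () = all channels
            amplitude={
                ("NT", "non-overlapping"): 5.0, ("NT", "overlapping"): 2.5,
                ("GTS", "non-overlapping"): 5.0, ("GTS", "overlapping"): 3.5,
            },
        ),
        BurstSpec(
            band="beta", center_hz=22.0, t0_s=0.50, sigma_s=0.18, channels=extended,
            amplitude={
                ("NT", "non-overlapping"): 4.0, ("NT", "overlapping"): 2.4,
                ("GTS", "non-overlapping"): 4.0, ("GTS", "overlapping"): 4.0,
            },
        ),
    ]
    return replace(EffectSpec(bursts=bursts), **overrides)


def one_over_f_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    sfreq: float,
    exponent: float = 1.0,
    rms_uv: float = 10.0,
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to
    1/f**exponent along the last axis, scaled to the requested RMS."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / sfreq)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms * rms_uv


def simulate_epochs(spec: EffectSpec, array: SensorArray, seed: int | None = None) -> list[Epochs]:
    """Generate one Epochs object per subject x condition for all groups.

    Each burst's amplitude is multiplied by a per-subject gain (shared
    across conditions, so the paired condition contrast is stable) and
    enters every trial with an independent uniform phase.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n_times = int(round((spec.tmax - spec.tmin) * spec.sfreq))
    t = spec.tmin + np.arange(n_times) / spec.sfreq
    out: list[Epochs] = []
    for group in spec.groups:
        for s in range(spec.n_subjects):
            sid = f"{group}{s + 1:02d}"
            gains = {
                id(b): max(0.05, 1.0 + rng.normal(0.0, spec.subject_gain_sd))
                for b in spec.bursts
            }
            for cond in spec.conditions:
                data = one_over_f_noise(
                    rng,
                    (spec.n_trials, len(array), n_times),
                    spec.sfreq,
                    spec.background_exponent,
                    spec.noise_scale_uv,
                )
                for b in spec.bursts:
                    amp = b.amplitude.get((group, cond), 0.0) * gains[id(b)]
                    if amp == 0.0:
                        continue
                    ch_idx = (
                        np.arange(len(array))
                        if not b.channels
                        else array.index(b.channels)
                    )
                    env = np.exp(-((t - b.t0_s) ** 2) / (2.0 * b.sigma_s**2))
                    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_trials)
                    burst = amp * env * np.cos(
                        2.0 * np.pi * b.center_hz * (t - b.t0_s)[None, :]
                        + phases[:, None]
                    )
                    data[:, ch_idx, :] += burst[:, None, :]
                out.append(
                    Epochs(
                        subject_id=sid, group=group, condition=cond,
                        data=data.astype(spec.dtype, copy=False),
                        sfreq=spec.sfreq, tmin=spec.tmin, array=array,
                    )
                )
    return out


def simulate_null_epochs(spec: EffectSpec, array: SensorArray, seed: int | None = None) -> list[Epochs]:
    """Effect-free generator: identical to :func:`simulate_epochs` with
    every burst amplitude forced to zero, making the condition labels
    statistically exchangeable."""
    return simulate_epochs(spec.null(), array, seed=seed)


# ---------------------------------------------------------------------------
# toy source model
# ---------------------------------------------------------------------------

#: atlas labels excluded from source-peak localisation
RESERVED_LABELS = ("non-labelled", "cerebellar")


@dataclass
class SourceModel:
    """Regular-grid volumetric source space inside a spherical head.

    Leadfields are free-orientation (channels x 3) dipole gain matrices
    from a current dipole in a homogeneous spherical conductor,
    average-referenced to match average-referenced sensor data.  The
    atlas is a geometric parcellation (octants x depth shells) with the
    two reserved labels required by the masking stage.
    """

    positions: np.ndarray    # (n_vox, 3) mm, inside voxels only
    spacing_mm: float
    leadfields: np.ndarray   # (n_vox, n_channels, 3)
    labels: np.ndarray       # (n_vox,) str
    array: SensorArray
    head_radius_mm: float

    @property
    def n_voxels(self) -> int:
        return len(self.positions)


def make_source_model(
    grid_spacing_mm: float = 5.0,
    array: SensorArray | None = None,
    seed: int | None = None,
    head_radius_mm: float = 85.0,
    brain_radius_mm: float = 72.0,
) -> SourceModel:
    """Toy volumetric source model (deterministic; the seed is accepted
    for interface symmetry with the other generators)."""
    if grid_spacing_mm <= 0:
        raise ValueError("grid spacing must be positive")
    if array is None:
        array = make_sensor_array()
    ax = np.arange(-brain_radius_mm, brain_radius_mm + grid_spacing_mm / 2, grid_spacing_mm)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    r = np.linalg.norm(pos, axis=1)
    inside = (r <= brain_radius_mm) & (pos[:, 2] >= -0.75 * brain_radius_mm)
    pos = pos[inside]
    r = r[inside]

    sensors_mm = array.positions * head_radius_mm
    # current dipole in a homogeneous conductor: phi(e) = q . (e - v) / (4 pi sigma |e - v|^3)
    diff = sensors_mm[None, :, :] - pos[:, None, :]          # (n_vox, n_ch, 3)
    dist = np.linalg.norm(diff, axis=2, keepdims=True)
    lead = diff / (4.0 * np.pi * 0.33e-3 * dist**3)
    lead -= lead.mean(axis=1, keepdims=True)                 # average reference

    labels = np.empty(len(pos), dtype=object)
    deep = r < 0.33 * brain_radius_mm
    cereb = (pos[:, 2] < -0.45 * brain_radius_mm) & (pos[:, 1] < 0)
    octant = (
        (pos[:, 0] >= 0).astype(int)
        + 2 * (pos[:, 1] >= 0).astype(int)
        + 4 * (pos[:, 2] >= 0).astype(int)
    )
    shell = np.where(r < 0.66 * brain_radius_mm, "deep", "superficial")
    for i in range(len(pos)):
        if cereb[i]:
            labels[i] = "cerebellar"
        elif deep[i]:
            labels[i] = "non-labelled"
        else:
            labels[i] = f"parcel-{octant[i]}-{shell[i]}"
    return SourceModel(
        positions=pos, spacing_mm=float(grid_spacing_mm),
        leadfields=lead, labels=labels.astype(str), array=array,
        head_radius_mm=head_radius_mm,
    )


def simulate_dipole_epochs(
    model: SourceModel,
    voxel: int,
    freq_hz: float,
    snr: float,
    orientation: np.ndarray | None = None,
    n_trials: int = 60,
    duration_s: float = 1.0,
    sfreq: float = 256.0,
    seed: int | None = None,
    condition: str = "active",
    amplitude: float = 1.0,
) -> Epochs:
    """Sensor epochs from a single oscillating dipole plus white sensor
    noise, for beamformer localisation tests.

    ``snr`` is the amplitude SNR (RMS unit-amplitude signal to RMS
    noise at the strongest channel); ``amplitude`` scales only the
    dipole moment, leaving the noise floor fixed, so condition pairs
    with different amplitudes share a common noise level.
    """
    rng = np.random.default_rng(seed)
    if orientation is None:
        orientation = np.array([0.0, 0.0, 1.0])
    orientation = np.asarray(orientation, float)
    orientation = orientation / np.linalg.norm(orientation)
    gain = model.leadfields[voxel] @ orientation          # (n_ch,)
    n = int(round(duration_s * sfreq)) + 1                # inclusive end point
    t = np.arange(n) / sfreq
    phases = rng.uniform(0, 2 * np.pi, size=n_trials)
    s = np.cos(2 * np.pi * freq_hz * t[None, :] + phases[:, None])  # (trials, n)
    sig = amplitude * gain[None, :, None] * s[:, None, :]
    sig_rms = np.abs(gain).max() / math.sqrt(2.0)
    noise = rng.standard_normal(sig.shape) * (sig_rms / snr)
    return Epochs(
        subject_id="dipole", group="sim", condition=condition,
        data=sig + noise, sfreq=sfreq, tmin=0.0, array=model.array,
    )
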