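"""Synthetic ECG waveforms and low-rate monitor "numerics" streams.

The generators stand in for one-minute excerpts of PhysioNet-style bedside
recordings: a 250 Hz single-lead ECG stored as (time s, voltage mV) pairs,
and numerics channels (SpO2, heart rate, arterial/pulmonary/non-invasive
pressures) sampled every 1.024 s.  Every ECG is built as a train of Gaussian
wave components (P, Q, R, S, T) per cardiac cycle plus an optional smooth
ST-segment plateau, so the true R times, Q/S trough times and ST offset are
known exactly and are attached to the record as ground truth for testing the
feature extractor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import IO, Mapping, Sequence

import numpy as np

__all__ = [
    "WaveComponent",
    "ECGMorphologyParams",
    "ECGClassProfile",
    "WaveformRecord",
    "NumericsRecord",
    "NUMERICS_CHANNELS",
    "PROFILE_NAMES",
    "synthesize_ecg",
    "synthesize_numerics",
    "class_profile",
    "write_waveform_text",
    "read_waveform_text",
    "write_numerics_csv",
]

#: Channel names a numerics record may carry (printed units: %, bpm, mmHg).
NUMERICS_CHANNELS = (
    "SpO2",
    "HR",
    "ABP Sys",
    "ABP Dias",
    "PAP Sys",
    "PAP Dias",
    "NBP Sys",
    "NBP Dias",
)


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian deflection of the cardiac cycle.

    ``center`` is the offset in seconds of the wave apex relative to the R
    apex of the same cycle; ``width`` is the Gaussian standard deviation.
    """

    amplitude: float  # mV, signed
    center: float  # s relative to R
    width: float  # s, > 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"width must be positive, got {self.width}")


@dataclass(frozen=True)
class ECGMorphologyParams:
    """Morphology of one synthetic ECG class.

    The R wave must dominate the Q and S troughs in magnitude so that the
    cycle maximum is the R apex.  ``st_offset`` lifts the segment between the
    S trough and the T wave by a constant plateau (mV); ``noise_sd`` adds
    white Gaussian noise.
    """

    heart_rate: float  # beats / min
    p: WaveComponent
    q: WaveComponent
    r: WaveComponent
    s: WaveComponent
    t: WaveComponent
    st_offset: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError(f"heart_rate must be positive, got {self.heart_rate}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.r.amplitude <= abs(self.q.amplitude) or self.r.amplitude <= abs(
            self.s.amplitude
        ):
            raise ValueError(
                "R amplitude must exceed |Q| and |S| amplitudes so the R apex "
                "is the cycle maximum"
            )

    @property
    def qrs_width(self) -> float:
        """True Q-trough to S-trough spacing in seconds."""
        return self.s.center - self.q.center


@dataclass(frozen=True)
class ECGClassProfile:
    """Printed feature targets for one ECG class of the triage table."""

    name: str
    target_peaks: int | None
    target_qrs_width: float | None  # s
    target_st_elevated: bool | None
    target_pp_label: str
    target_heart_rate: float | None  # bpm, only fixed for the HR-110 class
    excerpt_duration: float  # s of signal analysed to yield target_peaks
    peaks_cell: str  # value printed in the "Peaks" column
    qrs_cell: str
    st_cell: str


@dataclass
class WaveformRecord:
    """Uniformly sampled (t, v) signal; t in seconds, v in millivolts.

    Sampling starts at t = 0 with constant step 1/fs; the sample count is
    ``round(duration * fs)``.
    """

    record_id: str
    fs: float
    duration: float
    v: np.ndarray
    ground_truth: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.v.size) / self.fs

    @property
    def n_samples(self) -> int:
        return int(self.v.size)

    def samples(self) -> np.ndarray:
        """The two-column (t, v) array form."""
        return np.column_stack([self.t, self.v])


@dataclass
class NumericsRecord:
    """Low-rate numerics channels sampled every ``interval`` seconds."""

    record_id: str
    interval: float
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError(f"interval must be positive, got {self.interval}")
        lengths = {name: len(v) for name, v in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channels differ in length: {lengths}")

    @property
    def times(self) -> np.ndarray:
        n = len(next(iter(self.channels.values()))) if self.channels else 0
        return np.arange(n) * self.interval

    @property
    def implied_fs(self) -> float:
        """Sampling frequency in Hz, rounded half-up to 6 decimal places.

        A 1.024 s interval reports 0.976563 Hz.
        """
        hz = Decimal(1) / Decimal(repr(self.interval))
        return float(hz.quantize(Decimal("0.000001"), rounding=ROUND_HALF_UP))


def _smoothstep(t: np.ndarray, edge: float, scale: float = 0.005) -> np.ndarray:
    # logistic ramp; ~0 below the edge, ~1 above, 10 ms transition
    z = np.clip((t - edge) / scale, -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(-z))


def synthesize_ecg(
    params: ECGMorphologyParams,
    duration: float = 60.0,
    fs: float = 250.0,
    record_id: str = "synthetic",
) -> WaveformRecord:
    """Render a Gaussian-wave ECG train.

    Beats are placed at ``(k + 1/2) * T`` for cycle length ``T = 60 /
    heart_rate`` so every beat has a complete cycle around it.  Deterministic
    for a fixed ``params.seed``.  The returned record's ``ground_truth``
    holds the true R times, Q/S trough times, QRS width and ST offset.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")

    n = round(duration * fs)
    t = np.arange(n) / fs
    v = np.zeros(n)

    cycle = 60.0 / params.heart_rate
    n_beats = math.floor(duration / cycle + 1e-9)
    r_times = (np.arange(n_beats) + 0.5) * cycle

    waves = (params.p, params.q, params.r, params.s, params.t)
    for rt in r_times:
        u = t - rt
        for w in waves:
            if w.amplitude != 0.0:
                v += w.amplitude * np.exp(-((u - w.center) ** 2) / (2 * w.width**2))
        if params.st_offset != 0.0:
            lo = params.s.center + 2 * params.s.width
            hi = params.t.center - 2 * params.t.width
            v += params.st_offset * _smoothstep(u, lo) * _smoothstep(-u, -hi)

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        v += rng.normal(0.0, params.noise_sd, n)

    truth = {
        "r_times": r_times,
        "q_times": r_times + params.q.center,
        "s_times": r_times + params.s.center,
        "qrs_width": params.qrs_width,
        "st_offset": params.st_offset,
    }
    return WaveformRecord(record_id=record_id, fs=fs, duration=duration, v=v, ground_truth=truth)


def synthesize_numerics(
    channel_specs: Mapping[str, object],
    duration: float = 60.0,
    interval: float = 1.024,
    record_id: str = "synthetic-numerics",
    seed: int = 0,
) -> NumericsRecord:
    """Generate a numerics record with ``floor(duration/interval) + 1`` samples.

    Each spec is a constant, a ``(mean, sd)`` pair / ``{"mean": m, "sd": s}``
    mapping for Gaussian samples, or an explicit value sequence of the right
    length.  Channel names must come from :data:`NUMERICS_CHANNELS`.
    """
    if interval <= 0:
        raise ValueError(f"interval must be positive, got {interval}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    unknown = set(channel_specs) - set(NUMERICS_CHANNELS)
    if unknown:
        raise ValueError(
            f"unknown channel name(s) {sorted(unknown)}; "
            f"allowed: {list(NUMERICS_CHANNELS)}"
        )

    n = math.floor(duration / interval) + 1
    rng = np.random.default_rng(seed)
    channels: dict[str, np.ndarray] = {}
    for name, spec in channel_specs.items():
        if isinstance(spec, Mapping):
            vals = rng.normal(float(spec["mean"]), float(spec.get("sd", 0.0)), n)
        elif isinstance(spec, (int, float)):
            vals = np.full(n, float(spec))
        elif isinstance(spec, tuple) and len(spec) == 2:
            vals = rng.normal(float(spec[0]), float(spec[1]), n)
        else:
            vals = np.asarray(spec, dtype=float)
            if vals.size != n:
                raise ValueError(
                    f"channel {name!r}: sequence of length {vals.size}, expected {n}"
                )
        channels[name] = vals
    return NumericsRecord(record_id=record_id, interval=interval, channels=channels)


def _morphology(
    heart_rate: float,
    qrs_width: float,
    st_offset: float,
    r_amp: float = 1.2,
    qs_amp: float = 0.35,
) -> ECGMorphologyParams:
    """Shape a cycle whose extractable QRS width equals ``qrs_width``.

    Q and S troughs sit at -/+ half the width; trough Gaussians are kept
    narrow relative to the half-width so the R tail shifts them by less than
    one sample at 250 Hz.
    """
    half = qrs_width / 2.0
    b_qs = max(qrs_width / 10.0, 0.006)
    b_r = max(qrs_width / 8.0, 0.009)
    c_t = half + 0.22
    return ECGMorphologyParams(
        heart_rate=heart_rate,
        p=WaveComponent(0.10, -(half + 0.16), 0.02),
        q=WaveComponent(-qs_amp, -half, b_qs),
        r=WaveComponent(r_amp, 0.0, b_r),
        s=WaveComponent(-qs_amp, half, b_qs),
        t=WaveComponent(0.25, c_t, 0.025),
        st_offset=st_offset,
    )


def _profiles() -> dict[str, tuple[ECGClassProfile, ECGMorphologyParams]]:
    # Printed targets per class block: (peaks, QRS s, ST elevated, heart rate,
    # excerpt s).  The excerpt length is what makes the small printed peak
    # counts recoverable: peaks = excerpt * HR / 60.
    spec = {
        "sleep_apnea": (6, 0.06, True, 60.0, 6.0),
        "arrhythmia_wide": (5, 0.5, False, 50.0, 6.0),
        "arrhythmia_narrow": (7, 0.047, True, 70.0, 6.0),
        "heart_failure": (6, 0.169, False, 60.0, 6.0),
    }
    out: dict[str, tuple[ECGClassProfile, ECGMorphologyParams]] = {}
    for name, (peaks, width, st, hr, excerpt) in spec.items():
        profile = ECGClassProfile(
            name=name,
            target_peaks=peaks,
            target_qrs_width=width,
            target_st_elevated=st,
            target_pp_label="Regular",
            target_heart_rate=None,
            excerpt_duration=excerpt,
            peaks_cell=str(peaks),
            qrs_cell=f"{width:g}",
            st_cell="true" if st else "false",
        )
        params = _morphology(hr, width, 0.2 if st else 0.0)
        out[name] = (profile, params)

    # healthy reference signals: printed cells collapse to a "normal" marker
    # (or the numeric heart rate for the HR-110 block)
    out["normal"] = (
        ECGClassProfile(
            name="normal",
            target_peaks=None,
            target_qrs_width=None,
            target_st_elevated=False,
            target_pp_label="Regular",
            target_heart_rate=None,
            excerpt_duration=60.0,
            peaks_cell="normal",
            qrs_cell="",
            st_cell="",
        ),
        _morphology(75.0, 0.08, 0.0),
    )
    out["normal_hr110"] = (
        ECGClassProfile(
            name="normal_hr110",
            target_peaks=110,
            target_qrs_width=0.08,
            target_st_elevated=False,
            target_pp_label="Regular",
            target_heart_rate=110.0,
            excerpt_duration=60.0,
            peaks_cell="110",
            qrs_cell="",
            st_cell="",
        ),
        _morphology(110.0, 0.08, 0.0),
    )
    return out


_PROFILES = _profiles()

#: Names accepted by :func:`class_profile`.
PROFILE_NAMES = tuple(_PROFILES)


def class_profile(name: str) -> tuple[ECGClassProfile, ECGMorphologyParams]:
    """Printed feature targets and matching morphology for an ECG class."""
    try:
        profile, params = _PROFILES[name]
    except KeyError:
        raise ValueError(
            f"unknown profile {name!r}; valid profiles: {list(_PROFILES)}"
        ) from None
    return profile, replace(params)


# ----------------------------------------------------------------------------
# plain-text signal I/O: one header line, then t<TAB>v per sample


def write_waveform_text(record: WaveformRecord, fh: IO[str]) -> None:
    fh.write(f"# record_id={record.record_id} fs={record.fs:g}\n")
    for ti, vi in zip(record.t, record.v):
        fh.write(f"{ti:.6f}\t{vi:.6f}\n")


def read_waveform_text(fh: IO[str]) -> WaveformRecord:
    header = fh.readline().strip()
    if not header.startswith("#"):
        raise ValueError("missing header line '# record_id=<id> fs=<Hz>'")
    meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
    fs = float(meta["fs"])
    v = [float(line.split("\t")[1]) for line in fh if line.strip()]
    arr = np.asarray(v)
    return WaveformRecord(
        record_id=meta.get("record_id", "unknown"),
        fs=fs,
        duration=arr.size / fs,
        v=arr,
    )


def write_numerics_csv(record: NumericsRecord, fh: IO[str]) -> None:
    names = list(record.channels)
    fh.write(",".join(["t"] + names) + "\n")
    times = record.times
    for i, ti in enumerate(times):
        row = [f"{ti:.3f}"] + [f"{record.channels[c][i]:g}" for c in names]
        fh.write(",".join(row) + "\n")
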