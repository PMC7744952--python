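"""ECG fiducial-point detection and feature extraction.

The algorithm follows the classic split-and-sort recipe: the record is
re-centred on its baseline ("zero line"), split into cardiac cycles around
the dominant deflections, and within each cycle the R apex is the maximum of
the upper half, while Q and S are the deepest troughs in bounded windows to
the left and right of R.  Per-record features are the peak count, the QRS
width (Q-to-S trough spacing), ST elevation past the S point, and the
regularity of the R-R (peak-to-peak) intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
from scipy.signal import find_peaks

from .waveform import WaveformRecord

__all__ = [
    "CycleSegment",
    "FiducialPoints",
    "ECGFeatureVector",
    "split_cycles",
    "locate_r",
    "locate_qs",
    "qrs_width",
    "st_elevation",
    "extract_features",
    "write_features_csv",
]

#: Coefficient-of-variation bound below which R-R intervals count as Regular.
RR_REGULAR_CV = 0.10
#: ST elevation call threshold, mV (standard clinical convention).
ST_THRESHOLD = 0.1
#: ST measurement window after the S trough, seconds.
ST_WINDOW = (0.04, 0.08)
#: Half-width of the Q/S trough search window around R, seconds.
QS_WINDOW = 0.3
#: Minimum R-R spacing enforced during peak detection, seconds.
MIN_RR = 0.2


@dataclass
class CycleSegment:
    """One cardiac cycle: a (t, v) slice plus the record baseline."""

    t: np.ndarray
    v: np.ndarray
    baseline: float

    @property
    def up_half(self) -> np.ndarray:
        """Indices of samples on or above the baseline."""
        return np.flatnonzero(self.v - self.baseline >= 0)

    @property
    def down_half(self) -> np.ndarray:
        """Indices of samples below the baseline."""
        return np.flatnonzero(self.v - self.baseline < 0)


@dataclass(frozen=True)
class FiducialPoints:
    q: tuple[float, float]
    r: tuple[float, float]
    s: tuple[float, float]
    st_measure_point: tuple[float, float]


@dataclass(frozen=True)
class ECGFeatureVector:
    """Record-level summary in the triage table's feature vocabulary."""

    peaks: int
    qrs_width: float | None  # s, median over cycles; None without any QRS
    pp_label: str  # "Regular" | "Irregular"
    pp_interval: float | None  # s, mean R-R; None with < 2 peaks
    st_magnitude: float | None  # mV above baseline
    st_elevated: bool | None
    heart_rate: float  # beats/min over the record duration


def split_cycles(record: WaveformRecord, min_rr: float = MIN_RR) -> list[CycleSegment]:
    """Segment a record into cycles around its dominant deflections.

    The baseline is the record median; candidate beats are local maxima of
    the re-centred signal above half its global maximum, at least ``min_rr``
    apart.  Cycle boundaries are midpoints between successive beats, so the
    cycles tile the record.  A flat record yields no cycles.
    """
    v = np.asarray(record.v, dtype=float)
    if v.size == 0:
        return []
    baseline = float(np.median(v))
    x = v - baseline
    vmax = x.max()
    if vmax <= 0:
        return []
    distance = max(1, int(round(min_rr * record.fs)))
    peaks, _ = find_peaks(x, height=0.5 * vmax, distance=distance)
    if peaks.size == 0:
        return []
    bounds = np.concatenate(
        [[0], ((peaks[:-1] + peaks[1:]) // 2 + 1), [v.size]]
    )
    t = record.t
    return [
        CycleSegment(t=t[a:b], v=v[a:b], baseline=baseline)
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def locate_r(cycle: CycleSegment) -> tuple[float, float]:
    """R apex: the maximum-voltage sample of the cycle's upper half.

    Ties resolve to the earliest sample.  Raises if the cycle never reaches
    the baseline ("no R wave in cycle").
    """
    up = cycle.up_half
    if up.size == 0:
        raise ValueError("no R wave in cycle: upper half is empty")
    i = up[int(np.argmax(cycle.v[up]))]
    return float(cycle.t[i]), float(cycle.v[i])


def locate_qs(
    cycle: CycleSegment,
    r: tuple[float, float],
    window: float = QS_WINDOW,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Q and S troughs: windowed minima left and right of the R apex.

    The search spans ``window`` seconds on each side of R, clipped to the
    cycle bounds; ties resolve to the earliest sample.
    """
    rt = r[0]
    left = np.flatnonzero((cycle.t >= rt - window) & (cycle.t < rt))
    right = np.flatnonzero((cycle.t > rt) & (cycle.t <= rt + window))
    if left.size == 0 or right.size == 0:
        raise ValueError("degenerate cycle: no samples on one side of R")
    qi = left[int(np.argmin(cycle.v[left]))]
    si = right[int(np.argmin(cycle.v[right]))]
    q = (float(cycle.t[qi]), float(cycle.v[qi]))
    s = (float(cycle.t[si]), float(cycle.v[si]))
    return q, s


def qrs_width(q: tuple[float, float], s: tuple[float, float]) -> float:
    """QRS width in seconds: S-trough time minus Q-trough time."""
    if q[0] > s[0]:
        raise ValueError(f"Q time {q[0]} exceeds S time {s[0]}")
    return s[0] - q[0]


def st_elevation(
    cycle: CycleSegment,
    s: tuple[float, float],
    window: tuple[float, float] = ST_WINDOW,
    threshold: float = ST_THRESHOLD,
) -> tuple[float, bool]:
    """ST elevation after the S trough.

    Returns the mean voltage over the ``window`` (seconds after S) relative
    to the baseline, and whether it reaches ``threshold`` mV.
    """
    lo, hi = s[0] + window[0], s[0] + window[1]
    idx = np.flatnonzero((cycle.t >= lo) & (cycle.t <= hi))
    if idx.size == 0:
        raise ValueError("truncated cycle: no samples in the ST window")
    magnitude = float(np.mean(cycle.v[idx]) - cycle.baseline)
    return magnitude, magnitude >= threshold


def extract_features(record: WaveformRecord) -> ECGFeatureVector:
    """Full feature vector for one record.

    Peak count is the number of cycles with an R apex; QRS width and ST
    magnitude are medians over the cycles that yield them; the peak-to-peak
    label is Regular when the R-R coefficient of variation stays below
    ``RR_REGULAR_CV`` (fewer than two peaks count as Regular); heart rate is
    the peak count scaled to beats per minute over the record duration.
    """
    cycles = split_cycles(record)
    r_times: list[float] = []
    widths: list[float] = []
    st_mags: list[float] = []
    for cyc in cycles:
        try:
            r = locate_r(cyc)
        except ValueError:
            continue
        r_times.append(r[0])
        try:
            q, s = locate_qs(cyc, r)
            widths.append(qrs_width(q, s))
            mag, _ = st_elevation(cyc, s)
            st_mags.append(mag)
        except ValueError:
            continue

    peaks = len(r_times)
    if peaks >= 2:
        rr = np.diff(r_times)
        pp_interval = float(np.mean(rr))
        cv = float(np.std(rr) / np.mean(rr))
        pp_label = "Regular" if cv < RR_REGULAR_CV else "Irregular"
    else:
        pp_interval = None
        pp_label = "Regular"

    qrs = float(np.median(widths)) if widths else None
    if st_mags:
        st_mag = float(np.median(st_mags))
        st_flag = st_mag >= ST_THRESHOLD
    else:
        st_mag, st_flag = None, None
    heart_rate = peaks * 60.0 / record.duration
    return ECGFeatureVector(
        peaks=peaks,
        qrs_width=qrs,
        pp_label=pp_label,
        pp_interval=pp_interval,
        st_magnitude=st_mag,
        st_elevated=st_flag,
        heart_rate=heart_rate,
    )


def write_features_csv(rows: Sequence[tuple[str, ECGFeatureVector]], fh: IO[str]) -> None:
    """Emit feature vectors with the triage table's ECG column names."""
    fh.write("Record,Peaks,QRS width,Peak to Peak,ST El.,Heart Rate\n")
    for record_id, fv in rows:
        qrs = f"{fv.qrs_width:g}" if fv.qrs_width is not None else ""
        st = "" if fv.st_elevated is None else str(fv.st_elevated).lower()
        fh.write(
            f"{record_id},{fv.peaks},{qrs},{fv.pp_label},{st},{fv.heart_rate:g}\n"
        )
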