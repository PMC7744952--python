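"""Summarise numerics records into vital-feature rows.

Each monitor channel collapses to the rounded mean of its valid samples.
Two missing-value codes mirror the source tables: a channel the monitor
never recorded is ABSENT (printed "x"), while a channel that is present but
holds no valid sample reports ZERO (printed 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np

from .waveform import NUMERICS_CHANNELS, NumericsRecord

__all__ = ["VitalFeatureRow", "VITALS_HEADER", "summarize_numerics", "write_vitals_csv"]

#: Printed header order of the vital-features table.
VITALS_HEADER = (
    "Record",
    "Spo2 level",
    "Heart Rates (HR)",
    "ABP Sys",
    "ABP Dias",
    "PAP Sys",
    "PAP Dias",
    "NBP Sys",
    "NBP Dias",
)

_FIELD_TO_CHANNEL = {
    "spo2_level": "SpO2",
    "hr": "HR",
    "abp_sys": "ABP Sys",
    "abp_dias": "ABP Dias",
    "pap_sys": "PAP Sys",
    "pap_dias": "PAP Dias",
    "nbp_sys": "NBP Sys",
    "nbp_dias": "NBP Dias",
}


@dataclass(frozen=True)
class VitalFeatureRow:
    """One summarised patient row; ``None`` fields are ABSENT ("x")."""

    record_id: str
    spo2_level: int | None
    hr: int | None
    abp_sys: int | None
    abp_dias: int | None
    pap_sys: int | None
    pap_dias: int | None
    nbp_sys: int | None
    nbp_dias: int | None

    def printed(self) -> list[str]:
        cells = [self.record_id]
        for name in _FIELD_TO_CHANNEL:
            val = getattr(self, name)
            cells.append("x" if val is None else str(val))
        return cells


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def _valid(samples: np.ndarray, spo2: bool) -> np.ndarray:
    mask = np.isfinite(samples) & (samples >= 0)
    if spo2:
        mask &= samples <= 100
    return samples[mask]


def summarize_numerics(record: NumericsRecord) -> VitalFeatureRow:
    """Collapse every present channel to the rounded mean of valid samples.

    Valid means finite and non-negative (SpO2 additionally at most 100 %).
    Channels not in the record become ABSENT; a present channel with no
    valid sample reports 0.
    """
    if not record.channels:
        raise ValueError("empty numerics record: no channels")
    values: dict[str, int | None] = {}
    for field, channel in _FIELD_TO_CHANNEL.items():
        if channel not in record.channels:
            values[field] = None
            continue
        good = _valid(np.asarray(record.channels[channel], dtype=float), channel == "SpO2")
        values[field] = 0 if good.size == 0 else _round_half_up(float(good.mean()))
    return VitalFeatureRow(record_id=record.record_id, **values)


def write_vitals_csv(rows: Sequence[VitalFeatureRow], fh: IO[str]) -> None:
    """Emit rows under the printed header order."""
    fh.write(",".join(VITALS_HEADER) + "\n")
    for row in rows:
        fh.write(",".join(row.printed()) + "\n")
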