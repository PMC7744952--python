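"""Orchestrate generation, extraction, enumeration and classification.

The builder turns a declarative configuration — which ECG class blocks to
emit, with which vitals combinations and which symptom enumeration order —
into the two output tables: the 143-row symptom-by-vitals enumeration and
the 580-row, 11-feature triage dataset.  The shipped default configuration
transcribes the source design, and building with it reproduces the packaged
fixtures cell for cell; ``validate`` diffs any build against a fixture.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Mapping, Sequence

from . import ecg, waveform
from .triage import (
    DecisionModel,
    PatientFeatureVector,
    SymptomVector,
    TriageTable,
    VitalBlock,
    induce_decision_model,
    load_table6,
    symptom_sequence,
)

__all__ = [
    "SegmentSpec",
    "DatasetConfig",
    "OutputTable",
    "ValidationReport",
    "load_config",
    "default_config",
    "build_triage_dataset",
    "build_enumeration_table",
    "fixture_table",
    "validate",
    "verify_class_profiles",
]

log = logging.getLogger(__name__)

TABLE6_COLUMNS = (
    "p_no",
    "ecg_class",
    "spo2",
    "bp_high",
    "bp_low",
    "chest_pain",
    "short_breath",
    "palpitation",
    "at_rest",
    "peaks",
    "qrs_width",
    "pp",
    "st",
    "triage",
)
TABLE5_COLUMNS = (
    "patient",
    "chest_pain",
    "short_breath",
    "palpitation",
    "at_rest",
    "spo2",
    "bp_high_printed",
    "bp_low_printed",
)

#: Printed headers for CSV emission, in the source tables' column order.
PRINTED_HEADERS = {
    "table6": (
        "p. no.",
        "ECG Records",
        "Spo2",
        "H. Blood(mHg)",
        "L. Blood(mHg)",
        "Chest Pain",
        "Short-ness of Breath",
        "Palpitation",
        "rest?",
        "Peaks",
        "QRS width",
        "Peak to Peak",
        "ST El.",
        "Output Triage level",
    ),
    "table5": (
        "Patient number",
        "Chest pain",
        "Shortness of Breath",
        "Palpitation.",
        "Patient at rest",
        "SpO2 Value",
        "High Blood Pressure (Bp) Value (mHg)",
        "Low Blood Pressure (Bp) Value (mHg)",
    ),
}


@dataclass(frozen=True)
class SegmentSpec:
    """A run of triage-table rows: one ECG class, one vitals block, and a
    symptom sequence (a named enumeration order or an explicit list)."""

    ecg_class: str
    spo2: int
    bp_high: int
    bp_low: int
    symptoms: tuple[SymptomVector, ...]

    @classmethod
    def from_dict(cls, d: Mapping) -> "SegmentSpec":
        sym = d["symptoms"]
        if "explicit" in sym:
            seq = tuple(
                SymptomVector(*(c == "Y" for c in code)) for code in sym["explicit"]
            )
        else:
            seq = tuple(symptom_sequence(sym["order"], sym.get("count", 16)))
        return cls(
            ecg_class=d["ecg_class"],
            spo2=int(d["spo2"]),
            bp_high=int(d["bp_high"]),
            bp_low=int(d["bp_low"]),
            symptoms=seq,
        )


@dataclass
class DatasetConfig:
    """Declarative build plan for both output tables."""

    table6_segments: list[SegmentSpec]
    label_overrides: dict[int, str] = field(default_factory=dict)
    table5_blocks: list[dict] = field(default_factory=list)
    table5_order: str = "chest_pain_lsb"
    strict_conflicts: bool = False

    @classmethod
    def from_dict(cls, d: Mapping) -> "DatasetConfig":
        t6 = d.get("table6", {})
        t5 = d.get("table5", {})
        return cls(
            table6_segments=[SegmentSpec.from_dict(s) for s in t6.get("segments", [])],
            label_overrides={int(k): v for k, v in t6.get("label_overrides", {}).items()},
            table5_blocks=list(t5.get("blocks", [])),
            table5_order=t5.get("order", "chest_pain_lsb"),
            strict_conflicts=bool(d.get("strict_conflicts", False)),
        )


def load_config(fh: IO[str]) -> DatasetConfig:
    return DatasetConfig.from_dict(json.load(fh))


def default_config() -> DatasetConfig:
    """The shipped configuration transcribing the source enumeration design."""
    text = resources.files("triagesim.data").joinpath("default_config.json").read_text()
    return DatasetConfig.from_dict(json.loads(text))


@dataclass
class OutputTable:
    schema_id: str  # "table5" | "table6"
    columns: tuple[str, ...]
    rows: list[list[str]]

    def to_csv(self, fh: IO[str], printed_header: bool = False) -> None:
        header = PRINTED_HEADERS[self.schema_id] if printed_header else self.columns
        fh.write(",".join(header) + "\n")
        for row in self.rows:
            fh.write(",".join(row) + "\n")


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def build_triage_dataset(
    config: DatasetConfig,
    model: DecisionModel | None = None,
    table: TriageTable | None = None,
) -> OutputTable:
    """Emit the triage dataset for a configuration.

    Feature cells per row come from the class profile's printed targets;
    the outcome column comes from the decision model (induced from the
    packaged table unless supplied).  Positional label overrides in the
    config preserve rows whose printed label loses a duplicate-vector
    conflict.  Fully deterministic.
    """
    if model is None:
        if table is None:
            table = load_table6()
        model = induce_decision_model(
            table, on_conflict="error" if config.strict_conflicts else "first"
        )
    profiles = {}
    for seg in config.table6_segments:
        if seg.ecg_class not in profiles:
            profiles[seg.ecg_class] = waveform.class_profile(seg.ecg_class)[0]

    rows: list[list[str]] = []
    p_no = 0
    for seg in config.table6_segments:
        prof = profiles[seg.ecg_class]
        for sym in seg.symptoms:
            p_no += 1
            vector = PatientFeatureVector(
                spo2=seg.spo2,
                bp_high=seg.bp_high,
                bp_low=seg.bp_low,
                chest_pain=sym.chest_pain,
                shortness_of_breath=sym.shortness_of_breath,
                palpitation=sym.palpitation,
                at_rest=sym.at_rest,
                peaks=prof.peaks_cell,
                qrs_width=prof.qrs_cell,
                pp=prof.target_pp_label,
                st=prof.st_cell,
            )
            if p_no in config.label_overrides:
                label = config.label_overrides[p_no]
            else:
                level, _ = model.classify(vector)
                label = level.printed
            rows.append(
                [
                    str(p_no),
                    seg.ecg_class,
                    str(seg.spo2),
                    str(seg.bp_high),
                    str(seg.bp_low),
                    _fmt_bool(sym.chest_pain),
                    _fmt_bool(sym.shortness_of_breath),
                    _fmt_bool(sym.palpitation),
                    _fmt_bool(sym.at_rest),
                    prof.peaks_cell,
                    prof.qrs_cell,
                    prof.target_pp_label,
                    prof.st_cell,
                    label,
                ]
            )
    log.info(
        "build_triage_dataset: %d segments -> %d rows (%d overridden)",
        len(config.table6_segments),
        len(rows),
        len(config.label_overrides),
    )
    return OutputTable(schema_id="table6", columns=TABLE6_COLUMNS, rows=rows)


def build_enumeration_table(config: DatasetConfig) -> OutputTable:
    """Emit the symptom-by-vitals enumeration in the printed block design."""
    rows: list[list[str]] = []
    patient = 0
    for block in config.table5_blocks:
        count = int(block.get("count", 16))
        for sym in symptom_sequence(config.table5_order, count):
            patient += 1
            rows.append(
                [
                    str(patient),
                    _fmt_bool(sym.chest_pain),
                    _fmt_bool(sym.shortness_of_breath),
                    _fmt_bool(sym.palpitation),
                    _fmt_bool(sym.at_rest),
                    str(block["spo2"]),
                    str(block["bp_high_printed"]),
                    str(block["bp_low_printed"]),
                ]
            )
    log.info(
        "build_enumeration_table: %d blocks -> %d rows", len(config.table5_blocks), len(rows)
    )
    return OutputTable(schema_id="table5", columns=TABLE5_COLUMNS, rows=rows)


def fixture_table(schema_id: str) -> OutputTable:
    """The packaged fixture in canonical column form."""
    if schema_id not in ("table5", "table6"):
        raise ValueError(f"unknown schema {schema_id!r}")
    text = resources.files("triagesim.data").joinpath(f"{schema_id}.csv").read_text()
    lines = [ln for ln in text.splitlines() if ln]
    header = lines[0].split(",")
    columns = TABLE6_COLUMNS if schema_id == "table6" else TABLE5_COLUMNS
    idx = [header.index(c) for c in columns]
    rows = [[ln.split(",")[i] for i in idx] for ln in lines[1:]]
    return OutputTable(schema_id=schema_id, columns=columns, rows=rows)


@dataclass
class ValidationReport:
    diffs: list[tuple[int, str, str, str]]  # (row number, column, expected, got)

    @property
    def ok(self) -> bool:
        return not self.diffs

    def __str__(self) -> str:
        if self.ok:
            return "OK: tables identical"
        lines = [f"{len(self.diffs)} differing cell(s):"]
        for row, col, exp, got in self.diffs[:50]:
            lines.append(f"  row {row}, column {col}: expected {exp!r}, got {got!r}")
        return "\n".join(lines)


def validate(output: OutputTable, fixture: OutputTable) -> ValidationReport:
    """Cell-by-cell diff of a build against a fixture of the same schema."""
    if output.schema_id != fixture.schema_id or output.columns != fixture.columns:
        raise ValueError(
            f"schema mismatch: {output.schema_id}/{output.columns} vs "
            f"{fixture.schema_id}/{fixture.columns}"
        )
    diffs: list[tuple[int, str, str, str]] = []
    n = max(len(output.rows), len(fixture.rows))
    for i in range(n):
        if i >= len(output.rows):
            diffs.append((i + 1, "<row>", ",".join(fixture.rows[i]), "<missing>"))
            continue
        if i >= len(fixture.rows):
            diffs.append((i + 1, "<row>", "<missing>", ",".join(output.rows[i])))
            continue
        for col, exp, got in zip(output.columns, fixture.rows[i], output.rows[i]):
            if exp != got:
                diffs.append((i + 1, col, exp, got))
    return ValidationReport(diffs=diffs)


def verify_class_profiles(
    config: DatasetConfig, fs: float = 250.0
) -> dict[str, ecg.ECGFeatureVector]:
    """Synthesize and re-extract every ECG class used by a configuration.

    Runs the generation → extraction stage of the pipeline and checks the
    extractor recovers each class's printed targets (peak count exact, QRS
    width within one sample, ST flag and regularity label exact, heart rate
    for the fixed-rate class).  Returns the extracted feature vectors;
    raises if any target is missed.
    """
    out: dict[str, ecg.ECGFeatureVector] = {}
    for name in sorted({seg.ecg_class for seg in config.table6_segments}):
        profile, params = waveform.class_profile(name)
        rec = waveform.synthesize_ecg(
            params, duration=profile.excerpt_duration, fs=fs, record_id=name
        )
        fv = ecg.extract_features(rec)
        tol = 1.0 / fs + 1e-9
        if profile.target_peaks is not None and fv.peaks != profile.target_peaks:
            raise AssertionError(
                f"{name}: peaks {fv.peaks} != target {profile.target_peaks}"
            )
        if (
            profile.target_qrs_width is not None
            and abs((fv.qrs_width or 0.0) - profile.target_qrs_width) > tol
        ):
            raise AssertionError(
                f"{name}: QRS width {fv.qrs_width} outside ±1/fs of "
                f"{profile.target_qrs_width}"
            )
        if (
            profile.target_st_elevated is not None
            and fv.st_elevated is not None
            and fv.st_elevated != profile.target_st_elevated
        ):
            raise AssertionError(f"{name}: ST flag {fv.st_elevated}")
        if fv.pp_label != profile.target_pp_label:
            raise AssertionError(f"{name}: regularity label {fv.pp_label}")
        if (
            profile.target_heart_rate is not None
            and abs(fv.heart_rate - profile.target_heart_rate) > 0.5
        ):
            raise AssertionError(f"{name}: heart rate {fv.heart_rate}")
        out[name] = fv
        log.info("verify_class_profiles: %s ok (peaks=%d)", name, fv.peaks)
    return out
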