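"""Patient feature vectors, symptom enumeration and triage classification.

The triage mapping is specified extensionally: a printed table of 580
patient rows, each an 11-feature vector (SpO2, high/low blood pressure, four
yes/no symptoms, and four ECG feature cells) with an ordered outcome level
Normal < Cold State < Sick < Urgent < Risk.  No closed-form rules are given,
so a deterministic model is induced from the table (an exact-fit decision
tree plus an exact lookup); vectors outside the table are routed through the
tree and flagged as extrapolation.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, fields
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "SymptomVector",
    "VitalBlock",
    "PatientFeatureVector",
    "TriageLevel",
    "TableRow",
    "TriageTable",
    "DecisionModel",
    "SYMPTOM_ORDERS",
    "enumerate_combinations",
    "check_consistency",
    "induce_decision_model",
    "classify",
    "audit_symptom_monotonicity",
    "load_table6",
    "load_table5",
]


@dataclass(frozen=True)
class SymptomVector:
    """The four yes/no intake questions."""

    chest_pain: bool
    shortness_of_breath: bool
    palpitation: bool
    at_rest: bool

    def as_tuple(self) -> tuple[bool, bool, bool, bool]:
        return (self.chest_pain, self.shortness_of_breath, self.palpitation, self.at_rest)


@dataclass(frozen=True)
class VitalBlock:
    """One printed vitals combination: SpO2 % and high/low pressure values."""

    spo2: int
    bp_high: int
    bp_low: int


class TriageLevel(enum.IntEnum):
    """Ordered emergency level; comparisons follow clinical severity."""

    NORMAL = 0
    COLD_STATE = 1
    SICK = 2
    URGENT = 3
    RISK = 4

    @classmethod
    def from_printed(cls, label: str) -> "TriageLevel":
        try:
            return _PRINTED_TO_LEVEL[label.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown triage label {label!r}") from None

    @property
    def printed(self) -> str:
        """The spelling used in the source table ("risk", "Cold State", ...)."""
        return _LEVEL_TO_PRINTED[self]


_PRINTED_TO_LEVEL = {
    "normal": TriageLevel.NORMAL,
    "cold state": TriageLevel.COLD_STATE,
    "cold case": TriageLevel.COLD_STATE,
    "sick": TriageLevel.SICK,
    "urgent": TriageLevel.URGENT,
    "risk": TriageLevel.RISK,
}
_LEVEL_TO_PRINTED = {
    TriageLevel.NORMAL: "Normal",
    TriageLevel.COLD_STATE: "Cold State",
    TriageLevel.SICK: "Sick",
    TriageLevel.URGENT: "Urgent",
    TriageLevel.RISK: "risk",
}


@dataclass(frozen=True)
class PatientFeatureVector:
    """The 11 feature columns of one triage-table row.

    The four ECG cells are kept as printed strings: ``peaks`` is "5"/"6"/"7"
    for the disease classes but "normal" or "110" for the healthy blocks,
    and ``qrs_width`` / ``st`` are empty there.
    """

    spo2: int
    bp_high: int
    bp_low: int
    chest_pain: bool
    shortness_of_breath: bool
    palpitation: bool
    at_rest: bool
    peaks: str
    qrs_width: str
    pp: str
    st: str

    def key(self) -> tuple:
        return tuple(getattr(self, f.name) for f in fields(self))

    @classmethod
    def from_mapping(cls, row: Mapping[str, object]) -> "PatientFeatureVector":
        kwargs = {}
        for f in fields(cls):
            if f.name not in row:
                raise ValueError(f"missing feature field {f.name!r}")
            val = row[f.name]
            if f.type == "bool" and isinstance(val, str):
                val = val.strip().lower() in ("true", "y", "yes", "1")
            elif f.type == "int":
                val = int(val)
            elif f.type == "str":
                val = str(val)
            kwargs[f.name] = val
        return cls(**kwargs)


@dataclass(frozen=True)
class TableRow:
    p_no: int
    ecg_class: str
    vector: PatientFeatureVector
    label: TriageLevel
    label_printed: str


@dataclass
class TriageTable:
    rows: list[TableRow]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.rows)


#: Bit-order conventions for enumerating the 16 symptom combinations.
#: "chest_pain_msb": chest pain is the most significant bit and at-rest the
#: fastest (FFFF, FFFT, FFTF, ...); "chest_pain_lsb": chest pain flips
#: fastest (NNNN, YNNN, NYNN, ...).
SYMPTOM_ORDERS = ("chest_pain_msb", "chest_pain_lsb")


def symptom_sequence(order: str, count: int = 16) -> list[SymptomVector]:
    """The first ``count`` symptom vectors in the given bit-order convention."""
    if order not in SYMPTOM_ORDERS:
        raise ValueError(f"unknown order convention {order!r}; allowed: {list(SYMPTOM_ORDERS)}")
    out = []
    for i in range(count):
        if order == "chest_pain_msb":
            bits = (i >> 3 & 1, i >> 2 & 1, i >> 1 & 1, i & 1)
        else:
            bits = (i & 1, i >> 1 & 1, i >> 2 & 1, i >> 3 & 1)
        out.append(SymptomVector(*(bool(b) for b in bits)))
    return out


def enumerate_combinations(
    blocks: Sequence[VitalBlock],
    order: str = "chest_pain_lsb",
    counts: Sequence[int] | None = None,
) -> list[tuple[SymptomVector, VitalBlock]]:
    """Full-factorial symptom enumeration per vitals block.

    ``counts`` optionally truncates individual blocks (the printed
    enumeration stops its final block early); default is all 16 per block.
    """
    if counts is None:
        counts = [16] * len(blocks)
    if len(counts) != len(blocks):
        raise ValueError("counts must match blocks in length")
    out: list[tuple[SymptomVector, VitalBlock]] = []
    for block, cnt in zip(blocks, counts):
        for sym in symptom_sequence(order, cnt):
            out.append((sym, block))
    return out


def check_consistency(table: TriageTable) -> list[list[TableRow]]:
    """Group rows whose identical feature vectors carry different labels.

    An empty result means the table defines a function from vectors to
    levels.
    """
    groups: dict[tuple, list[TableRow]] = {}
    for row in table.rows:
        groups.setdefault(row.vector.key(), []).append(row)
    return [
        rows
        for rows in groups.values()
        if len({r.label for r in rows}) > 1
    ]


def _encode(vectors: Iterable[PatientFeatureVector], categories: dict[str, list[str]]) -> np.ndarray:
    rows = []
    for v in vectors:
        rows.append(
            [
                v.spo2,
                v.bp_high,
                v.bp_low,
                int(v.chest_pain),
                int(v.shortness_of_breath),
                int(v.palpitation),
                int(v.at_rest),
                categories["peaks"].index(v.peaks) if v.peaks in categories["peaks"] else -1,
                categories["qrs_width"].index(v.qrs_width)
                if v.qrs_width in categories["qrs_width"]
                else -1,
                categories["pp"].index(v.pp) if v.pp in categories["pp"] else -1,
                categories["st"].index(v.st) if v.st in categories["st"] else -1,
            ]
        )
    return np.asarray(rows, dtype=float)


@dataclass
class DecisionModel:
    """Deterministic total mapping from feature vectors to triage levels.

    Seen vectors resolve through an exact lookup; unseen vectors fall back
    to the induced decision tree and are flagged as extrapolation.
    """

    tree: DecisionTreeClassifier
    lookup: dict[tuple, TriageLevel]
    categories: dict[str, list[str]]
    conflicts: list[list[TableRow]]

    def classify(self, vector: PatientFeatureVector) -> tuple[TriageLevel, bool]:
        """Return (level, extrapolated)."""
        key = vector.key()
        if key in self.lookup:
            return self.lookup[key], False
        return self.predict_tree(vector), True

    def predict_tree(self, vector: PatientFeatureVector) -> TriageLevel:
        """The induced tree's prediction, bypassing the exact lookup."""
        x = _encode([vector], self.categories)
        return TriageLevel(int(self.tree.predict(x)[0]))


def induce_decision_model(
    table: TriageTable, on_conflict: str = "first"
) -> DecisionModel:
    """Fit an exact decision tree to the table.

    Duplicate vectors with contradictory labels are resolved to the first
    occurrence (``on_conflict="first"``) or rejected (``"error"``); the
    conflict groups are retained on the model either way.  The tree is grown
    without depth limit, so it reproduces every retained row exactly.
    """
    conflicts = check_consistency(table)
    if conflicts and on_conflict == "error":
        detail = [
            [(r.p_no, r.label.printed) for r in grp] for grp in conflicts
        ]
        raise ValueError(f"conflicting duplicate vectors: {detail}")
    if on_conflict not in ("first", "error"):
        raise ValueError(f"unknown conflict policy {on_conflict!r}")

    lookup: dict[tuple, TriageLevel] = {}
    for row in table.rows:
        lookup.setdefault(row.vector.key(), row.label)

    categories = {
        name: sorted({getattr(r.vector, name) for r in table.rows})
        for name in ("peaks", "qrs_width", "pp", "st")
    }
    vectors = [PatientFeatureVector(*key) for key in lookup]
    X = _encode(vectors, categories)
    y = np.array([int(lookup[v.key()]) for v in vectors])
    tree = DecisionTreeClassifier(random_state=0)
    tree.fit(X, y)
    return DecisionModel(tree=tree, lookup=lookup, categories=categories, conflicts=conflicts)


def classify(vector: PatientFeatureVector, model: DecisionModel) -> TriageLevel:
    """Triage level for one patient vector (exact for table rows)."""
    level, _ = model.classify(vector)
    return level


def audit_symptom_monotonicity(table: TriageTable) -> list[tuple[TableRow, str, TriageLevel]]:
    """Flag fixture pairs where turning one symptom on lowers the level.

    Purely a report: the printed table is canonical even where it violates
    the intuition that more symptoms never mean less urgency.
    """
    index: dict[tuple, TriageLevel] = {}
    for row in table.rows:
        index.setdefault(row.vector.key(), row.label)
    violations = []
    sym_fields = ("chest_pain", "shortness_of_breath", "palpitation", "at_rest")
    for row in table.rows:
        for name in sym_fields:
            if getattr(row.vector, name):
                continue
            flipped = PatientFeatureVector(
                **{
                    f.name: (True if f.name == name else getattr(row.vector, f.name))
                    for f in fields(PatientFeatureVector)
                }
            )
            other = index.get(flipped.key())
            if other is not None and other < row.label:
                violations.append((row, name, other))
    return violations


# ----------------------------------------------------------------------------
# packaged fixtures


def _data_text(name: str) -> str:
    return resources.files("triagesim.data").joinpath(name).read_text()


def load_table6() -> TriageTable:
    """The packaged 580-row triage table (feature vectors + printed labels)."""
    rows = []
    for rec in csv.DictReader(_data_text("table6.csv").splitlines()):
        vector = PatientFeatureVector.from_mapping(
            {**rec, "shortness_of_breath": rec["short_breath"]}
        )
        rows.append(
            TableRow(
                p_no=int(rec["p_no"]),
                ecg_class=rec["ecg_class"],
                vector=vector,
                label=TriageLevel.from_printed(rec["triage"]),
                label_printed=rec["triage"],
            )
        )
    return TriageTable(rows=rows, provenance="table6")


def load_table5() -> list[dict]:
    """The packaged 143-row symptom-by-vitals enumeration, as printed.

    The printed high/low pressure columns are transposed relative to the
    triage table; ``bp_high_printed``/``bp_low_printed`` preserve the
    printed order.
    """
    out = []
    for rec in csv.DictReader(_data_text("table5.csv").splitlines()):
        out.append(
            {
                "patient": int(rec["patient"]),
                "symptoms": SymptomVector(
                    chest_pain=rec["chest_pain"] == "true",
                    shortness_of_breath=rec["short_breath"] == "true",
                    palpitation=rec["palpitation"] == "true",
                    at_rest=rec["at_rest"] == "true",
                ),
                "spo2": int(rec["spo2"]),
                "bp_high_printed": int(rec["bp_high_printed"]),
                "bp_low_printed": int(rec["bp_low_printed"]),
            }
        )
    return out
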