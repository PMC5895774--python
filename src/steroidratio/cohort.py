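"""Subjects, steroid panels and cohort tables.

A cohort is a list of subjects, each carrying a class label (``PCa`` —
prostate cancer, ``BPH`` — benign prostate hypertrophy, ``HC`` — healthy
control), age, total PSA, and a panel of serum steroid concentrations in
ng/mL. The canonical panel covers ten steroids; the tuple
:data:`ANALYTES` fixes their order, and every positional index used by
the ratio formulas refers to that order.

Two reference tables ship with the package: the 71-subject clinical
characteristics table (:func:`builtin_table1`, which carries PSA, DHEAS,
the reported 1-100 discriminating coefficient and the three reported
classification columns, but no full panels) and the MRM transition table
(:func:`builtin_transitions`, two parent->fragment transitions per
analyte).

Missing values (e.g. a PSA printed as "ND") are represented by ``None``
on records and by empty cells on disk — never by zero.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "ANALYTES",
    "CLASS_LABELS",
    "SchemaError",
    "ValidationError",
    "SteroidPanel",
    "SubjectRecord",
    "CohortTable",
    "TransitionTable",
    "load_cohort",
    "write_cohort",
    "builtin_table1",
    "builtin_transitions",
]

#: Canonical analyte order; index i in the ratio formulas refers to this order.
ANALYTES: tuple[str, ...] = (
    "aldosterone",
    "corticosterone",
    "cortisol",
    "11-deoxycortisol",
    "androstenedione",
    "testosterone",
    "DHEA",
    "DHEAS",
    "17-OH-progesterone",
    "progesterone",
)

CLASS_LABELS: tuple[str, ...] = ("PCa", "BPH", "HC")

#: Sentinel strings treated as missing when reading delimited files.
_MISSING_TOKENS = {"", "ND", "NA", "NaN", "nan", "None"}


class SchemaError(ValueError):
    """A cohort file does not conform to the expected column schema."""


class ValidationError(ValueError):
    """Field values violate a cohort invariant (negative, duplicate, ...)."""


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    return False


@dataclass(frozen=True)
class SteroidPanel:
    """Concentrations (ng/mL) over a fixed, ordered analyte list.

    Parameters
    ----------
    concentrations
        Mapping from analyte name to concentration. The analyte set must
        equal ``analytes`` exactly; all values must be >= 0.
    analytes
        Ordered analyte tuple; defaults to the ten-steroid panel.
    normalized
        True once the cortisol/DHEAS weight normalization has been
        applied (the operation is not idempotent, so the flag guards
        against double application).
    """

    concentrations: Mapping[str, float]
    analytes: tuple[str, ...] = ANALYTES
    normalized: bool = False

    def __post_init__(self):
        got = set(self.concentrations)
        want = set(self.analytes)
        if got != want:
            missing = sorted(want - got)
            extra = sorted(got - want)
            raise ValidationError(
                f"panel analyte set mismatch: missing={missing}, extra={extra}"
            )
        for name, value in self.concentrations.items():
            if _is_missing(value):
                continue
            if value < 0:
                raise ValidationError(f"negative concentration for {name!r}: {value}")
        object.__setattr__(self, "concentrations", dict(self.concentrations))

    def __getitem__(self, analyte: str) -> float:
        return self.concentrations[analyte]

    def values(self) -> list[float]:
        """Concentrations in canonical analyte order."""
        return [self.concentrations[a] for a in self.analytes]

    def replace_values(self, updates: Mapping[str, float], *, normalized: bool | None = None) -> "SteroidPanel":
        new = dict(self.concentrations)
        new.update(updates)
        return SteroidPanel(
            new,
            analytes=self.analytes,
            normalized=self.normalized if normalized is None else normalized,
        )


@dataclass
class SubjectRecord:
    """One subject: identity, class label, PSA and steroid panel."""

    id: str
    class_label: str | None = None
    age: float | None = None
    psa: float | None = None
    panel: SteroidPanel | None = None
    dheas: float | None = None
    reported_coefficient: float | None = None
    reported_classifications: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self):
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise ValidationError(
                f"unknown class label {self.class_label!r} for subject {self.id!r}"
            )
        if self.dheas is None and self.panel is not None:
            self.dheas = self.panel["DHEAS"]


@dataclass
class CohortTable:
    """Ordered list of subjects with unique ids."""

    subjects: list[SubjectRecord]
    provenance: str = ""

    def __post_init__(self):
        seen: set[str] = set()
        for s in self.subjects:
            if s.id in seen:
                raise ValidationError(f"duplicate subject id {s.id!r}")
            seen.add(s.id)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def __getitem__(self, item):
        if isinstance(item, str):
            for s in self.subjects:
                if s.id == item:
                    return s
            raise KeyError(item)
        return self.subjects[item]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.subjects:
            key = s.class_label or "unknown"
            counts[key] = counts.get(key, 0) + 1
        return counts

    def panel_matrix(self):
        """(labels, ids, list-of-concentration-rows) for subjects with panels.

        Raises
        ------
        ValidationError
            If any subject lacks a panel; the message lists them.
        """
        missing = [s.id for s in self.subjects if s.panel is None]
        if missing:
            raise ValidationError(f"subjects without panels: {missing}")
        rows = [s.panel.values() for s in self.subjects]
        labels = [s.class_label for s in self.subjects]
        ids = [s.id for s in self.subjects]
        return labels, ids, rows

    def to_frame(self) -> pd.DataFrame:
        records = []
        for s in self.subjects:
            rec: dict[str, object] = {
                "id": s.id,
                "class_label": s.class_label,
                "age": s.age,
                "psa": s.psa,
                "dheas": s.dheas,
                "coefficient": s.reported_coefficient,
            }
            for key in ("psa_rule", "dheas_rule", "ratio_rule"):
                rec[key] = s.reported_classifications.get(key)
            if s.panel is not None:
                for a in s.panel.analytes:
                    rec[a] = s.panel[a]
            records.append(rec)
        frame = pd.DataFrame.from_records(records)
        return frame.dropna(axis=1, how="all")


_DEFAULT_COLUMNS = {
    "id": "id",
    "class_label": "class_label",
    "age": "age",
    "psa": "psa",
    "dheas": "dheas",
    "coefficient": "coefficient",
    "psa_rule": "psa_rule",
    "dheas_rule": "dheas_rule",
    "ratio_rule": "ratio_rule",
}


def _read_dialect(dialect) -> dict[str, str]:
    """dialect: None, a mapping, or a path to a YAML/JSON key->column file."""
    if dialect is None:
        return dict(_DEFAULT_COLUMNS)
    if isinstance(dialect, (str, Path)):
        with open(dialect, "r", encoding="utf-8") as fh:
            dialect = yaml.safe_load(fh)
    mapping = dict(_DEFAULT_COLUMNS)
    mapping.update(dialect)
    return mapping


def _parse_cell(raw) -> float | None:
    if _is_missing(raw):
        return None
    if isinstance(raw, str):
        raw = raw.strip().replace(",", "")
        if raw in _MISSING_TOKENS:
            return None
        return float(raw)
    return float(raw)


def load_cohort(path, dialect=None, provenance: str | None = None) -> CohortTable:
    """Read a delimited cohort table (comma default, tab accepted).

    ``dialect`` maps schema keys (``id``, ``class_label``, ``psa``,
    analyte names, ...) to the file's column names; it may be a mapping
    or a path to a YAML/JSON file. "ND" and empty cells become missing.
    """
    cols = _read_dialect(dialect)
    path = Path(path)
    try:
        head = path.read_text(encoding="utf-8").lstrip("﻿")
    except FileNotFoundError:
        raise
    if not head.strip():
        raise SchemaError(f"empty cohort file: {path}")
    sep = "\t" if "\t" in head.splitlines()[0] else ","
    frame = pd.read_csv(io.StringIO(head), sep=sep, dtype=str, keep_default_na=False)
    return cohort_from_frame(frame, cols, provenance or str(path))


def cohort_from_frame(frame: pd.DataFrame, cols=None, provenance: str = "") -> CohortTable:
    cols = cols or dict(_DEFAULT_COLUMNS)
    for mandatory in ("id", "class_label"):
        if cols.get(mandatory, mandatory) not in frame.columns:
            raise SchemaError(f"missing mandatory column {cols.get(mandatory)!r}")

    analyte_cols = {a: cols.get(a, a) for a in ANALYTES if cols.get(a, a) in frame.columns}
    subjects = []
    for _, row in frame.iterrows():
        panel = None
        if len(analyte_cols) == len(ANALYTES):
            values = {a: _parse_cell(row[c]) for a, c in analyte_cols.items()}
            if any(v is None for v in values.values()):
                panel = None
            else:
                panel = SteroidPanel(values)
        reported = {}
        for key in ("psa_rule", "dheas_rule", "ratio_rule"):
            col = cols.get(key, key)
            if col in frame.columns:
                raw = str(row[col]).strip()
                reported[key] = raw if raw and raw not in _MISSING_TOKENS else None

        def cell(key):
            col = cols.get(key, key)
            return _parse_cell(row[col]) if col in frame.columns else None

        raw_label = str(row[cols.get("class_label", "class_label")]).strip()
        subjects.append(
            SubjectRecord(
                id=str(row[cols.get("id", "id")]).strip(),
                class_label=raw_label if raw_label in CLASS_LABELS else None,
                age=cell("age"),
                psa=cell("psa"),
                panel=panel,
                dheas=cell("dheas"),
                reported_coefficient=cell("coefficient"),
                reported_classifications=reported,
            )
        )
    return CohortTable(subjects, provenance=provenance)


def write_cohort(cohort: CohortTable, path, sep: str = ",") -> None:
    """Write a cohort as delimited text; missing values become empty cells."""
    frame = cohort.to_frame()
    frame.to_csv(path, sep=sep, index=False)


def _data_text(name: str) -> str:
    return resources.files("steroidratio.data").joinpath(name).read_text(encoding="utf-8")


def builtin_table1() -> CohortTable:
    """The embedded 71-subject clinical table (20 PCa, 20 BPH, 31 HC).

    Carries PSA, DHEAS, the reported 1-100 discriminating coefficient and
    the three reported classification columns. Full steroid panels are
    not part of this table and are marked missing.
    """
    frame = pd.read_csv(
        io.StringIO(_data_text("table1.csv")), dtype=str, keep_default_na=False
    )
    return cohort_from_frame(frame, provenance="builtin clinical characteristics table")


@dataclass
class TransitionTable:
    """MRM transitions: two parent->fragment ion pairs per analyte."""

    frame: pd.DataFrame

    def __post_init__(self):
        counts = self.frame.groupby("analyte").size()
        if not (counts == 2).all():
            raise ValidationError("expected exactly two transitions per analyte")
        if (self.frame["parent_mz"] <= 0).any() or (self.frame["fragment_mz"] <= 0).any():
            raise ValidationError("m/z values must be positive")

    def __len__(self) -> int:
        return len(self.frame)

    def parent_mz(self, analyte: str) -> float:
        rows = self.frame[self.frame["analyte"] == analyte]
        if rows.empty:
            raise KeyError(analyte)
        return float(rows["parent_mz"].iloc[0])

    def transitions(self, analyte: str) -> list[tuple[float, float]]:
        rows = self.frame[self.frame["analyte"] == analyte]
        if rows.empty:
            raise KeyError(analyte)
        return list(zip(rows["parent_mz"], rows["fragment_mz"]))


def builtin_transitions() -> TransitionTable:
    """The embedded MRM transition table (10 analytes x 2 transitions)."""
    frame = pd.read_csv(io.StringIO(_data_text("transitions.csv")))
    return TransitionTable(frame)
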