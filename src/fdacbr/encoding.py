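"""Exam-record data model, attribute quantization, and cohort CSV I/O.

Community health-examination records arrive as one row per (resident, exam)
with a mix of categorical risk factors (gender, smoking, ...) and numeric
measurements (BMI, blood lipids, ...).  Each attribute is quantized to a
small integer code by an :class:`EncodingScheme`; the resulting code vector
is what the forest-based weighting and the per-exam risk score consume.

Exams sit on a half-yearly grid: the community station examines residents
every March and September, so an exam in March of the first study year has
index 1, September index 2, and so on up to 20 over ten years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EncodingError",
    "CategoricalAttribute",
    "RangeAttribute",
    "EncodingScheme",
    "ExamRecord",
    "Cohort",
    "default_scheme",
    "exam_time_index",
    "encode_record",
    "read_cohort",
    "write_cohort",
]

START_YEAR = 2012
GRID_LENGTH = 20
LABEL_COLUMN = "hypertension"


class EncodingError(ValueError):
    """Raised for unknown categories, missing fields, or malformed schemes."""


def exam_time_index(year: int, month: int, start_year: int = START_YEAR,
                    grid_length: int = GRID_LENGTH) -> int:
    """Map an exam date to its ordinal index on the half-yearly grid.

    March of ``start_year`` is index 1, September index 2; each later year
    adds two slots.  Only March and September are valid exam months.
    """
    if month not in (3, 9):
        raise EncodingError(
            f"invalid exam month {month!r}: examinations are held in March (3) "
            f"and September (9) only"
        )
    idx = 2 * (year - start_year) + (1 if month == 3 else 2)
    if not 1 <= idx <= grid_length:
        raise EncodingError(
            f"exam date {year}-{month:02d} falls outside the study grid "
            f"1..{grid_length} (start year {start_year})"
        )
    return idx


@dataclass(frozen=True)
class CategoricalAttribute:
    """Attribute whose raw values are category labels mapped to integer codes."""

    name: str
    mapping: Mapping[str, int]

    def encode(self, raw: object) -> int:
        key = str(raw)
        try:
            return self.mapping[key]
        except KeyError:
            raise EncodingError(
                f"attribute {self.name!r}: unknown category {raw!r} "
                f"(expected one of {sorted(self.mapping)})"
            ) from None

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.mapping.values())))

    def to_dict(self) -> dict:
        return {"kind": "categorical", "mapping": dict(self.mapping)}


@dataclass(frozen=True)
class RangeAttribute:
    """Numeric attribute quantized by half-open bins [lo, hi) -> code.

    Bin edges are lower-inclusive / upper-exclusive; the outermost bins are
    open-ended so the scheme is total on the real line.  Edges must tile the
    line without gaps or overlaps.
    """

    name: str
    # ordered (lo, hi, code); lo may be -inf and hi +inf
    bins: tuple[tuple[float, float, int], ...]

    def __post_init__(self) -> None:
        b = sorted(self.bins, key=lambda x: x[0])
        if b[0][0] != -math.inf or b[-1][1] != math.inf:
            raise EncodingError(f"attribute {self.name!r}: bins must cover the real line")
        for (lo, hi, _), (lo2, _, _) in zip(b, b[1:]):
            if hi != lo2:
                raise EncodingError(
                    f"attribute {self.name!r}: bins must tile without gaps or "
                    f"overlaps (edge {hi} vs {lo2})"
                )
        object.__setattr__(self, "bins", tuple(b))

    def encode(self, raw: object) -> int:
        try:
            x = float(raw)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise EncodingError(
                f"attribute {self.name!r}: expected a number, got {raw!r}"
            ) from None
        if math.isnan(x):
            raise EncodingError(f"attribute {self.name!r}: value is NaN")
        for lo, hi, code in self.bins:
            if lo <= x < hi:
                return code
        raise EncodingError(f"attribute {self.name!r}: no bin for {x}")  # pragma: no cover

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(sorted({c for _, _, c in self.bins}))

    def to_dict(self) -> dict:
        return {
            "kind": "range",
            "bins": [
                {
                    "lo": None if lo == -math.inf else lo,
                    "hi": None if hi == math.inf else hi,
                    "code": code,
                }
                for lo, hi, code in self.bins
            ],
        }


Attribute = CategoricalAttribute | RangeAttribute


@dataclass(frozen=True)
class EncodingScheme:
    """Ordered collection of attribute quantizers.

    The attribute order is fixed and defines the layout of every encoded
    vector and of the weight vector; encoding is deterministic and total on
    each attribute's declared domain.
    """

    attributes: tuple[Attribute, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    def __len__(self) -> int:
        return len(self.attributes)

    def __getitem__(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def encode(self, raw: Mapping[str, object]) -> np.ndarray:
        """Encode a raw name->value map into the scheme-ordered code vector."""
        out = np.empty(len(self.attributes), dtype=float)
        for i, attr in enumerate(self.attributes):
            if attr.name not in raw:
                raise EncodingError(f"missing attribute {attr.name!r} in record")
            out[i] = attr.encode(raw[attr.name])
        return out

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {"attributes": [{"name": a.name, **a.to_dict()} for a in self.attributes]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "EncodingScheme":
        attrs: list[Attribute] = []
        for spec in d["attributes"]:
            if spec["kind"] == "categorical":
                attrs.append(CategoricalAttribute(spec["name"], dict(spec["mapping"])))
            elif spec["kind"] == "range":
                bins = tuple(
                    (
                        -math.inf if b["lo"] is None else float(b["lo"]),
                        math.inf if b["hi"] is None else float(b["hi"]),
                        int(b["code"]),
                    )
                    for b in spec["bins"]
                )
                attrs.append(RangeAttribute(spec["name"], bins))
            else:
                raise EncodingError(f"unknown attribute kind {spec['kind']!r}")
        return cls(tuple(attrs))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EncodingScheme":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def encode_record(raw: Mapping[str, object], scheme: EncodingScheme) -> np.ndarray:
    """Functional alias for :meth:`EncodingScheme.encode`."""
    return scheme.encode(raw)


_INF = math.inf


def default_scheme() -> EncodingScheme:
    """The shipped quantization scheme for the hypertension risk factors.

    Sixteen attributes: demographics and lifestyle are categorical; clinical
    measurements are binned with lower-inclusive cut points (a BMI of exactly
    24 codes as overweight).  The hypertension status itself is the label,
    coded NO->0 / YES->1, and is not part of the feature vector.
    """
    return EncodingScheme((
        CategoricalAttribute("gender", {"Female": 0, "Male": 1}),
        RangeAttribute("age", ((-_INF, 35.0, 3), (35.0, 65.0, 2), (65.0, _INF, 1))),
        CategoricalAttribute("exercise_frequency", {
            "Never": 1, "Everyday": 2, "Once a week or more": 3, "Occasionally": 4,
        }),
        CategoricalAttribute("dietary_habit", {
            "Meat diet": 1, "Vegetarian diet": 2, "Equilibrium": 3,
        }),
        CategoricalAttribute("smoking", {"Yes": 1, "Never": 2, "Quitting": 3}),
        CategoricalAttribute("drinking", {
            "Everyday": 1, "Frequently": 2, "Never": 3, "Occasionally": 4,
        }),
        CategoricalAttribute("heart_rhythm", {"Normal": 0, "Arrhythmia": 1}),
        CategoricalAttribute("central_obesity", {"No": 0, "Yes": 1}),
        RangeAttribute("bmi", (
            (-_INF, 18.5, 4), (18.5, 24.0, 1), (24.0, 28.0, 2), (28.0, _INF, 3),
        )),
        CategoricalAttribute("diabetes", {"No": 0, "Yes": 1}),
        RangeAttribute("heart_rate", (
            (-_INF, 60.0, 3), (60.0, 100.0, 1), (100.0, _INF, 2),
        )),
        RangeAttribute("blood_urea", (
            (-_INF, 3.2, 3), (3.2, 7.2, 1), (7.2, _INF, 2),
        )),
        RangeAttribute("total_cholesterol", (
            (-_INF, 3.0, 3), (3.0, 5.2, 2), (5.2, _INF, 1),
        )),
        RangeAttribute("triglyceride", (
            (-_INF, 1.7, 1), (1.7, 5.65, 2), (5.65, _INF, 3),
        )),
        RangeAttribute("ldl_cholesterol", ((-_INF, 4.14, 0), (4.14, _INF, 1))),
        RangeAttribute("hdl_cholesterol", ((-_INF, 1.2, 1), (1.2, _INF, 0))),
    ))


@dataclass
class ExamRecord:
    """One medical examination of one resident."""

    resident_id: str
    exam_index: int
    raw_attributes: dict[str, object]
    encoded: np.ndarray
    hypertension_label: int

    def __post_init__(self) -> None:
        if not 1 <= self.exam_index:
            raise ValueError(f"exam_index must be positive, got {self.exam_index}")

    @classmethod
    def from_raw(cls, resident_id: str, exam_index: int,
                 raw: Mapping[str, object], label: int,
                 scheme: EncodingScheme) -> "ExamRecord":
        return cls(
            resident_id=str(resident_id),
            exam_index=int(exam_index),
            raw_attributes=dict(raw),
            encoded=scheme.encode(raw),
            hypertension_label=int(label),
        )


@dataclass
class Cohort:
    """Residents and their time-ordered exam records.

    Per resident, exam indices are strictly increasing with no duplicates;
    the container enforces this on insertion.
    """

    scheme: EncodingScheme
    residents: dict[str, list[ExamRecord]] = field(default_factory=dict)
    grid_length: int = GRID_LENGTH

    def add(self, record: ExamRecord) -> None:
        if record.exam_index > self.grid_length:
            raise ValueError(
                f"exam_index {record.exam_index} beyond grid length {self.grid_length}"
            )
        exams = self.residents.setdefault(record.resident_id, [])
        if any(e.exam_index == record.exam_index for e in exams):
            raise ValueError(
                f"duplicate record for resident {record.resident_id!r} at "
                f"exam index {record.exam_index}"
            )
        exams.append(record)
        exams.sort(key=lambda e: e.exam_index)

    def __len__(self) -> int:
        return len(self.residents)

    def __contains__(self, resident_id: str) -> bool:
        return resident_id in self.residents

    def ids(self) -> list[str]:
        return list(self.residents)

    def exams(self, resident_id: str) -> list[ExamRecord]:
        return self.residents[resident_id]

    def n_records(self) -> int:
        return sum(len(v) for v in self.residents.values())

    def feature_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack every exam into (X, y): one training row per examination."""
        rows = [e for exams in self.residents.values() for e in exams]
        X = np.array([e.encoded for e in rows], dtype=float)
        y = np.array([e.hypertension_label for e in rows], dtype=int)
        return X, y


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as a UTF-8 CSV: resident_id, exam_index, attributes, label."""
    names = cohort.scheme.names
    rows = []
    for rid in cohort.residents:
        for e in cohort.residents[rid]:
            row = {"resident_id": rid, "exam_index": e.exam_index}
            row.update({n: e.raw_attributes[n] for n in names})
            row[LABEL_COLUMN] = e.hypertension_label
            rows.append(row)
    df = pd.DataFrame(rows, columns=["resident_id", "exam_index", *names, LABEL_COLUMN])
    df.to_csv(path, index=False)


def read_cohort(path: str | Path, scheme: EncodingScheme,
                grid_length: int = GRID_LENGTH) -> Cohort:
    """Read a cohort CSV; inverse of :func:`write_cohort`."""
    df = pd.read_csv(path)
    required = {"resident_id", "exam_index", LABEL_COLUMN, *scheme.names}
    missing = required - set(df.columns)
    if missing:
        raise EncodingError(f"cohort CSV {path} lacks columns: {sorted(missing)}")
    cohort = Cohort(scheme=scheme, grid_length=grid_length)
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        d = row._asdict()
        try:
            rec = ExamRecord.from_raw(
                resident_id=str(d["resident_id"]),
                exam_index=int(d["exam_index"]),
                raw={n: d[n] for n in scheme.names},
                label=int(d[LABEL_COLUMN]),
                scheme=scheme,
            )
            cohort.add(rec)
        except (ValueError, EncodingError) as exc:
            raise EncodingError(f"{path} line {pos}: {exc}") from exc
    return cohort
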