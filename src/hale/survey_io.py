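"""Respondent-level survey file I/O against a declared variable dictionary.

Cohort files are plain CSV (comma, UTF-8, ``.`` decimal) with a header row.
Two columns are structural — ``record_id`` and ``weight`` (the expansion
factor, i.e. the number of population persons the respondent represents) —
and every other column must be declared in a :class:`VariableDictionary`.
Missing values are written as a sentinel token (default ``NA``) and held
in memory as ``None``; missingness is never silently coerced to a valid
code, because descriptive tables report it as its own category.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableDef",
    "VariableDictionary",
    "SurveyRecord",
    "WeightedTable",
    "read_cohort",
    "write_cohort",
    "describe_cohort",
    "records_to_frame",
]

#: canonical missing sentinel used in files
MISSING_TOKEN = "NA"

VALID_KINDS = ("binary", "categorical", "count", "real")


@dataclass(frozen=True)
class VariableDef:
    """One survey variable: name, value domain, missing codes, unit."""

    name: str
    kind: str  # binary | categorical | count | real
    codes: tuple[str, ...] | None = None  # categorical only
    missing_codes: tuple[str, ...] = (MISSING_TOKEN,)
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical":
            if not self.codes:
                raise ValueError(f"categorical variable {self.name!r} has no codes")
            if set(self.codes) & set(self.missing_codes):
                raise ValueError(
                    f"missing codes overlap valid codes for {self.name!r}"
                )

    def parse(self, token: str):
        """Parse a raw file token to its in-memory value (None when missing)."""
        token = token.strip()
        if token in self.missing_codes or token == "":
            return None
        if self.kind == "binary":
            if token not in ("0", "1"):
                raise ValueError(f"binary code {token!r} not in {{0,1}}")
            return int(token)
        if self.kind == "categorical":
            if token not in self.codes:
                raise ValueError(f"code {token!r} not in declared codes")
            return token
        if self.kind == "count":
            value = int(token)
            if value < 0:
                raise ValueError(f"negative count {value}")
            return value
        value = float(token)
        if not np.isfinite(value) or value < 0:
            raise ValueError(f"invalid nonnegative real {token!r}")
        return value

    def format(self, value) -> str:
        """Inverse of :meth:`parse`; ``None`` becomes the first missing code."""
        if value is None:
            return self.missing_codes[0]
        if self.kind == "real":
            return repr(float(value))
        return str(value)

    def validate(self, value) -> None:
        if value is None:
            return
        if self.kind == "binary" and value not in (0, 1):
            raise ValueError(f"{self.name}: binary value {value!r}")
        if self.kind == "categorical" and value not in self.codes:
            raise ValueError(f"{self.name}: code {value!r} outside domain")
        if self.kind == "count" and (not isinstance(value, (int, np.integer)) or value < 0):
            raise ValueError(f"{self.name}: invalid count {value!r}")
        if self.kind == "real" and (float(value) < 0 or not np.isfinite(float(value))):
            raise ValueError(f"{self.name}: invalid real {value!r}")


class VariableDictionary:
    """Ordered collection of :class:`VariableDef` with unique names."""

    def __init__(self, entries: list[VariableDef]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate variable names: {dupes}")
        self.entries: list[VariableDef] = list(entries)
        self._by_name = {e.name: e for e in entries}

    def __getitem__(self, name: str) -> VariableDef:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def to_yaml(self, path=None) -> str | None:
        payload = [
            {
                "name": e.name,
                "kind": e.kind,
                "codes": list(e.codes) if e.codes else None,
                "missing_codes": list(e.missing_codes),
                "unit": e.unit,
            }
            for e in self.entries
        ]
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "VariableDictionary":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            try:
                with open(source, "r", encoding="utf-8") as fh:
                    payload = yaml.safe_load(fh)
            except (OSError, ValueError):
                payload = yaml.safe_load(source)
        entries = [
            VariableDef(
                name=item["name"],
                kind=item["kind"],
                codes=tuple(item["codes"]) if item.get("codes") else None,
                missing_codes=tuple(item.get("missing_codes") or (MISSING_TOKEN,)),
                unit=item.get("unit", "") or "",
            )
            for item in payload
        ]
        return cls(entries)


@dataclass
class SurveyRecord:
    """One respondent: id, expansion weight, and dictionary-declared values."""

    record_id: str
    weight: float
    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.weight > 0):
            raise ValueError(f"record {self.record_id}: nonpositive weight {self.weight}")

    def get(self, name: str):
        return self.values.get(name)

    def validate(self, dictionary: VariableDictionary) -> None:
        for name, value in self.values.items():
            if name not in dictionary:
                raise ValueError(f"record {self.record_id}: unknown variable {name!r}")
            dictionary[name].validate(value)


@dataclass
class WeightedTable:
    """Weighted frequency table in the style of published survey descriptives.

    Rows are (variable, category) pairs, one explicit ``Missing`` row per
    variable; cells hold the weighted frequency and the percent of the grand
    weighted total.
    """

    row_labels: list[tuple[str, str]]
    column_labels: tuple[str, ...]
    cells: np.ndarray
    total_weight: float

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.row_labels, names=["variable", "category"])
        return pd.DataFrame(self.cells, index=idx, columns=list(self.column_labels))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def to_json(self) -> str:
        return self.to_frame().reset_index().to_json(orient="records")


def read_cohort(path, dictionary: VariableDictionary) -> list[SurveyRecord]:
    """Read a cohort CSV into validated :class:`SurveyRecord` objects.

    Declared missing codes are mapped to ``None``; weights are parsed as
    positive reals. Unknown columns, nonpositive weights and out-of-domain
    codes raise ``ValueError`` naming the offending column / row / value.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    columns = list(frame.columns)
    if "record_id" not in columns or "weight" not in columns:
        raise ValueError("cohort file must have 'record_id' and 'weight' columns")
    unknown = [c for c in columns if c not in ("record_id", "weight") and c not in dictionary]
    if unknown:
        raise ValueError(f"unknown column(s) not in variable dictionary: {unknown}")

    records: list[SurveyRecord] = []
    var_cols = [c for c in columns if c in dictionary]
    for _, row in frame.iterrows():
        rid = str(row["record_id"])
        try:
            weight = float(row["weight"])
        except ValueError as exc:
            raise ValueError(f"record {rid}: unparseable weight {row['weight']!r}") from exc
        if not (weight > 0):
            raise ValueError(f"record {rid}: nonpositive weight {weight}")
        values = {}
        for name in var_cols:
            try:
                values[name] = dictionary[name].parse(row[name])
            except ValueError as exc:
                raise ValueError(
                    f"variable {name!r}, record {rid}: value {row[name]!r} invalid ({exc})"
                ) from exc
        records.append(SurveyRecord(record_id=rid, weight=weight, values=values))
    return records


def write_cohort(records: list[SurveyRecord], path, dictionary: VariableDictionary) -> None:
    """Write records as CSV with stable column order; round-trips exactly.

    Every record is validated against the dictionary before any output is
    produced, so a failed write never leaves a partial file.
    """
    for rec in records:
        rec.validate(dictionary)
    columns = ["record_id", "weight"] + dictionary.names
    buf = io.StringIO()
    buf.write(",".join(columns) + "\n")
    for rec in records:
        row = [rec.record_id, repr(float(rec.weight))]
        row += [dictionary[name].format(rec.values.get(name)) for name in dictionary.names]
        buf.write(",".join(row) + "\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def records_to_frame(records: list[SurveyRecord], dictionary: VariableDictionary) -> pd.DataFrame:
    """In-memory DataFrame view (missing as NaN/None), one row per record."""
    data = {
        "record_id": [r.record_id for r in records],
        "weight": [r.weight for r in records],
    }
    for name in dictionary.names:
        data[name] = [r.values.get(name) for r in records]
    return pd.DataFrame(data)


def _categories_for(variable: VariableDef, observed) -> list:
    if variable.kind == "categorical":
        return list(variable.codes)
    if variable.kind == "binary":
        return [0, 1]
    present = sorted({v for v in observed if v is not None})
    return present


def describe_cohort(records: list[SurveyRecord], variables: list[str],
                    dictionary: VariableDictionary) -> WeightedTable:
    """Weighted frequency and percent per category, with explicit missing rows.

    Percentages are computed on the grand weighted total over *all* records,
    so within each variable the category rows plus the missing row sum to
    the total included weight (conservation) and percents sum to 100.
    """
    for name in variables:
        if name not in dictionary:
            raise ValueError(f"variable {name!r} not in dictionary")
    weights = np.array([r.weight for r in records], dtype=float)
    total = float(weights.sum())
    rows: list[tuple[str, str]] = []
    cells: list[list[float]] = []
    for name in variables:
        observed = [r.values.get(name) for r in records]
        categories = _categories_for(dictionary[name], observed)
        for cat in categories:
            mask = np.array([v == cat for v in observed], dtype=bool)
            freq = float(weights[mask].sum())
            rows.append((name, str(cat)))
            cells.append([freq, 100.0 * freq / total if total > 0 else 0.0])
        miss = np.array([v is None for v in observed], dtype=bool)
        freq = float(weights[miss].sum())
        rows.append((name, "Missing"))
        cells.append([freq, 100.0 * freq / total if total > 0 else 0.0])
    return WeightedTable(
        row_labels=rows,
        column_labels=("weighted_n", "percent"),
        cells=np.asarray(cells, dtype=float),
        total_weight=total,
    )
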