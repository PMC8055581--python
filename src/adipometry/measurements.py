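"""Athlete anthropometry records, cohort CSV I/O and validation.

Units are fixed by convention and never inferred: skinfolds in mm, girths,
breadths and heights in cm, body mass in kg, fat percentages as percent of
body mass.  A :class:`Cohort` is an ordered, uniquely identified collection
of :class:`AthleteRecord` objects with a round-trippable canonical CSV
representation (see :data:`CANONICAL_COLUMNS` for the column dictionary).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

SEXES = ("F", "M")

SKINFOLD_SITES = (
    "triceps",
    "biceps",
    "subscapular",
    "suprailiac",
    "supraspinale",
    "abdominal",
    "front_thigh",
    "medial_calf",
)
GIRTH_SITES = ("head", "relaxed_arm", "forearm", "thigh", "calf", "chest", "waist")
BREADTH_SITES = (
    "biacromial",
    "biiliocristal",
    "humerus",
    "femur",
    "ap_chest",
    "transverse_chest",
)

SKINFOLD_COLUMNS = tuple(f"skinfold_{s}" for s in SKINFOLD_SITES)
GIRTH_COLUMNS = tuple(f"girth_{s}" for s in GIRTH_SITES)
BREADTH_COLUMNS = tuple(f"breadth_{s}" for s in BREADTH_SITES)

#: Canonical CSV column order.  ``id`` is an opaque string, ``sex`` is F/M,
#: everything else numeric.  Optional cells are left empty, never zero.
CANONICAL_COLUMNS = (
    "id",
    "sex",
    "age",
    "body_mass",
    "stature",
    "sitting_height",
    *SKINFOLD_COLUMNS,
    *GIRTH_COLUMNS,
    *BREADTH_COLUMNS,
    "dexa_fp",
)

MANDATORY_COLUMNS = ("id", "sex", "age", "body_mass", "stature")

#: Harpenden caliper measuring range upper bound, mm.
SKINFOLD_MAX_MM = 80.0
#: Study age window: athletes aged 18 or older were excluded.
AGE_MIN, AGE_MAX = 5.0, 18.0


@dataclass(frozen=True)
class AthleteRecord:
    """One athlete's anthropometry plus (optionally) the DEXA criterion.

    ``skinfolds``/``girths``/``breadths`` map site name -> measurement;
    absent sites are simply missing keys.  ``sitting_height`` and
    ``dexa_fp`` are optional: prediction-only use needs no criterion, and
    only the five-component model needs sitting height.
    """

    id: str
    sex: str
    age: float
    body_mass: float
    stature: float
    sitting_height: float | None = None
    skinfolds: Mapping[str, float] = field(default_factory=dict)
    girths: Mapping[str, float] = field(default_factory=dict)
    breadths: Mapping[str, float] = field(default_factory=dict)
    dexa_fp: float | None = None

    def problems(self) -> list[str]:
        """Return invariant violations as human-readable messages (empty if valid)."""
        out: list[str] = []
        if self.sex not in SEXES:
            out.append(f"sex={self.sex!r} not one of {SEXES}")
        if not (AGE_MIN <= self.age < AGE_MAX):
            out.append(f"age={self.age} outside [{AGE_MIN}, {AGE_MAX})")
        for name, value in (("body_mass", self.body_mass), ("stature", self.stature)):
            if not (math.isfinite(value) and value > 0):
                out.append(f"{name}={value} must be strictly positive")
        if self.sitting_height is not None and not (
            math.isfinite(self.sitting_height) and self.sitting_height > 0
        ):
            out.append(f"sitting_height={self.sitting_height} must be strictly positive")
        for site, value in self.skinfolds.items():
            if site not in SKINFOLD_SITES:
                out.append(f"unknown skinfold site {site!r}")
            elif not (math.isfinite(value) and 0 < value <= SKINFOLD_MAX_MM):
                out.append(
                    f"skinfold_{site}={value} outside (0, {SKINFOLD_MAX_MM:g}] mm"
                )
        for label, sites, mapping in (
            ("girth", GIRTH_SITES, self.girths),
            ("breadth", BREADTH_SITES, self.breadths),
        ):
            for site, value in mapping.items():
                if site not in sites:
                    out.append(f"unknown {label} site {site!r}")
                elif not (math.isfinite(value) and value > 0):
                    out.append(f"{label}_{site}={value} must be strictly positive")
        if self.dexa_fp is not None and not (
            math.isfinite(self.dexa_fp) and 0 < self.dexa_fp < 100
        ):
            out.append(f"dexa_fp={self.dexa_fp} outside (0, 100) %")
        return out

    def validate(self) -> "AthleteRecord":
        """Raise :class:`ValueError` listing every invariant violation."""
        probs = self.problems()
        if probs:
            raise ValueError(f"invalid record {self.id!r}: " + "; ".join(probs))
        return self

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {c: np.nan for c in CANONICAL_COLUMNS}
        row["id"] = self.id
        row["sex"] = self.sex
        row["age"] = self.age
        row["body_mass"] = self.body_mass
        row["stature"] = self.stature
        if self.sitting_height is not None:
            row["sitting_height"] = self.sitting_height
        for site, value in self.skinfolds.items():
            row[f"skinfold_{site}"] = value
        for site, value in self.girths.items():
            row[f"girth_{site}"] = value
        for site, value in self.breadths.items():
            row[f"breadth_{site}"] = value
        if self.dexa_fp is not None:
            row["dexa_fp"] = self.dexa_fp
        return row

    @classmethod
    def from_row(cls, row: Mapping[str, object]) -> "AthleteRecord":
        def opt(name: str) -> float | None:
            value = row.get(name)
            if value is None:
                return None
            value = float(value)  # type: ignore[arg-type]
            return None if math.isnan(value) else value

        def sites(prefix: str, names: Iterable[str]) -> dict[str, float]:
            out = {}
            for site in names:
                value = opt(f"{prefix}_{site}")
                if value is not None:
                    out[site] = value
            return out

        return cls(
            id=str(row["id"]),
            sex=str(row["sex"]),
            age=float(row["age"]),  # type: ignore[arg-type]
            body_mass=float(row["body_mass"]),  # type: ignore[arg-type]
            stature=float(row["stature"]),  # type: ignore[arg-type]
            sitting_height=opt("sitting_height"),
            skinfolds=sites("skinfold", SKINFOLD_SITES),
            girths=sites("girth", GIRTH_SITES),
            breadths=sites("breadth", BREADTH_SITES),
            dexa_fp=opt("dexa_fp"),
        )


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of athlete records with unique ids."""

    records: tuple[AthleteRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("cohort must contain at least one record")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate athlete ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AthleteRecord]:
        return iter(self.records)

    @cached_property
    def frame(self) -> pd.DataFrame:
        """Canonical wide table (one row per athlete, canonical column order)."""
        df = pd.DataFrame([r.to_row() for r in self.records], columns=CANONICAL_COLUMNS)
        for col in CANONICAL_COLUMNS:
            if col not in ("id", "sex"):
                df[col] = pd.to_numeric(df[col])
        return df

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "") -> "Cohort":
        records = tuple(
            AthleteRecord.from_row(row) for row in frame.to_dict(orient="records")
        )
        return cls(records=records, provenance=provenance)

    def subset(self, mask: np.ndarray, provenance: str | None = None) -> "Cohort":
        kept = tuple(r for r, keep in zip(self.records, mask) if keep)
        return Cohort(kept, provenance if provenance is not None else self.provenance)


@dataclass(frozen=True)
class RowDiagnostic:
    """Exactly one diagnostic per malformed CSV row."""

    row: int  # zero-based data-row index (header excluded)
    athlete_id: str
    problems: tuple[str, ...]

    def __str__(self) -> str:
        return f"row {self.row} (id={self.athlete_id!r}): " + "; ".join(self.problems)


class CohortValidationError(ValueError):
    """Raised when a cohort file contains invariant-violating rows."""

    def __init__(self, diagnostics: list[RowDiagnostic]):
        self.diagnostics = diagnostics
        super().__init__(
            f"{len(diagnostics)} invalid row(s): "
            + " | ".join(str(d) for d in diagnostics)
        )


def read_cohort(
    path,
    *,
    decimal: str = ".",
    sep: str | None = None,
    strict: bool = True,
    provenance: str | None = None,
) -> Cohort:
    """Read a cohort CSV (UTF-8, header row mandatory).

    Column names must follow the canonical dictionary
    (:data:`CANONICAL_COLUMNS`); ``decimal=","`` accepts decimal-comma
    locales (the field separator then defaults to ``";"``).  Rows
    violating record invariants are collected into row-indexed
    diagnostics: with ``strict=True`` (default) a single
    :class:`CohortValidationError` listing every bad row is raised; with
    ``strict=False`` the bad rows are dropped and each diagnostic is
    emitted as a warning.  Missing optional cells stay absent — nothing is
    imputed.
    """
    if sep is None:
        sep = ";" if decimal == "," else ","
    if sep == decimal:
        raise ValueError("field separator must differ from the decimal separator")
    df = pd.read_csv(path, dtype=str, sep=sep, encoding="utf-8")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")
    unknown = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    if unknown:
        raise ValueError(
            f"unknown column(s) {unknown}; expected names from the canonical "
            "column dictionary"
        )

    diagnostics: list[RowDiagnostic] = []
    records: list[AthleteRecord] = []
    numeric_cols = [c for c in df.columns if c not in ("id", "sex")]
    if decimal != ".":
        df[numeric_cols] = df[numeric_cols].apply(
            lambda col: col.str.replace(decimal, ".", regex=False)
        )
    for i, raw in enumerate(df.to_dict(orient="records")):
        problems: list[str] = []
        row: dict[str, object] = {"id": raw.get("id"), "sex": raw.get("sex")}
        for col in numeric_cols:
            cell = raw.get(col)
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
                row[col] = None
                continue
            try:
                row[col] = float(cell)
            except ValueError:
                problems.append(f"non-numeric value {cell!r} in column {col!r}")
                row[col] = None
        for col in MANDATORY_COLUMNS:
            if row.get(col) is None and not any(col in p for p in problems):
                problems.append(f"missing mandatory value in column {col!r}")
        if not problems:
            record = AthleteRecord.from_row(row)
            problems.extend(record.problems())
        if problems:
            diagnostics.append(
                RowDiagnostic(row=i, athlete_id=str(raw.get("id")), problems=tuple(problems))
            )
        else:
            records.append(record)

    if diagnostics:
        if strict:
            raise CohortValidationError(diagnostics)
        for d in diagnostics:
            warnings.warn(f"dropping invalid cohort row: {d}", stacklevel=2)
    if not records:
        raise ValueError(f"no valid rows in {path}")
    return Cohort(tuple(records), provenance if provenance is not None else str(path))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as canonical-column CSV.

    Values are printed with 10 significant digits, so a write/read
    round-trip preserves measurements well beyond caliper precision;
    absent optional fields become empty cells.
    """
    df = cohort.to_frame()
    df.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")


def bmi(body_mass: float, stature: float) -> float:
    """Quetelet body mass index, kg/m^2, from mass in kg and stature in cm."""
    if not (body_mass > 0 and stature > 0):
        raise ValueError("body_mass and stature must be strictly positive")
    return body_mass / (stature / 100.0) ** 2
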