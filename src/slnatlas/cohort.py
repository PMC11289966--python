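"""Tumour/drainage cohort data model and preprocessing.

The unit of analysis is the tumour: each record carries the breast region of
the primary tumour (clockface 0-12, 0 = retroareolar), the body side, the
nipple distance, and the set of lymph-node fields that contained sentinel
lymph nodes (SLNs) on lymphoscintigraphy/SPECT-CT.  A patient appears at most
twice (bilateral primaries), and the two breasts of a bilateral patient are
treated as independent drainage systems.

Preprocessing applies two conventions before any estimation:

* tumours within 1 cm of the nipple are reclassified to the retroareolar
  (0 o'clock) region, and
* all right-sided data is reflected to the left side (clockface ``h`` maps to
  ``12 - h`` for ``h`` in 1..11; 0 and 12 lie on the mirror axis), since
  drainage and prevalence are symmetric between sides.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "NODE_FIELDS",
    "NODE_FIELD_INDEX",
    "N_REGIONS",
    "TumourRecord",
    "Cohort",
    "ContingencyTable",
    "reclassify_retroareolar",
    "reflect_to_left",
    "preprocess",
    "build_contingency",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: Controlled vocabulary of the 12 lymph-node fields, in reporting order.
NODE_FIELDS: tuple[str, ...] = (
    "axilla-I-anterior",
    "axilla-I-central",
    "axilla-I-lateral",
    "axilla-I-posterior",
    "axilla-I-interpectoral",
    "axilla-II",
    "axilla-III",
    "internal-mammary",
    "supraclavicular",
    "mediastinal",
    "interval",
    "contralateral",
)
NODE_FIELD_INDEX: dict[str, int] = {f: i for i, f in enumerate(NODE_FIELDS)}

#: Clockface regions 0..12 (0 = retroareolar).
N_REGIONS = 13

_SIDES = ("L", "R")
_SEXES = ("F", "M", "unknown")

_CSV_COLUMNS = (
    "patient_id",
    "sex",
    "age_years",
    "side",
    "clockface",
    "nipple_distance_cm",
    "node_fields",
)


class CohortValidationError(ValueError):
    """Raised when a record or CSV row violates the cohort schema."""


def _check_clockface(clockface: int) -> int:
    clockface = int(clockface)
    if not 0 <= clockface <= 12:
        raise CohortValidationError(f"clockface must be in 0..12, got {clockface}")
    return clockface


@dataclass(frozen=True)
class TumourRecord:
    """One tumour: region, side, nipple distance and draining node fields."""

    patient_id: str
    side: str
    clockface: int
    nipple_distance_cm: float
    drained_fields: frozenset[str] = frozenset()
    sex: str = "unknown"
    age_years: float | None = None

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise CohortValidationError(f"side must be L or R, got {self.side!r}")
        if self.sex not in _SEXES:
            raise CohortValidationError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        _check_clockface(self.clockface)
        d = float(self.nipple_distance_cm)
        if not np.isfinite(d) or d < 0:
            raise CohortValidationError(
                f"nipple_distance_cm must be finite and non-negative, got {d}"
            )
        unknown = set(self.drained_fields) - set(NODE_FIELDS)
        if unknown:
            raise CohortValidationError(f"unknown node field(s): {sorted(unknown)}")
        object.__setattr__(self, "drained_fields", frozenset(self.drained_fields))


@dataclass(frozen=True)
class Cohort:
    """Ordered tumour records; a patient_id may appear at most twice.

    Opposite-sidedness of bilateral pairs is a property of raw (unreflected)
    cohorts only — after reflection every record is left-sided — so it is not
    enforced by the container.
    """

    records: tuple[TumourRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.patient_id] = counts.get(r.patient_id, 0) + 1
        for pid, n in counts.items():
            if n > 2:
                raise CohortValidationError(
                    f"patient {pid!r} has {n} tumours (max 2, bilateral)"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def patients(self) -> tuple[str, ...]:
        """Distinct patient ids in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return tuple(seen)


@dataclass(frozen=True)
class ContingencyTable:
    """Region x node-field counts: the aggregate object behind all estimation.

    ``field_counts[r, f]`` is the number of tumours in clockface region ``r``
    with at least one SLN in node field ``f``; rows are *not* exclusive, so
    column sums may exceed ``n_total``.
    """

    region_totals: np.ndarray  # (13,) int
    field_counts: np.ndarray  # (13, 12) int

    def __post_init__(self) -> None:
        rt = np.asarray(self.region_totals, dtype=int)
        fc = np.asarray(self.field_counts, dtype=int)
        if rt.shape != (N_REGIONS,) or fc.shape != (N_REGIONS, len(NODE_FIELDS)):
            raise CohortValidationError(
                f"expected shapes ({N_REGIONS},) and ({N_REGIONS}, {len(NODE_FIELDS)}), "
                f"got {rt.shape} and {fc.shape}"
            )
        if (rt < 0).any() or (fc < 0).any():
            raise CohortValidationError("counts must be non-negative")
        if (fc > rt[:, None]).any():
            raise CohortValidationError("field_counts[r, f] cannot exceed region_totals[r]")
        rt.setflags(write=False)
        fc.setflags(write=False)
        object.__setattr__(self, "region_totals", rt)
        object.__setattr__(self, "field_counts", fc)

    @property
    def n_total(self) -> int:
        return int(self.region_totals.sum())

    @property
    def field_totals(self) -> np.ndarray:
        """Per node field, number of tumours (any region) draining to it."""
        return self.field_counts.sum(axis=0)


def reclassify_retroareolar(record: TumourRecord) -> TumourRecord:
    """Move tumours <= 1 cm from the nipple into the 0 o'clock region."""
    if record.nipple_distance_cm <= 1.0:
        return replace(record, clockface=0)
    return record


def reflect_to_left(record: TumourRecord) -> TumourRecord:
    """Reflect right-sided records to the left side (clockface h -> 12 - h).

    0 (retroareolar) and 12 o'clock lie on the mirror axis and are unchanged;
    node-field labels are side-agnostic after reflection.  Left records are
    returned as-is, so the map is idempotent.
    """
    if record.side == "L":
        return record
    h = record.clockface
    mirrored = h if h in (0, 12) else 12 - h
    return replace(record, side="L", clockface=mirrored)


def preprocess(cohort: Cohort) -> Cohort:
    """Apply retroareolar reclassification then reflection; drop nothing.

    Raises if any record has no drained field (such patients never proceeded
    to SPECT/CT and must not enter the analysis cohort).
    """
    out = []
    for i, rec in enumerate(cohort):
        if not rec.drained_fields:
            raise CohortValidationError(
                f"record {i} ({rec.patient_id}) has no drained node field"
            )
        out.append(reflect_to_left(reclassify_retroareolar(rec)))
    return Cohort(tuple(out))


def build_contingency(cohort: Cohort) -> ContingencyTable:
    """Count tumours per region and per (region, node field) cell."""
    if len(cohort) == 0:
        raise CohortValidationError("cannot build a contingency table from an empty cohort")
    region_totals = np.zeros(N_REGIONS, dtype=int)
    field_counts = np.zeros((N_REGIONS, len(NODE_FIELDS)), dtype=int)
    for rec in cohort:
        if not rec.drained_fields:
            raise CohortValidationError(
                f"record for patient {rec.patient_id!r} has no drained node field"
            )
        region_totals[rec.clockface] += 1
        for f in rec.drained_fields:
            field_counts[rec.clockface, NODE_FIELD_INDEX[f]] += 1
    return ContingencyTable(region_totals, field_counts)


def read_cohort_csv(path) -> Cohort:
    """Read a cohort CSV (see module docs); raises naming the offending row."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise CohortValidationError(f"missing CSV column(s): {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                fields = [s for s in row["node_fields"].split(";") if s]
                age = row["age_years"]
                records.append(
                    TumourRecord(
                        patient_id=row["patient_id"],
                        sex=row["sex"] or "unknown",
                        age_years=float(age) if age not in ("", None) else None,
                        side=row["side"],
                        clockface=int(row["clockface"]),
                        nipple_distance_cm=float(row["nipple_distance_cm"]),
                        drained_fields=frozenset(fields),
                    )
                )
            except (CohortValidationError, ValueError, KeyError) as exc:
                raise CohortValidationError(f"row {lineno}: {exc}") from exc
    return Cohort(tuple(records))


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort CSV; node fields are serialized in vocabulary order."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in cohort:
            fields = ";".join(f for f in NODE_FIELDS if f in r.drained_fields)
            writer.writerow(
                [
                    r.patient_id,
                    r.sex,
                    "" if r.age_years is None else f"{r.age_years:g}",
                    r.side,
                    r.clockface,
                    f"{r.nipple_distance_cm:g}",
                    fields,
                ]
            )


def contingency_to_csv(table: ContingencyTable, path) -> None:
    """Write the 13 x (12 + total) contingency CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["clockface", *NODE_FIELDS, "region_total"])
        for r in range(N_REGIONS):
            writer.writerow([r, *table.field_counts[r].tolist(), int(table.region_totals[r])])


def contingency_from_csv(path) -> ContingencyTable:
    """Read a contingency CSV written by :func:`contingency_to_csv`."""
    region_totals = np.zeros(N_REGIONS, dtype=int)
    field_counts = np.zeros((N_REGIONS, len(NODE_FIELDS)), dtype=int)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                r = _check_clockface(int(row["clockface"]))
                region_totals[r] = int(row["region_total"])
                for f in NODE_FIELDS:
                    field_counts[r, NODE_FIELD_INDEX[f]] = int(row[f])
            except (KeyError, ValueError) as exc:
                raise CohortValidationError(f"row {lineno}: {exc}") from exc
    return ContingencyTable(region_totals, field_counts)
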