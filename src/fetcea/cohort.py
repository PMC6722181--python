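"""Cohort data model and CSV input/output.

A cohort is an ordered collection of patient records, each holding the
longitudinal imaging measurements used for response assessment in
glioblastoma follow-up — gadolinium contrast-enhancing tumour volume on
T1-weighted MRI (cm^3) and the maximum tumour-to-background ratio
(TBRmax) of amino-acid PET tracer uptake — at two time points, plus
overall survival (OS) and progression-free survival (PFS) in months.
Any imaging measurement may be missing (a scan not acquired or not
evaluable); survival endpoints are always recorded.

The built-in 25-patient reference cohort, a published series of
glioblastoma patients scanned before and during temozolomide
chemoradiation, ships with the package and is the default input of the
analysis pipeline.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "PatientRecord",
    "Cohort",
    "CohortFormatError",
    "CohortValidationError",
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "builtin_table1",
]

#: Exact header of the cohort CSV dialect (comma-separated, UTF-8,
#: decimal point, empty field = missing value).
COHORT_COLUMNS = (
    "patient_id",
    "gd_vol_1",
    "gd_vol_2",
    "tbr_max_1",
    "tbr_max_2",
    "os_months",
    "pfs_months",
)


class CohortFormatError(ValueError):
    """Raised when a cohort file does not conform to the CSV dialect."""


class CohortValidationError(ValueError):
    """Raised when a field value violates a patient-record invariant."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient: two-scan imaging measurements and survival endpoints.

    ``None`` encodes a missing measurement.  Volumes are in cm^3 and must
    be non-negative; TBRmax is a dimensionless ratio and must be strictly
    positive; survival times are in months and must be strictly positive.
    """

    patient_id: int
    gd_vol_1: float | None
    gd_vol_2: float | None
    tbr_max_1: float | None
    tbr_max_2: float | None
    os_months: float
    pfs_months: float

    def __post_init__(self) -> None:
        if not isinstance(self.patient_id, int) or self.patient_id <= 0:
            raise CohortValidationError(
                f"patient_id must be a positive integer, got {self.patient_id!r}"
            )
        for name in ("gd_vol_1", "gd_vol_2"):
            v = getattr(self, name)
            if v is not None and (math.isnan(v) or v < 0):
                raise CohortValidationError(
                    f"patient {self.patient_id}: {name} must be >= 0, got {v!r}"
                )
        for name in ("tbr_max_1", "tbr_max_2"):
            v = getattr(self, name)
            if v is not None and (math.isnan(v) or v <= 0):
                raise CohortValidationError(
                    f"patient {self.patient_id}: {name} must be > 0, got {v!r}"
                )
        for name in ("os_months", "pfs_months"):
            v = getattr(self, name)
            if v is None or math.isnan(v) or v <= 0:
                raise CohortValidationError(
                    f"patient {self.patient_id}: {name} must be > 0, got {v!r}"
                )

    @property
    def has_pet(self) -> bool:
        """True when both PET TBRmax values are present."""
        return self.tbr_max_1 is not None and self.tbr_max_2 is not None

    @property
    def has_mri(self) -> bool:
        """True when both MRI Gd-volumes are present."""
        return self.gd_vol_1 is not None and self.gd_vol_2 is not None


@dataclass(frozen=True)
class Cohort:
    """Ordered, id-unique collection of :class:`PatientRecord`."""

    patients: tuple[PatientRecord, ...]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def __getitem__(self, idx: int) -> PatientRecord:
        return self.patients[idx]

    def get(self, patient_id: int) -> PatientRecord:
        """Return the record with the given id."""
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(f"no patient with id {patient_id}")

    @property
    def n_pet_available(self) -> int:
        return sum(p.has_pet for p in self.patients)

    @property
    def n_mri_available(self) -> int:
        return sum(p.has_mri for p in self.patients)


def _parse_field(name: str, raw: str, row_num: int) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise CohortFormatError(
            f"row {row_num}: cannot parse {name}={raw!r} as a number"
        ) from None


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV (see :data:`COHORT_COLUMNS` for the dialect).

    Empty fields become missing values.  A malformed header raises
    :class:`CohortFormatError`; out-of-range values raise
    :class:`CohortValidationError` naming the offending row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        return _read_cohort_stream(fh, str(path))


def _read_cohort_stream(fh: Iterable[str], source: str) -> Cohort:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise CohortFormatError(f"{source}: empty file, expected header row") from None
    if tuple(h.strip() for h in header) != COHORT_COLUMNS:
        raise CohortFormatError(
            f"{source}: bad header {header!r}, expected {list(COHORT_COLUMNS)}"
        )
    records = []
    for row_num, row in enumerate(reader, start=2):
        if not row or all(c.strip() == "" for c in row):
            continue
        if len(row) != len(COHORT_COLUMNS):
            raise CohortFormatError(
                f"{source}: row {row_num} has {len(row)} fields, "
                f"expected {len(COHORT_COLUMNS)}"
            )
        pid_raw = row[0].strip()
        try:
            pid = int(pid_raw)
        except ValueError:
            raise CohortFormatError(
                f"{source}: row {row_num}: patient_id {pid_raw!r} is not an integer"
            ) from None
        values = {
            name: _parse_field(name, raw, row_num)
            for name, raw in zip(COHORT_COLUMNS[1:], row[1:])
        }
        try:
            records.append(PatientRecord(patient_id=pid, **values))
        except CohortValidationError as exc:
            raise CohortValidationError(f"{source}: row {row_num}: {exc}") from None
    return Cohort(tuple(records))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the package CSV dialect (lossless round-trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for p in cohort:
            writer.writerow(
                [p.patient_id]
                + [
                    "" if getattr(p, f.name) is None else repr(getattr(p, f.name))
                    for f in fields(p)
                    if f.name != "patient_id"
                ]
            )


def builtin_table1() -> Cohort:
    """The built-in 25-patient glioblastoma reference cohort.

    Twenty-three patients have both PET scans and twenty-one both MRI
    scans; survival is recorded for all.  Values are exactly as published
    in the source series.
    """
    text = resources.files("fetcea.data").joinpath("table1.csv").read_text("utf-8")
    return _read_cohort_stream(text.splitlines(), "builtin_table1")
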