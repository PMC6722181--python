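"""Rule-based responder / non-responder classification.

Four deterministic rules, one per information source:

* **PET** — responder iff TBRmax at scan 2 dropped by at least 20 %,
  i.e. ``tbr_max_2 < 0.8 * tbr_max_1`` (strict inequality).
* **MRI** — responder iff the contrast-enhancing volume did not grow,
  i.e. ``gd_vol_2 <= gd_vol_1`` ("no change or a decrease").
* **OS endpoint** — clinical responder iff overall survival exceeds
  10 months (strictly), the median survival of the disease.
* **PFS endpoint** — clinical responder iff progression-free survival
  is 6 months or more (inclusive), the conventional long-/short-term
  survivor split.

An imaging call is *unavailable* when either scan value is missing;
survival endpoints are always classifiable.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from .cohort import Cohort, CohortValidationError

__all__ = [
    "ResponseStatus",
    "ClassifiedPatient",
    "Endpoint",
    "classify_pet",
    "classify_mri",
    "classify_os",
    "classify_pfs",
    "classify_cohort",
    "write_classification",
]

#: Clinical endpoint selector used throughout the pipeline.
Endpoint = Literal["os", "pfs"]

#: TBRmax ratio below which the PET scan calls a responder.
PET_RESPONSE_RATIO = 0.8
#: Overall-survival cut-off (months, exclusive) for clinical response.
OS_CUTOFF_MONTHS = 10.0
#: Progression-free-survival cut-off (months, inclusive).
PFS_CUTOFF_MONTHS = 6.0


class ResponseStatus(enum.Enum):
    """Outcome of one classification rule for one patient."""

    RESPONDER = "responder"
    NON_RESPONDER = "non_responder"
    UNAVAILABLE = "unavailable"

    @property
    def available(self) -> bool:
        return self is not ResponseStatus.UNAVAILABLE


@dataclass(frozen=True)
class ClassifiedPatient:
    """All four rule outcomes for one patient."""

    patient_id: int
    pet: ResponseStatus
    mri: ResponseStatus
    os_endpoint: ResponseStatus
    pfs_endpoint: ResponseStatus

    def clinical(self, endpoint: Endpoint) -> ResponseStatus:
        """The clinical truth status for the requested endpoint."""
        return self.os_endpoint if endpoint == "os" else self.pfs_endpoint


def _check_positive(name: str, value: float | None) -> None:
    if value is not None and value <= 0:
        raise CohortValidationError(f"{name} must be > 0, got {value!r}")


def classify_pet(
    tbr_max_1: float | None, tbr_max_2: float | None
) -> ResponseStatus:
    """PET call: responder iff TBRmax fell by at least 20 % between scans."""
    _check_positive("tbr_max_1", tbr_max_1)
    _check_positive("tbr_max_2", tbr_max_2)
    if tbr_max_1 is None or tbr_max_2 is None:
        return ResponseStatus.UNAVAILABLE
    if tbr_max_2 < PET_RESPONSE_RATIO * tbr_max_1:
        return ResponseStatus.RESPONDER
    return ResponseStatus.NON_RESPONDER


def classify_mri(
    gd_vol_1: float | None, gd_vol_2: float | None
) -> ResponseStatus:
    """MRI call: responder iff the Gd-enhancing volume did not increase."""
    for name, v in (("gd_vol_1", gd_vol_1), ("gd_vol_2", gd_vol_2)):
        if v is not None and v < 0:
            raise CohortValidationError(f"{name} must be >= 0, got {v!r}")
    if gd_vol_1 is None or gd_vol_2 is None:
        return ResponseStatus.UNAVAILABLE
    if gd_vol_2 <= gd_vol_1:
        return ResponseStatus.RESPONDER
    return ResponseStatus.NON_RESPONDER


def classify_os(os_months: float) -> ResponseStatus:
    """Clinical truth under the overall-survival endpoint (> 10 months)."""
    if os_months is None or os_months <= 0:
        raise CohortValidationError(f"os_months must be > 0, got {os_months!r}")
    if os_months > OS_CUTOFF_MONTHS:
        return ResponseStatus.RESPONDER
    return ResponseStatus.NON_RESPONDER


def classify_pfs(pfs_months: float) -> ResponseStatus:
    """Clinical truth under the progression-free-survival endpoint (>= 6 months)."""
    if pfs_months is None or pfs_months <= 0:
        raise CohortValidationError(f"pfs_months must be > 0, got {pfs_months!r}")
    if pfs_months >= PFS_CUTOFF_MONTHS:
        return ResponseStatus.RESPONDER
    return ResponseStatus.NON_RESPONDER


def classify_cohort(cohort: Cohort) -> tuple[ClassifiedPatient, ...]:
    """Apply all four rules to every patient, preserving cohort order."""
    return tuple(
        ClassifiedPatient(
            patient_id=p.patient_id,
            pet=classify_pet(p.tbr_max_1, p.tbr_max_2),
            mri=classify_mri(p.gd_vol_1, p.gd_vol_2),
            os_endpoint=classify_os(p.os_months),
            pfs_endpoint=classify_pfs(p.pfs_months),
        )
        for p in cohort
    )


_STATUS_CODE = {
    ResponseStatus.RESPONDER: "1",
    ResponseStatus.NON_RESPONDER: "0",
    ResponseStatus.UNAVAILABLE: "",
}


def write_classification(
    classified: tuple[ClassifiedPatient, ...], path: str | Path
) -> None:
    """Export statuses as CSV: 1 = responder, 0 = non-responder, empty = unavailable."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["patient_id", "pet_status", "mri_status", "os_status", "pfs_status"]
        )
        for c in classified:
            writer.writerow(
                [
                    c.patient_id,
                    _STATUS_CODE[c.pet],
                    _STATUS_CODE[c.mri],
                    _STATUS_CODE[c.os_endpoint],
                    _STATUS_CODE[c.pfs_endpoint],
                ]
            )
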