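"""Incremental cost-effectiveness ratios (ICER).

The ICER of PET-based over MRI-based response assessment is the added
cost per unit of added effectiveness,

    ICER = cost_PET / (effectiveness_PET - effectiveness_MRI),

with the MRI scan cost not subtracted (in practice MRI is acquired in
both strategies).  Two effectiveness scales are reported:

* per identified non-responder — the increment in the non-responder
  identification rate (the clinically decisive gain: a flagged
  non-responder can be spared ineffective maintenance chemotherapy);
* per correct diagnosis — the increment in overall diagnostic
  accuracy, the scale used by comparable PET health-technology
  assessments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .classify import ClassifiedPatient, Endpoint
from .costs import CostParameters, followup_cost
from .tree import TreeEffectiveness, effectiveness, estimate_chance_nodes

__all__ = ["IcerResult", "UndefinedIcerError", "icer", "full_cea"]


class UndefinedIcerError(ZeroDivisionError):
    """The effectiveness increment is zero; the ratio is undefined."""


@dataclass(frozen=True)
class IcerResult:
    """Cost, effectiveness increments, and the two ICER scales."""

    endpoint: Endpoint
    cost: float
    delta_nr: float
    delta_accuracy: float
    icer_per_nonresponder: float
    icer_per_diagnosis: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def icer(cost: float, effectiveness_pet: float, effectiveness_mri: float) -> float:
    """``cost / (effectiveness_pet - effectiveness_mri)``, sign included."""
    delta = effectiveness_pet - effectiveness_mri
    if delta == 0.0:
        raise UndefinedIcerError("zero effectiveness increment, ICER undefined")
    return cost / delta


def full_cea(
    classified: tuple[ClassifiedPatient, ...] | list[ClassifiedPatient],
    endpoint: Endpoint,
    cost_params: CostParameters | None = None,
    annual_scans: float | None = None,
    eff: TreeEffectiveness | None = None,
) -> IcerResult:
    """Classified cohort -> chance nodes -> effectiveness -> both ICERs.

    With the default ``cost_params`` the deterministic base case uses the
    fixed per-patient follow-up cost of 780.50 EUR; pass a
    volume-dependent model together with ``annual_scans`` to price at a
    specific scan volume.  A precomputed ``eff`` skips re-estimation.
    """
    if cost_params is None:
        cost_params = CostParameters(model="fixed")
    if cost_params.model == "fixed":
        cost = followup_cost(cost_params, annual_scans if annual_scans else 1.0)
    else:
        if annual_scans is None:
            raise ValueError(f"cost model {cost_params.model!r} needs annual_scans")
        cost = followup_cost(cost_params, annual_scans)

    if eff is None:
        eff = effectiveness(estimate_chance_nodes(classified, endpoint))
    return IcerResult(
        endpoint=endpoint,
        cost=cost,
        delta_nr=eff.delta_nr,
        delta_accuracy=eff.delta_accuracy,
        icer_per_nonresponder=icer(
            cost, eff.pet_nr_identification, eff.mri_nr_identification
        ),
        icer_per_diagnosis=icer(cost, eff.pet_accuracy, eff.mri_accuracy),
    )
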