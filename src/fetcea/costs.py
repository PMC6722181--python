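"""Per-patient follow-up cost of amino-acid PET imaging.

Reimbursement of a PET scan in the Belgian system combines a fixed
annual budget envelope (purchase and maintenance of scanners, shared
across all scans performed nationally) with a per-scan fee for
acquisition and interpretation.  The per-patient follow-up cost — two
scans per patient in the follow-up protocol — therefore falls as the
annual national scan volume rises.

Three (annual scan volume, per-patient cost) anchor points are known
for the reference reimbursement year::

    5,063 scans -> 813.20 EUR
    5,626 scans -> 780.50 EUR   (base case)
    6,189 scans -> 735.74 EUR

The anchors are not mutually consistent with any two-parameter smooth
form (neither ``a + b/n`` nor a straight line passes through all
three), so the default volume-dependent model interpolates linearly
between adjacent anchors and extrapolates linearly beyond them —
exact at every anchor.  A ``fixed`` model (constant 780.50 EUR,
used by the deterministic analyses) and an explicit two-cost-center
reciprocal model ``scans_per_patient * (F/n + r)`` are available as
alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = ["CostParameters", "followup_cost", "DEFAULT_ANCHORS", "BASE_FOLLOWUP_COST"]

#: Printed (annual scan volume, per-patient follow-up cost in EUR) anchors.
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (5063, 813.20),
    (5626, 780.50),
    (6189, 735.74),
)

#: Base-case per-patient follow-up cost (EUR), two scans per patient.
BASE_FOLLOWUP_COST = 780.50

CostModel = Literal["fixed", "piecewise_linear", "two_cost_center"]


@dataclass(frozen=True)
class CostParameters:
    """Configuration of the scan-volume-dependent cost model.

    ``fixed_budget`` (EUR/year) and ``scan_fee`` (EUR/scan) are only
    used by the ``two_cost_center`` model.
    """

    model: CostModel = "piecewise_linear"
    scans_per_patient: int = 2
    anchor_points: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS
    fixed_cost: float = BASE_FOLLOWUP_COST
    # two_cost_center defaults calibrated to the base anchor:
    # 2 * (490_025/5_626 + 303.15) = 780.50 EUR
    fixed_budget: float = 490_025.0
    scan_fee: float = 303.15

    def __post_init__(self) -> None:
        if self.scans_per_patient < 1:
            raise ValueError("scans_per_patient must be >= 1")
        if self.fixed_cost <= 0:
            raise ValueError("fixed_cost must be > 0")
        volumes = [v for v, _ in self.anchor_points]
        costs = [c for _, c in self.anchor_points]
        if len(self.anchor_points) < 2 and self.model == "piecewise_linear":
            raise ValueError("piecewise_linear needs at least two anchors")
        if sorted(volumes) != volumes or len(set(volumes)) != len(volumes):
            raise ValueError("anchor volumes must be strictly increasing")
        if any(c2 >= c1 for c1, c2 in zip(costs, costs[1:])):
            raise ValueError("anchor costs must be strictly decreasing")
        if any(c <= 0 for c in costs):
            raise ValueError("anchor costs must be > 0")


def followup_cost(
    params: CostParameters, annual_scans: float | Sequence[float] | np.ndarray
):
    """Per-patient follow-up cost (EUR) at the given annual scan volume.

    Accepts a scalar or an array of volumes; returns the same shape.
    Volumes must be strictly positive.
    """
    scans = np.asarray(annual_scans, dtype=float)
    if np.any(scans <= 0):
        raise ValueError("annual_scans must be > 0")

    if params.model == "fixed":
        out = np.full_like(scans, params.fixed_cost)
    elif params.model == "two_cost_center":
        out = params.scans_per_patient * (params.fixed_budget / scans + params.scan_fee)
    elif params.model == "piecewise_linear":
        volumes = np.array([v for v, _ in params.anchor_points], dtype=float)
        costs = np.array([c for _, c in params.anchor_points], dtype=float)
        # np.interp clamps outside the anchor range; extend the outer
        # segments linearly instead so extrapolation keeps the local slope.
        out = np.interp(scans, volumes, costs)
        lo = scans < volumes[0]
        hi = scans > volumes[-1]
        if np.any(lo):
            slope = (costs[1] - costs[0]) / (volumes[1] - volumes[0])
            out = np.where(lo, costs[0] + slope * (scans - volumes[0]), out)
        if np.any(hi):
            slope = (costs[-1] - costs[-2]) / (volumes[-1] - volumes[-2])
            out = np.where(hi, costs[-1] + slope * (scans - volumes[-1]), out)
    else:  # pragma: no cover - guarded by the Literal type
        raise ValueError(f"unknown cost model {params.model!r}")

    if out.ndim == 0:
        return float(out)
    return out
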