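"""One-way deterministic sensitivity analysis (tornado diagram data).

Each decision-tree parameter — the six chance nodes plus the annual
scan volume driving the per-patient cost — is swept across a plausible
interval while all other parameters stay at their base-case values.
At each interval endpoint the incremental non-responder identification
rate (``delta_nr``, the tree's effectiveness increment) and the ICER
are recomputed.  Sweeping a chance node leaves the cost at base case;
sweeping the scan volume leaves the effectiveness at base case and
re-prices the follow-up via the cost model.

The default node intervals are those of the reference analysis
(half-widths 0.15 for the call probabilities N1/N2 and 0.075 for the
conditional truth probabilities N3–N6, truncated at 1), taken from
confidence intervals of a comparable PET assessment study; the scan
volume interval is one standard deviation around the national annual
volume (5,626 ± 563).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .classify import Endpoint
from .costs import CostParameters, followup_cost
from .tree import ChanceNodeSet, effectiveness

__all__ = [
    "ParameterInterval",
    "TornadoRow",
    "default_intervals",
    "sweep",
    "tornado_extrema",
    "write_tornado_tsv",
    "BASE_ANNUAL_SCANS",
]

#: Base-case annual national scan volume.
BASE_ANNUAL_SCANS = 5626.0

_NODE_NAMES = ("n1", "n2", "n3", "n4", "n5", "n6")

# (low, high) per parameter and decision tree; N1/N2 and the scan
# volume are endpoint-independent.
_INTERVALS: dict[Endpoint, dict[str, tuple[float, float]]] = {
    "os": {
        "n1": (0.2848, 0.5848),
        "n2": (0.5167, 0.8167),
        "n3": (0.9250, 1.0000),
        "n4": (0.6173, 0.7673),
        "n5": (0.6393, 0.7893),
        "n6": (0.3536, 0.5036),
        "annual_scans": (5063.0, 6189.0),
    },
    "pfs": {
        "n1": (0.2848, 0.5848),
        "n2": (0.5167, 0.8167),
        "n3": (0.6250, 0.7750),
        "n4": (0.4635, 0.6135),
        "n5": (0.4250, 0.5750),
        "n6": (0.0679, 0.2179),
        "annual_scans": (5063.0, 6189.0),
    },
}


@dataclass(frozen=True)
class ParameterInterval:
    """A swept parameter with its low/base/high values."""

    parameter: str  # "n1" … "n6" or "annual_scans"
    low: float
    high: float
    base: float

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"{self.parameter}: need low <= base <= high, "
                f"got {self.low} / {self.base} / {self.high}"
            )
        if self.parameter in _NODE_NAMES and not (
            0.0 <= self.low and self.high <= 1.0
        ):
            raise ValueError(f"{self.parameter}: node interval must lie in [0, 1]")


@dataclass(frozen=True)
class TornadoRow:
    """delta_nr and ICER at both endpoints of one parameter sweep."""

    parameter: str
    low: float
    high: float
    delta_at_low: float
    delta_at_high: float
    icer_at_low: float
    icer_at_high: float


def default_intervals(endpoint: Endpoint) -> tuple[ParameterInterval, ...]:
    """The reference sweep intervals for the given decision tree."""
    if endpoint not in _INTERVALS:
        raise ValueError(f"endpoint must be 'os' or 'pfs', got {endpoint!r}")
    table = _INTERVALS[endpoint]
    out = []
    for name, (low, high) in table.items():
        if name == "annual_scans":
            base = BASE_ANNUAL_SCANS
        else:
            # node intervals are symmetric half-widths around the base,
            # except where truncation at 1 made them one-sided (tree 1 N3)
            base = 1.0 if high >= 1.0 else (low + high) / 2.0
        out.append(ParameterInterval(name, low, high, base))
    return tuple(out)


def sweep(
    nodes: ChanceNodeSet,
    cost_params: CostParameters | None = None,
    intervals: Sequence[ParameterInterval] | None = None,
    base_annual_scans: float = BASE_ANNUAL_SCANS,
) -> tuple[TornadoRow, ...]:
    """One-way sweep of every interval around the given base-case nodes."""
    if cost_params is None:
        cost_params = CostParameters()  # piecewise-linear through the anchors
    if intervals is None:
        intervals = default_intervals(nodes.endpoint)

    base_probs = nodes.probabilities()
    base_cost = followup_cost(cost_params, base_annual_scans)
    base_delta = effectiveness(base_probs, nodes.endpoint).delta_nr

    rows = []
    for iv in intervals:
        deltas, icers = [], []
        for value in (iv.low, iv.high):
            if iv.parameter == "annual_scans":
                delta = base_delta
                cost = followup_cost(cost_params, value)
            else:
                probs = dict(base_probs)
                probs[iv.parameter] = value
                delta = effectiveness(probs, nodes.endpoint).delta_nr
                cost = base_cost
            deltas.append(delta)
            icers.append(cost / delta)
        rows.append(
            TornadoRow(
                parameter=iv.parameter,
                low=iv.low,
                high=iv.high,
                delta_at_low=deltas[0],
                delta_at_high=deltas[1],
                icer_at_low=icers[0],
                icer_at_high=icers[1],
            )
        )
    return tuple(rows)


def tornado_extrema(rows: Iterable[TornadoRow]) -> tuple[float, float]:
    """Global (min, max) ICER over all sweep endpoints."""
    icers = [x for r in rows for x in (r.icer_at_low, r.icer_at_high)]
    if not icers:
        raise ValueError("no tornado rows")
    return min(icers), max(icers)


def write_tornado_tsv(rows: Iterable[TornadoRow], path: str | Path) -> None:
    """TSV export suitable for plotting a tornado diagram."""
    lines = ["parameter\tlow\thigh\tdelta_low\tdelta_high\ticer_low\ticer_high"]
    for r in rows:
        lines.append(
            f"{r.parameter}\t{r.low:g}\t{r.high:g}\t"
            f"{r.delta_at_low:.6f}\t{r.delta_at_high:.6f}\t"
            f"{r.icer_at_low:.2f}\t{r.icer_at_high:.2f}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def plot_tornado(rows: Iterable[TornadoRow], base_icer: float, ax=None):
    """Render a tornado diagram (requires matplotlib); returns the axes."""
    import matplotlib.pyplot as plt

    rows = sorted(
        rows, key=lambda r: abs(r.icer_at_high - r.icer_at_low), reverse=True
    )
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * len(rows) + 1))
    labels = [r.parameter.upper() for r in rows]
    for i, r in enumerate(rows):
        lo, hi = sorted((r.icer_at_low, r.icer_at_high))
        ax.barh(i, hi - lo, left=lo, color="#4878a8", height=0.6)
    ax.axvline(base_icer, color="k", lw=1, ls="--")
    ax.set_yticks(range(len(rows)), labels)
    ax.invert_yaxis()
    ax.set_xlabel("ICER (EUR per identified non-responder)")
    return ax
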