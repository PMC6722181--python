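"""Probabilistic sensitivity analysis by Monte Carlo simulation.

All model parameters — the six chance nodes and the annual scan
volume — are sampled jointly and independently from normal
distributions centred on their base-case values.  Per draw the
pipeline is re-evaluated end to end: the follow-up cost from the
sampled scan volume through the cost model, the incremental
non-responder identification rate (``delta_nr``) from the sampled
nodes, and their ratio, the ICER.  The output distribution is
summarised by mean, minimum, maximum and standard deviation.

Node draws are probabilities and must stay in [0, 1].  Two bounding
policies are available:

* ``clip`` (default) — out-of-range draws are set to the nearest
  bound.  For a node whose base value sits *on* a bound (tree 1's N3
  is exactly 1) this leaves about half of the draws at the bound, an
  asymmetry that pulls the mean incremental effectiveness below its
  base-case value.
* ``resample`` — out-of-range draws are redrawn until they land in
  [0, 1] (truncated-normal sampling).

Draws where the incremental effectiveness is non-positive or a
conditional stratum has zero probability are excluded from the ICER
summary and counted.

The standard deviations default to those of the reference analysis:
0.0750 for the call probabilities N1/N2, 0.0375 for the conditional
probabilities N3–N6, and 287 scans for the annual volume
(mean 5,626).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .classify import Endpoint
from .costs import CostParameters, followup_cost
from .tree import ChanceNodeSet

__all__ = [
    "MCConfig",
    "SummaryStats",
    "MCSummary",
    "DEFAULT_NODE_SDS",
    "run_psa",
    "sample_draws",
    "psa_convergence",
    "relative_frequency_histogram",
]

_NODE_NAMES = ("n1", "n2", "n3", "n4", "n5", "n6")

#: Reference standard deviations of the chance nodes.
DEFAULT_NODE_SDS: dict[str, float] = {
    "n1": 0.0750,
    "n2": 0.0750,
    "n3": 0.0375,
    "n4": 0.0375,
    "n5": 0.0375,
    "n6": 0.0375,
}

#: Reference annual scan volume distribution.
DEFAULT_SCANS_MEAN = 5626.0
DEFAULT_SCANS_SD = 287.0


@dataclass(frozen=True)
class MCConfig:
    """Sampling configuration of the probabilistic sensitivity analysis."""

    node_means: dict[str, float]
    node_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NODE_SDS))
    scans_mean: float = DEFAULT_SCANS_MEAN
    scans_sd: float = DEFAULT_SCANS_SD
    draws: int = 10_000
    seed: int = 0
    bounding: Literal["clip", "resample"] = "clip"

    def __post_init__(self) -> None:
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        missing = [k for k in _NODE_NAMES if k not in self.node_means]
        if missing:
            raise ValueError(f"node_means missing {missing}")
        if any(sd < 0 for sd in self.node_sds.values()) or self.scans_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.bounding not in ("clip", "resample"):
            raise ValueError(f"unknown bounding policy {self.bounding!r}")

    @classmethod
    def from_nodes(cls, nodes: ChanceNodeSet, **kwargs) -> "MCConfig":
        """Centre the node distributions on an estimated chance-node set."""
        return cls(node_means=nodes.probabilities(), **kwargs)


@dataclass(frozen=True)
class SummaryStats:
    """Mean / min / max / sample standard deviation of one statistic."""

    mean: float
    minimum: float
    maximum: float
    sd: float

    @classmethod
    def of(cls, values: np.ndarray) -> "SummaryStats":
        return cls(
            mean=float(np.mean(values)),
            minimum=float(np.min(values)),
            maximum=float(np.max(values)),
            sd=float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        )


@dataclass(frozen=True)
class MCSummary:
    """Distribution summaries of cost, delta_nr and ICER over the draws."""

    endpoint: Endpoint
    draws: int
    n_excluded: int
    cost: SummaryStats
    delta_nr: SummaryStats
    icer: SummaryStats

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "endpoint": self.endpoint,
            "draws": self.draws,
            "n_excluded": self.n_excluded,
            **{
                stat: vars(getattr(self, stat))
                for stat in ("cost", "delta_nr", "icer")
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def _bounded_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size: int,
    lo: float,
    hi: float,
    policy: str,
) -> np.ndarray:
    x = rng.normal(mean, sd, size)
    if policy == "clip" or sd == 0.0:
        return np.clip(x, lo, hi)
    out_of_range = (x < lo) | (x > hi)
    while np.any(out_of_range):
        x[out_of_range] = rng.normal(mean, sd, int(out_of_range.sum()))
        out_of_range = (x < lo) | (x > hi)
    return x


def sample_draws(
    config: MCConfig, cost_params: CostParameters | None = None
) -> pd.DataFrame:
    """Per-draw samples and derived quantities as a data frame.

    Columns: the six nodes, ``annual_scans``, ``cost``, ``delta_nr``
    (NaN where a conditional stratum is degenerate) and ``icer``
    (NaN where excluded).
    """
    if cost_params is None:
        cost_params = CostParameters()
    rng = np.random.default_rng(config.seed)

    cols: dict[str, np.ndarray] = {}
    for name in _NODE_NAMES:
        cols[name] = _bounded_normal(
            rng,
            config.node_means[name],
            config.node_sds.get(name, 0.0),
            config.draws,
            0.0,
            1.0,
            config.bounding,
        )
    # scan volumes are bounded below at one scan
    scans = rng.normal(config.scans_mean, config.scans_sd, config.draws)
    cols["annual_scans"] = np.maximum(scans, 1.0)
    cols["cost"] = np.asarray(
        followup_cost(cost_params, cols["annual_scans"]), dtype=float
    ).reshape(config.draws)

    def nr_rate(R, p, q):
        true_nr = (1 - R) * q + R * (1 - p)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(true_nr > 0, (1 - R) * q / true_nr, np.nan)

    pet = nr_rate(cols["n1"], cols["n3"], cols["n4"])
    mri = nr_rate(cols["n2"], cols["n5"], cols["n6"])
    delta = pet - mri
    cols["delta_nr"] = delta
    with np.errstate(divide="ignore", invalid="ignore"):
        cols["icer"] = np.where(delta > 0, cols["cost"] / delta, np.nan)
    return pd.DataFrame(cols)


def run_psa(
    config: MCConfig,
    cost_params: CostParameters | None = None,
    endpoint: Endpoint = "os",
    return_draws: bool = False,
):
    """Run the Monte Carlo analysis and summarise the distributions.

    Fully reproducible for a fixed ``config.seed``.  Returns an
    :class:`MCSummary`, or ``(summary, draws_frame)`` when
    ``return_draws`` is set.
    """
    frame = sample_draws(config, cost_params)
    icer_values = frame["icer"].to_numpy()
    valid = ~np.isnan(icer_values)
    n_excluded = int((~valid).sum())
    if n_excluded == config.draws:
        raise ValueError("all draws degenerate: no positive effectiveness increment")
    delta = frame["delta_nr"].to_numpy()
    summary = MCSummary(
        endpoint=endpoint,
        draws=config.draws,
        n_excluded=n_excluded,
        cost=SummaryStats.of(frame["cost"].to_numpy()),
        delta_nr=SummaryStats.of(delta[~np.isnan(delta)]),
        icer=SummaryStats.of(icer_values[valid]),
    )
    if return_draws:
        return summary, frame
    return summary


def psa_convergence(
    config: MCConfig,
    cost_params: CostParameters | None = None,
    endpoint: Endpoint = "os",
    batch_sizes: Sequence[int] = (100, 1_000, 10_000),
) -> pd.DataFrame:
    """Mean ICER and its standard error at increasing numbers of draws.

    The standard error of the mean shrinks like 1/sqrt(draws); the
    table makes the Monte Carlo error at a given budget explicit.
    """
    records = []
    for n in batch_sizes:
        summary = run_psa(replace(config, draws=int(n)), cost_params, endpoint)
        kept = summary.draws - summary.n_excluded
        records.append(
            {
                "draws": int(n),
                "mean_icer": summary.icer.mean,
                "sd_icer": summary.icer.sd,
                "se_mean_icer": summary.icer.sd / np.sqrt(kept),
            }
        )
    return pd.DataFrame.from_records(records)


def relative_frequency_histogram(
    values: np.ndarray | pd.Series, bins: int = 40
) -> pd.DataFrame:
    """Histogram of a sampled statistic as relative frequencies."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    counts, edges = np.histogram(values, bins=bins)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "relative_frequency": counts / counts.sum(),
        }
    )
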