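"""Full-analysis orchestration.

Runs classification, chance-node estimation, effectiveness, ICERs,
one-way deterministic sensitivity analysis and Monte Carlo
probabilistic sensitivity analysis for one or both clinical endpoints,
and bundles everything into a single machine-readable report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import yaml

from .cea import IcerResult, full_cea
from .classify import ClassifiedPatient, Endpoint, classify_cohort, write_classification
from .cohort import Cohort, builtin_table1, read_cohort
from .costs import CostParameters
from .oneway import (
    BASE_ANNUAL_SCANS,
    TornadoRow,
    default_intervals,
    sweep,
    tornado_extrema,
    write_tornado_tsv,
)
from .psa import MCConfig, MCSummary, run_psa
from .tree import ChanceNodeSet, TreeEffectiveness, effectiveness, estimate_chance_nodes

__all__ = ["PipelineConfig", "EndpointReport", "RunReport", "run_full", "load_config"]

logger = logging.getLogger("fetcea")

ENDPOINTS: tuple[Endpoint, ...] = ("os", "pfs")


@dataclass(frozen=True)
class PipelineConfig:
    """Flat configuration of a full pipeline run."""

    endpoints: tuple[Endpoint, ...] = ENDPOINTS
    cost_model: str = "fixed"  # deterministic stages price at the fixed base cost
    sweep_cost_model: str = "piecewise_linear"  # scan-volume sweep needs a curve
    base_annual_scans: float = BASE_ANNUAL_SCANS
    mc_draws: int = 10_000
    mc_bounding: str = "clip"
    seed: int = 0
    write_draws: bool = False

    def cost_parameters(self, model: str | None = None) -> CostParameters:
        return CostParameters(model=model or self.cost_model)  # type: ignore[arg-type]

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["endpoints"] = list(self.endpoints)
        return d

    @property
    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a flat YAML mapping of config keys; missing keys keep defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a flat mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "endpoints" in raw:
        raw["endpoints"] = tuple(raw["endpoints"])
    return PipelineConfig(**raw)


@dataclass(frozen=True)
class EndpointReport:
    """All results for one clinical endpoint (one decision tree)."""

    endpoint: Endpoint
    nodes: ChanceNodeSet
    effectiveness: TreeEffectiveness
    icer: IcerResult
    tornado: tuple[TornadoRow, ...]
    tornado_min_icer: float
    tornado_max_icer: float
    psa: MCSummary


@dataclass(frozen=True)
class RunReport:
    """Results for every analysed endpoint plus run provenance."""

    cohort_size: int
    classified: tuple[ClassifiedPatient, ...]
    endpoints: dict[Endpoint, EndpointReport]
    config: PipelineConfig

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "provenance": {
                "config": self.config.to_dict(),
                "config_hash": self.config.digest,
                "seed": self.config.seed,
            },
            "cohort_size": self.cohort_size,
            "endpoints": {},
        }
        for ep, rep in self.endpoints.items():
            out["endpoints"][ep] = {
                "chance_nodes": json.loads(rep.nodes.to_json()),
                "effectiveness": dataclasses.asdict(rep.effectiveness),
                "icer": dataclasses.asdict(rep.icer),
                "tornado": [dataclasses.asdict(r) for r in rep.tornado],
                "tornado_extrema": {
                    "min_icer": rep.tornado_min_icer,
                    "max_icer": rep.tornado_max_icer,
                },
                "psa": json.loads(rep.psa.to_json()),
            }
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def _load_cohort(source: str | Path | Cohort | None) -> Cohort:
    if source is None:
        return builtin_table1()
    if isinstance(source, Cohort):
        return source
    return read_cohort(source)


def analyse_endpoint(
    classified: Sequence[ClassifiedPatient],
    endpoint: Endpoint,
    config: PipelineConfig,
) -> EndpointReport:
    """Run every analysis stage for one decision tree."""
    logger.info("[%s] estimating chance nodes", endpoint)
    nodes = estimate_chance_nodes(tuple(classified), endpoint)
    eff = effectiveness(nodes)
    logger.info(
        "[%s] delta_nr=%.4f delta_accuracy=%.4f", endpoint, eff.delta_nr,
        eff.delta_accuracy,
    )
    icer_result = full_cea(
        tuple(classified), endpoint, config.cost_parameters(), eff=eff
    )
    logger.info(
        "[%s] ICER %.2f EUR per identified non-responder", endpoint,
        icer_result.icer_per_nonresponder,
    )
    rows = sweep(
        nodes,
        config.cost_parameters(config.sweep_cost_model),
        default_intervals(endpoint),
        config.base_annual_scans,
    )
    lo, hi = tornado_extrema(rows)
    logger.info("[%s] one-way ICER range %.2f - %.2f EUR", endpoint, lo, hi)
    mc_config = MCConfig.from_nodes(
        nodes,
        draws=config.mc_draws,
        seed=config.seed,
        bounding=config.mc_bounding,  # type: ignore[arg-type]
    )
    psa_summary = run_psa(
        mc_config, config.cost_parameters(config.sweep_cost_model), endpoint
    )
    logger.info(
        "[%s] PSA mean ICER %.0f EUR over %d draws", endpoint,
        psa_summary.icer.mean, psa_summary.draws,
    )
    return EndpointReport(
        endpoint=endpoint,
        nodes=nodes,
        effectiveness=eff,
        icer=icer_result,
        tornado=rows,
        tornado_min_icer=lo,
        tornado_max_icer=hi,
        psa=psa_summary,
    )


def run_full(
    cohort_source: str | Path | Cohort | None = None,
    config: PipelineConfig | None = None,
    output_dir: str | Path | None = None,
) -> RunReport:
    """Execute the complete analysis; optionally write all output files.

    ``cohort_source`` may be a cohort CSV path, an in-memory cohort, or
    ``None`` for the built-in reference cohort.  When ``output_dir`` is
    given, writes ``report.json``, ``classification.csv``,
    ``tornado_<endpoint>.tsv`` and ``psa_<endpoint>.json``; on failure
    any partially written outputs are removed.
    """
    config = config or PipelineConfig()
    cohort = _load_cohort(cohort_source)
    logger.info("cohort of %d patients loaded", len(cohort))
    classified = classify_cohort(cohort)

    report = RunReport(
        cohort_size=len(cohort),
        classified=classified,
        endpoints={
            ep: analyse_endpoint(classified, ep, config) for ep in config.endpoints
        },
        config=config,
    )

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            path = out / "report.json"
            report.to_json(path)
            written.append(path)
            path = out / "classification.csv"
            write_classification(classified, path)
            written.append(path)
            for ep, rep in report.endpoints.items():
                path = out / f"tornado_{ep}.tsv"
                write_tornado_tsv(rep.tornado, path)
                written.append(path)
                path = out / f"psa_{ep}.json"
                rep.psa.to_json(path)
                written.append(path)
        except Exception:
            for p in written:
                p.unlink(missing_ok=True)
            raise
        logger.info("wrote %d output files to %s", len(written), out)
    return report
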