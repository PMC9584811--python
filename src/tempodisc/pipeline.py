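"""End-to-end pipeline: simulate -> qc -> score -> aggregate.

Every run writes a manifest recording the seed, a hash of the resolved
configuration and the package version, so artifacts can be traced back to
the exact run that produced them.  JSON artifacts embed the same metadata;
the CSV tables are kept metadata-free so that write-then-read is the
identity on valid tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import (
    meta_regression,
    proportion_meta,
    random_effects_meta,
    summarize_countries,
    variance_partition,
)
from .agents import InjectionRates, PopulationConfig, sample_population, simulate_study
from .io import (
    read_country_table,
    read_responses,
    write_json,
    write_responses,
    write_scored,
)
from .qc import apply_exclusions
from .scoring import ANOMALY_FLAGS, score_table, standardize

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "demo_country_table"]

log = logging.getLogger("tempodisc")


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "tempodisc_run"
    seed: int = 0
    country_table: str | None = None  # None -> bundled demo table
    responses: str | None = None  # existing response CSV; None -> simulate
    n_per_country: int = 200
    skip_qc: bool = False
    rule_variant: str = "example"
    injection: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def demo_country_table() -> Path:
    """Path to the bundled five-country demo anchor table."""
    return Path(resources.files("tempodisc") / "data" / "demo_countries.yaml")


def _aggregate(scored: pd.DataFrame, anchors_df: pd.DataFrame) -> dict:
    summary = summarize_countries(scored, anchors_df)
    result: dict = {"countries": summary.to_dict("records")}
    if len(summary) >= 2:
        var = summary["sd_score"] ** 2 / summary["n"]
        meta = random_effects_meta(summary["mean_score"], var)
        result["score_meta"] = meta.to_dict()
        result["anomaly_meta"] = {
            flag: proportion_meta(
                summary[f"count_{flag}"], summary["n"]
            ).to_dict()
            for flag in ANOMALY_FLAGS
        }
        vp = variance_partition(
            scored["discounting_score"].to_numpy(), scored["country_id"].to_numpy()
        )
        result["variance_partition"] = {
            "between": vp.between,
            "within": vp.within,
            "intraclass_share": vp.intraclass_share,
        }
        moderators = summary[["gini", "log_gdp_pc", "inflation_rate"]].dropna(axis=1)
        varying = [c for c in moderators.columns if moderators[c].nunique() > 1]
        if len(summary) >= len(varying) + 2 and varying:
            reg = meta_regression(summary["mean_score"], var, moderators[varying])
            result["meta_regression"] = reg.to_dict()
    return result, summary


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the pipeline and write all artifacts under ``out_dir``.

    Returns a mapping from artifact name to path.  Any stage failure is
    re-raised as :class:`PipelineError` naming the stage.
    """
    artifacts: dict[str, Path] = {}
    try:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table = (
            Path(config.country_table) if config.country_table else demo_country_table()
        )
        anchors = read_country_table(table)
        anchors_df = pd.DataFrame(
            {
                "country_id": [a.country_id for a in anchors],
                "gini": [a.gini for a in anchors],
                "log_gdp_pc": [a.log_gdp_pc for a in anchors],
                "inflation_rate": [a.inflation_rate for a in anchors],
            }
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("config", str(exc)) from exc

    rng = np.random.default_rng(config.seed)
    try:
        if config.responses is not None:
            responses = read_responses(config.responses)
            log.info("loaded %d responses from %s", len(responses), config.responses)
        else:
            pop_config = PopulationConfig(
                n_per_country=config.n_per_country,
                injection=InjectionRates(**config.injection),
                **config.population,
            )
            population = sample_population(pop_config, anchors, rng)
            responses, truth = simulate_study(population, rng, pop_config.injection)
            truth_path = out_dir / "truth.csv"
            truth.to_csv(truth_path, index=False)
            artifacts["truth"] = truth_path
            log.info("simulated %d respondents", len(responses))
        responses_path = out_dir / "responses.csv"
        write_responses(responses, responses_path)
        artifacts["responses"] = responses_path
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    try:
        if config.skip_qc:
            retained, report = responses, None
        else:
            retained, report = apply_exclusions(responses)
            qc_path = out_dir / "qc_report.json"
            payload = report.to_dict()
            payload["_meta"] = _meta(config)
            write_json(payload, qc_path)
            artifacts["qc_report"] = qc_path
            log.info(
                "qc retained %d of %d records", report.n_retained, report.n_input
            )
        if retained.empty:
            raise ValueError("no records retained after quality control")
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc

    try:
        scored = score_table(retained, variant=config.rule_variant)
        scored["z_score"] = standardize(scored["discounting_score"])
        scored_path = out_dir / "scored.csv"
        write_scored(scored, scored_path)
        artifacts["scored"] = scored_path
        log.info("scored %d respondents", len(scored))
    except Exception as exc:
        raise PipelineError("score", str(exc)) from exc

    try:
        result, summary = _aggregate(scored, anchors_df)
        result["_meta"] = _meta(config)
        agg_path = out_dir / "aggregate.json"
        write_json(result, agg_path)
        artifacts["aggregate"] = agg_path
        summary_path = out_dir / "country_summary.csv"
        summary.to_csv(summary_path, index=False)
        artifacts["country_summary"] = summary_path
    except Exception as exc:
        raise PipelineError("aggregate", str(exc)) from exc

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "version": __version__,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    manifest_path = out_dir / "manifest.json"
    write_json(manifest, manifest_path)
    artifacts["manifest"] = manifest_path
    return artifacts


def _meta(config: RunConfig) -> dict:
    return {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
    }
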