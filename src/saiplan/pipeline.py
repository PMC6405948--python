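"""End-to-end orchestration: data → VIF screen → importance → optimal → SAI.

A single YAML config drives the run. It must contain either a ``synthetic``
block (landscape generated in-package) or an ``inputs`` block naming the
occurrence, covariate and threatened-species CSVs. One master ``seed`` feeds
every stage through named substreams, so reruns of an unchanged config
produce byte-identical outputs.

Stages
------
1. ``data``        simulate or ingest + validate the three tables
2. ``encode``      indicator-encode categorical covariates
3. ``vif``         iterative collinearity reduction (threshold 3)
4. ``importance``  random-forest ensemble for threatened presence + the
                   soil-carbon ANOVA/Tukey group comparison
5. ``optimal``     greedy complementarity selection of priority plots
6. ``surrogacy``   paired SAI curves for soil carbon alone / abiotic /
                   abiotic + soil carbon
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from ._rng import spawn_int
from .collinearity import DEFAULT_VIF_THRESHOLD, reduce_collinearity
from .importance import fit_presence_ensemble, soil_carbon_group_test, summarize_importance
from .io import CovariateTable, OccurrenceMatrix, encode_covariates, read_covariates, read_occurrence
from .selection import greedy_richness_selection
from .surrogacy import EvaluationConfig, compare_surrogates
from .synthetic import SyntheticConfig, generate_landscape, write_landscape

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "DataError", "RunManifest", "load_config", "run_pipeline"]


class ConfigError(ValueError):
    """Schema-invalid or incomplete pipeline configuration."""


class DataError(ValueError):
    """Input data failed validation."""


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    version: str
    master_seed: int
    stage_seeds: dict[str, int] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    output_digests: dict[str, str] = field(default_factory=dict)
    wall_clock: dict[str, float] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_config(source: str | Path | dict) -> dict:
    if isinstance(source, dict):
        cfg = dict(source)
    else:
        cfg = yaml.safe_load(Path(source).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a mapping")
    if ("synthetic" in cfg) == ("inputs" in cfg):
        raise ConfigError("config needs exactly one of a 'synthetic' or an 'inputs' block")
    cfg.setdefault("seed", 0)
    return cfg


def _stage_data(cfg: dict, outdir: Path, manifest: RunManifest):
    if "synthetic" in cfg:
        try:
            syn = SyntheticConfig(**{**cfg["synthetic"], "seed": manifest.stage_seeds["data"]})
        except TypeError as exc:
            raise ConfigError(f"bad synthetic block: {exc}") from None
        landscape = generate_landscape(syn)
        paths = write_landscape(landscape, outdir / "data")
        for name, p in paths.items():
            manifest.outputs[f"data/{name}"] = str(p)
        return landscape.occurrence, landscape.covariates
    inputs = cfg["inputs"]
    for key in ("occurrence", "covariates", "threatened"):
        if key not in inputs:
            raise ConfigError(f"inputs block missing {key!r}")
        p = Path(inputs[key])
        if not p.exists():
            raise ConfigError(f"input file not found: {p}")
        manifest.input_digests[key] = _digest(p)
    occurrence = read_occurrence(inputs["occurrence"], inputs["threatened"])
    covariates = read_covariates(inputs["covariates"], inputs.get("soil_carbon_name", "soil_carbon"))
    if not occurrence.plot_ids.equals(covariates.plot_ids):
        raise DataError("occurrence and covariate tables disagree on plot IDs")
    return occurrence, covariates


def run_pipeline(config: str | Path | dict, outdir: str | Path) -> RunManifest:
    """Execute all stages; write JSON results plus ``manifest.json`` under ``outdir``."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(
        config=cfg,
        version=__version__,
        master_seed=seed,
        stage_seeds={
            stage: spawn_int(seed, "stage", stage)
            for stage in ("data", "importance", "surrogacy")
        },
    )

    def timed(stage, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except (ConfigError, DataError):
            raise
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.wall_clock[stage] = round(time.perf_counter() - t0, 3)
        return result

    occurrence, covariates = timed("data", lambda: _stage_data(cfg, outdir, manifest))
    if not occurrence.threatened_ids:
        raise DataError("no threatened species flagged; nothing to prioritize")

    encoded = timed("encode", lambda: encode_covariates(covariates))

    threshold = float(cfg.get("vif", {}).get("threshold", DEFAULT_VIF_THRESHOLD))
    report = timed("vif", lambda: reduce_collinearity(encoded, threshold=threshold))
    _dump_json(report.to_dict(), outdir / "vif_report.json")
    manifest.outputs["vif"] = str(outdir / "vif_report.json")
    retained = CovariateTable(
        encoded.data[report.retained]
        if encoded.soil_carbon_name in report.retained
        else encoded.data[[encoded.soil_carbon_name] + report.retained],
        soil_carbon_name=encoded.soil_carbon_name,
    )

    imp_cfg = cfg.get("importance", {})
    presence = (occurrence.data.loc[:, occurrence.threatened_mask.to_numpy()].sum(axis=1) >= 1).astype(int)

    def _importance():
        ensemble = fit_presence_ensemble(
            retained,
            presence,
            n_runs=int(imp_cfg.get("n_runs", 20)),
            train_fraction=float(imp_cfg.get("train_fraction", 0.7)),
            seed=manifest.stage_seeds["importance"],
        )
        counts = occurrence.data.loc[:, occurrence.threatened_mask.to_numpy()].sum(axis=1)
        group = soil_carbon_group_test(retained.data[retained.soil_carbon_name], counts)
        return ensemble, group

    ensemble, group = timed("importance", _importance)
    _dump_json(
        {**ensemble.to_dict(), "summary": summarize_importance(ensemble).to_dict(orient="index")},
        outdir / "importance.json",
    )
    _dump_json(group.to_dict(), outdir / "group_test.json")
    manifest.outputs["importance"] = str(outdir / "importance.json")
    manifest.outputs["group_test"] = str(outdir / "group_test.json")

    selection = timed("optimal", lambda: greedy_richness_selection(occurrence, occurrence.threatened_ids))
    _dump_json(selection.to_dict(), outdir / "selection.json")
    manifest.outputs["optimal"] = str(outdir / "selection.json")

    sur_cfg = cfg.get("surrogacy", {})
    soc = retained.soil_carbon_name
    abiotic = [v for v in retained.variables if v != soc]
    variable_sets = sur_cfg.get(
        "variable_sets",
        {"soil_carbon": [soc], "abiotic": abiotic, "abiotic_plus_soil_carbon": abiotic + [soc]},
    )
    eval_cfg = EvaluationConfig(
        q_values=tuple(sur_cfg.get("q_values", EvaluationConfig.q_values)),
        n_models=int(sur_cfg.get("n_models", 100)),
        n_random=int(sur_cfg.get("n_random", 1000)),
        n_trees=int(sur_cfg.get("n_trees", 500)),
        sai_variant=sur_cfg.get("sai_variant", "range_consistent"),
        site_budget=sur_cfg.get("site_budget"),
        surrogate_variables=tuple(next(iter(variable_sets.values()))),
        seed=manifest.stage_seeds["surrogacy"],
    )
    comparison = timed(
        "surrogacy", lambda: compare_surrogates(occurrence, retained, variable_sets, eval_cfg)
    )
    _dump_json(comparison.to_dict(), outdir / "sai_curves.json")
    manifest.outputs["surrogacy"] = str(outdir / "sai_curves.json")

    for key, p in manifest.outputs.items():
        manifest.output_digests[key] = _digest(Path(p))
    manifest.write(outdir / "manifest.json")
    return manifest
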