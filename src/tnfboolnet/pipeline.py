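"""Configuration-driven orchestration: filter -> enrich -> scenarios -> scan.

The config is a strict-schema YAML file; unknown keys are rejected so a
typo in a threshold name cannot silently fall back to a default.  Every
stage is optional: a config without a secretome runs model-only, one
without a model runs enrichment-only.  All results go to files under the
output directory; a markdown summary names each artifact written.  Given
identical inputs, re-running produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import enrichment as enr
from .dynamics import Perturbation, attractors_to_json, attractors_to_tsv
from .model import (
    PHENOTYPE_NODES,
    ScenarioSpec,
    load_paper_model,
    perturbation_scan,
    run_scenario,
)
from .network import parse_rules

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_SCENARIO_GRID = [
    {"macrophage": 0, "tnf": 0},
    {"macrophage": 0, "tnf": 1},
    {"macrophage": 1, "tnf": 0},
    {"macrophage": 1, "tnf": 1},
]


class ConfigError(ValueError):
    """Schema violation in a pipeline config."""


@dataclass
class PipelineConfig:
    out_dir: Path
    secretome: Path | None = None
    libraries: list[Path] = field(default_factory=list)
    threshold: float = enr.INTENSITY_THRESHOLD
    universe: int = enr.DEFAULT_UNIVERSE
    model: Path | None = None  # None -> packaged model
    scenarios: list[dict] = field(default_factory=lambda: [dict(s) for s in DEFAULT_SCENARIO_GRID])
    perturbation_candidates: list[str] = field(default_factory=list)
    seed: int = 0
    run_model: bool = True


_SCHEMA = {
    "out_dir": str,
    "secretome": str,
    "libraries": list,
    "threshold": (int, float),
    "universe": int,
    "model": str,
    "scenarios": list,
    "perturbation_candidates": list,
    "seed": int,
    "run_model": bool,
}


def _build_config(raw: dict, base: Path) -> PipelineConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError("unknown config key(s): " + ", ".join(sorted(unknown)))
    for key, expected in _SCHEMA.items():
        if key not in raw:
            continue
        value = raw[key]
        bad_bool = isinstance(value, bool) and expected is not bool
        if bad_bool or not isinstance(value, expected):
            raise ConfigError(
                f"config key {key!r} has invalid type {type(value).__name__}"
            )

    cfg = PipelineConfig(out_dir=base / raw.get("out_dir", "results"))
    if "secretome" in raw:
        cfg.secretome = base / raw["secretome"]
    cfg.libraries = [base / p for p in raw.get("libraries", [])]
    if "threshold" in raw:
        cfg.threshold = float(raw["threshold"])
    if "universe" in raw:
        cfg.universe = int(raw["universe"])
    if "model" in raw:
        cfg.model = base / raw["model"]
    if "scenarios" in raw:
        cfg.scenarios = []
        for i, cell in enumerate(raw["scenarios"]):
            if not isinstance(cell, dict) or set(cell) - {"macrophage", "tnf", "clamps"}:
                raise ConfigError(f"scenarios[{i}] must map macrophage/tnf (and optional clamps)")
            if cell.get("macrophage") not in (0, 1) or cell.get("tnf") not in (0, 1):
                raise ConfigError(f"scenarios[{i}]: macrophage and tnf must be 0 or 1")
            cfg.scenarios.append(cell)
    cfg.perturbation_candidates = [str(c) for c in raw.get("perturbation_candidates", [])]
    cfg.seed = int(raw.get("seed", 0))
    cfg.run_model = bool(raw.get("run_model", True))
    return cfg


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default and validate a YAML pipeline config.

    Relative paths inside the file resolve against the file's directory.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    cfg = _build_config(raw or {}, path.parent)
    for p in [cfg.secretome, cfg.model, *cfg.libraries]:
        if p is not None and not p.exists():
            raise ConfigError(f"input file not found: {p}")
    return cfg


def _scenario_name(cell: dict) -> str:
    name = f"m{cell['macrophage']}_tnf{cell['tnf']}"
    clamps = cell.get("clamps") or {}
    for node in sorted(clamps):
        name += f"_{node}{clamps[node]}"
    return name


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns a manifest of written outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    summary_lines = ["# Pipeline summary", ""]

    query: list[str] | None = None
    if config.secretome is not None:
        table = enr.read_secretome(config.secretome)
        query = enr.filter_secretome(table, config.threshold)
        path = out / "filtered_secretome.txt"
        enr.write_analyte_list(query, path)
        written.append(path.name)
        summary_lines.append(
            f"- Secretome filter (> {config.threshold}): kept {len(query)} of "
            f"{len(table)} analytes -> `{path.name}`"
        )
        for lib_path in config.libraries:
            library = enr.read_gmt(lib_path, universe=config.universe)
            results = enr.enrich(query, library)
            dest = out / f"enrichment_{lib_path.stem}.tsv"
            enr.write_results_tsv(results, dest)
            written.append(dest.name)
            n_sig = sum(r.significant for r in results)
            summary_lines.append(
                f"- Enrichment vs `{lib_path.name}` ({len(library)} terms, "
                f"universe {config.universe}): {n_sig} significant -> `{dest.name}`"
            )

    if config.run_model:
        if config.model is not None:
            net = parse_rules(Path(config.model).read_text())
        else:
            net = load_paper_model()
        for cell in config.scenarios:
            clamps = cell.get("clamps") or {}
            spec = ScenarioSpec(cell["macrophage"], cell["tnf"], Perturbation(clamps))
            result = run_scenario(net, spec)
            name = _scenario_name(cell)
            payload = {
                "scenario": {"macrophage": spec.macrophage, "tnf": spec.tnf, "clamps": clamps},
                "n_states": result.n_states,
                "n_attractors": len(result.attractors),
                "phenotype": result.phenotype,
                "attractors": json.loads(attractors_to_json(result.attractors)),
            }
            dest = out / f"scenario_{name}.json"
            dest.write_text(json.dumps(payload, indent=2) + "\n")
            written.append(dest.name)
            pheno = ", ".join(f"{k}={v}" for k, v in result.phenotype.items())
            summary_lines.append(f"- Scenario {name}: {pheno} -> `{dest.name}`")
        if config.perturbation_candidates:
            base = ScenarioSpec(1, 0)
            rows = perturbation_scan(net, base, config.perturbation_candidates)
            dest = out / "perturbation_scan.tsv"
            header = ["node", "clamp", "n_attractors", *PHENOTYPE_NODES]
            lines = ["\t".join(header)]
            for row in rows:
                lines.append("\t".join(str(row[h]) for h in header))
            dest.write_text("\n".join(lines) + "\n")
            written.append(dest.name)
            summary_lines.append(
                f"- Perturbation scan at (Macrophage=1, TNF=0) over "
                f"{len(config.perturbation_candidates)} node(s) -> `{dest.name}`"
            )

    summary = out / "summary.md"
    summary.write_text("\n".join(summary_lines) + "\n")
    written.append(summary.name)
    logger.info("pipeline wrote %d file(s) to %s", len(written), out)
    return {"out_dir": str(out), "files": written}


def write_attractor_reports(attractors, out_dir: Path, stem: str) -> list[Path]:
    """JSON + TSV attractor reports (shared by the CLI subcommands)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    j = out_dir / f"{stem}.json"
    j.write_text(attractors_to_json(attractors))
    t = out_dir / f"{stem}.tsv"
    t.write_text(attractors_to_tsv(attractors))
    paths.extend([j, t])
    return paths
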