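"""Declarative run configuration (YAML/JSON) and the end-to-end pipeline.

A run config names the inputs, the screening filters of the scenario matrix,
the benefit fields, the classification schemes, the α policy, and k. All
referenced paths and fields are resolved before any computation starts, so a
misconfigured run fails fast instead of after minutes of scenario work. No
behavior hides in environment variables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .compare import ComparisonReport, compare_topk
from .io import load_classification, load_country_table, load_threat_layers, write_results
from .models import ClassificationScheme, ConfigurationError, CountryRecord, ThreatLayerTable
from .scenarios import ScenarioResult, build_matrix, run_all, shared_alphas
from .screening import ConjunctionRule, FilterRule, compose_rules, rule_from_dict
from .threats import compute_alpha, summarize_threats

log = logging.getLogger(__name__)

#: The shipped default scenario design: four debt-to-GDP filters × two
#: benefits × two shipping classifications, k = 10.
PAPER_DEFAULT_FILTERS: list[list[dict] | None] = [
    None,
    [{"field": "debt_to_gdp", "op": "ge", "threshold": 0.4}],
    [{"field": "debt_to_gdp", "op": "ge", "threshold": 0.6}],
    [{"field": "debt_to_gdp", "op": "ge", "threshold": 0.8}],
]
PAPER_DEFAULT_BENEFITS = ["eez_area_km2", "coral_area_km2"]


@dataclass
class RunConfig:
    countries_path: str
    threats_path: str
    scheme_paths: list[str]
    out_dir: str
    threats_layout: str = "wide"
    debt_as_percent: bool = False
    #: each filter: None (no screening) or a list of rule dicts (conjunction)
    filters: list[list[dict] | None] = field(default_factory=lambda: PAPER_DEFAULT_FILTERS)
    benefit_fields: list[str] = field(default_factory=lambda: list(PAPER_DEFAULT_BENEFITS))
    alpha_policy: str = "pool_max_reciprocal"
    alpha_fixed_value: float | None = None
    alpha_scope: str = "shared"  # "shared" | "per_scenario"
    p_source: str = "constant_one"
    c_source: str = "constant_one"
    top_k: int = 10
    seed: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        text = path.read_text()
        payload = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(payload, dict):
            raise ConfigurationError(f"config {path} must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        missing = [k for k in ("countries_path", "threats_path", "scheme_paths", "out_dir")
                   if k not in payload]
        if missing:
            raise ConfigurationError(f"config missing required key(s): {missing}")
        base = path.parent
        cfg = cls(**payload)
        cfg.countries_path = str((base / cfg.countries_path))
        cfg.threats_path = str((base / cfg.threats_path))
        cfg.scheme_paths = [str(base / p) for p in cfg.scheme_paths]
        cfg.out_dir = str(base / cfg.out_dir)
        return cfg

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _build_filters(specs: list[list[dict] | None]) -> list[FilterRule | ConjunctionRule | None]:
    filters: list[FilterRule | ConjunctionRule | None] = []
    for spec in specs:
        if spec is None:
            filters.append(None)
        else:
            rules = [rule_from_dict(d) for d in spec]
            filters.append(rules[0] if len(rules) == 1 else compose_rules(rules))
    return filters


@dataclass
class RunOutput:
    countries: list[CountryRecord]
    layers: ThreatLayerTable
    schemes: dict[str, ClassificationScheme]
    results: list[ScenarioResult]
    report: ComparisonReport | None
    manifest: dict


def execute_run(config: RunConfig, write: bool = True) -> RunOutput:
    """validate → screen → matrix → score → compare → (optionally) write.

    Validation is fail-fast: inputs are loaded and every benefit field and
    scheme checked against them before the first scenario runs. The
    comparison step is skipped with a warning if fewer than two scenarios can
    fill a top-k set.
    """
    countries = load_country_table(config.countries_path, percent=config.debt_as_percent)
    layers = load_threat_layers(config.threats_path, layout=config.threats_layout)
    scheme_list = [load_classification(p) for p in config.scheme_paths]
    schemes = {s.scheme_id: s for s in scheme_list}
    if len(schemes) != len(scheme_list):
        raise ConfigurationError("duplicate scheme_id among scheme files")
    for s in scheme_list:
        s.validate_covers(layers.layer_names)
    table_countries = set(layers.country_ids)
    missing_threat = [c.country_id for c in countries if c.country_id not in table_countries]
    if missing_threat:
        raise ConfigurationError(
            f"countries without threat-layer rows: {missing_threat[:5]}"
        )
    for bf in config.benefit_fields:
        absent = [c.country_id for c in countries if bf not in c.benefits]
        if absent:
            raise ConfigurationError(f"benefit field {bf!r} absent for {absent[:5]}")

    filters = _build_filters(config.filters)
    specs = build_matrix(
        filters,
        config.benefit_fields,
        scheme_list,
        alpha_policy=config.alpha_scope,
        p_source=config.p_source,
        c_source=config.c_source,
        top_k=config.top_k,
    )

    alphas = None
    if config.alpha_scope == "shared":
        if config.alpha_policy == "fixed":
            ids = [c.country_id for c in countries]
            alphas = {
                s.scheme_id: compute_alpha(
                    summarize_threats(layers, s, ids),
                    policy="fixed",
                    fixed_value=config.alpha_fixed_value,
                    pool_id=f"full-pool/{s.scheme_id}",
                )
                for s in scheme_list
            }
        else:
            alphas = shared_alphas(countries, layers, scheme_list)
        for sid, a in alphas.items():
            log.info("shared alpha for scheme %s: %.6g", sid, a.value)

    results = run_all(specs, countries, layers, schemes, alphas)
    for res in results:
        log.info(
            "scenario %s: pool=%d alpha=%.6g top-%d=%s",
            res.scenario_id, res.pool_size, res.alpha_used,
            min(config.top_k, res.pool_size), sorted(res.top_set(config.top_k)),
        )
    try:
        report = compare_topk(results, config.top_k)
    except ConfigurationError as err:
        log.warning("comparison skipped: %s", err)
        report = None
    manifest = (
        write_results(results, report, config.out_dir, config=config.to_dict(), seed=config.seed)
        if write
        else {}
    )
    return RunOutput(
        countries=countries, layers=layers, schemes=schemes,
        results=results, report=report, manifest=manifest,
    )
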