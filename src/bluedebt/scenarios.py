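"""Scenario-matrix construction and execution.

A scenario is one cell of the Cartesian product

    enabling-condition filter  x  benefit metric  x  threat classification

mirroring the shipped default design: four debt-to-GDP filters (none, >=40%,
>=60%, >=80%), two benefits (EEZ area, coral-reef area) and two threat
classifications (shipping abatable vs. shipping unabatable) — 16 scenarios.
Each scenario screens the candidate pool, summarizes threats under its
scheme, scores with Eq.-style cost-effectiveness and ranks; the top-k set of
each ranked list is what the robustness comparison consumes.

By default α is shared: one α per classification scheme, derived over the
FULL candidate pool before any filtering, so a country's (I_a, I_u, discount)
triple is identical in every scenario using the same scheme and expected
benefits stay comparable across filters. (A single α across *different*
schemes is not used: the scheme with the larger max I_u would breach the
non-negativity rule.) A per-scenario recomputation switch is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .models import (
    AlphaParameter,
    ClassificationScheme,
    ConfigurationError,
    CountryRecord,
    PrioritizationError,
    ThreatLayerTable,
)
from .scoring import ScoredCandidate, rank_pool, score_pool
from .screening import ConjunctionRule, FilterRule, apply_rule
from .threats import compute_alpha, summarize_threats

log = logging.getLogger(__name__)


@dataclass
class ScenarioSpec:
    """Definition of one scenario (one cell of the matrix)."""

    scenario_id: str
    filter: FilterRule | ConjunctionRule | None
    benefit_field: str
    scheme_id: str
    alpha_policy: str = "shared"  # "shared" | "per_scenario"
    p_source: str = "constant_one"  # "constant_one" | "column"
    c_source: str = "constant_one"
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ConfigurationError(f"top_k must be >= 1, got {self.top_k}")
        for attr in ("p_source", "c_source"):
            if getattr(self, attr) not in ("constant_one", "column"):
                raise ConfigurationError(f"{attr} must be 'constant_one' or 'column'")
        if self.alpha_policy not in ("shared", "per_scenario"):
            raise ConfigurationError("alpha_policy must be 'shared' or 'per_scenario'")


@dataclass
class ScenarioResult:
    """Ranked, scored candidate list for one scenario."""

    scenario_id: str
    scheme_id: str
    alpha_used: float
    pool_size: int
    scored: list[ScoredCandidate] = field(default_factory=list)

    @property
    def top_k_set(self) -> set[str]:
        return set(c.country_id for c in self.scored[: self._top_k])

    def top_set(self, k: int) -> set[str]:
        """IDs of the first min(k, pool_size) ranked candidates."""
        return set(c.country_id for c in self.scored[:k])

    _top_k: int = 10


def _filter_label(rule: FilterRule | ConjunctionRule | None) -> str:
    return "all" if rule is None else rule.label


def build_matrix(
    filters: list[FilterRule | ConjunctionRule | None],
    benefit_fields: list[str],
    schemes: list[ClassificationScheme],
    alpha_policy: str = "shared",
    p_source: str = "constant_one",
    c_source: str = "constant_one",
    top_k: int = 10,
) -> list[ScenarioSpec]:
    """Cartesian product of filters × benefits × schemes, deterministic order.

    Scenario ids are ``"<filter>|<benefit>|<scheme>"``; filters vary slowest,
    schemes fastest. Duplicate ids (e.g. two identically-labelled filters)
    are a configuration error.
    """
    if not filters or not benefit_fields or not schemes:
        raise ConfigurationError("filters, benefit_fields and schemes must all be non-empty")
    specs = []
    for flt in filters:
        for benefit in benefit_fields:
            for scheme in schemes:
                specs.append(
                    ScenarioSpec(
                        scenario_id=f"{_filter_label(flt)}|{benefit}|{scheme.scheme_id}",
                        filter=flt,
                        benefit_field=benefit,
                        scheme_id=scheme.scheme_id,
                        alpha_policy=alpha_policy,
                        p_source=p_source,
                        c_source=c_source,
                        top_k=top_k,
                    )
                )
    ids = [s.scenario_id for s in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigurationError(f"duplicate scenario id(s): {dupes}")
    return specs


def shared_alphas(
    countries: list[CountryRecord],
    layers: ThreatLayerTable,
    schemes: list[ClassificationScheme],
) -> dict[str, AlphaParameter]:
    """One α per scheme over the full candidate pool (the shared-α default)."""
    ids = [c.country_id for c in countries]
    return {
        sch.scheme_id: compute_alpha(
            summarize_threats(layers, sch, ids), pool_id=f"full-pool/{sch.scheme_id}"
        )
        for sch in schemes
    }


def run_scenario(
    spec: ScenarioSpec,
    countries: list[CountryRecord],
    layers: ThreatLayerTable,
    schemes: dict[str, ClassificationScheme],
    alphas: dict[str, AlphaParameter] | None = None,
) -> ScenarioResult:
    """Screen → summarize threats → score → rank → extract top-k.

    ``alphas`` supplies the shared per-scheme α values; when absent, or when
    the spec asks for ``per_scenario`` α, the α is recomputed over the
    post-screening pool. An empty post-screening pool yields an empty ranking
    with a logged warning (a legitimate outcome of a strict filter).
    """
    if spec.scheme_id not in schemes:
        raise ConfigurationError(f"scenario {spec.scenario_id!r}: unknown scheme {spec.scheme_id!r}")
    scheme = schemes[spec.scheme_id]
    screening = apply_rule(countries, spec.filter)
    pool = [c for c in countries if c.country_id in set(screening.passed)]
    if not pool:
        log.warning("scenario %s: empty pool after screening", spec.scenario_id)
        return ScenarioResult(
            scenario_id=spec.scenario_id, scheme_id=spec.scheme_id,
            alpha_used=0.0, pool_size=0, scored=[], _top_k=spec.top_k,
        )
    missing_benefit = [c.country_id for c in pool if spec.benefit_field not in c.benefits]
    if missing_benefit:
        raise ConfigurationError(
            f"scenario {spec.scenario_id!r}: benefit field {spec.benefit_field!r} "
            f"absent for countries {missing_benefit[:5]}"
        )
    summaries = summarize_threats(layers, scheme, [c.country_id for c in pool])
    if spec.alpha_policy == "shared" and alphas is not None:
        alpha = alphas[spec.scheme_id]
    else:
        alpha = compute_alpha(summaries, pool_id=f"{spec.scenario_id}/pool")
    scored = rank_pool(
        score_pool(
            pool,
            summaries,
            spec.benefit_field,
            alpha,
            constant_p=spec.p_source == "constant_one",
            constant_c=spec.c_source == "constant_one",
        )
    )
    return ScenarioResult(
        scenario_id=spec.scenario_id,
        scheme_id=spec.scheme_id,
        alpha_used=alpha.value,
        pool_size=len(pool),
        scored=scored,
        _top_k=spec.top_k,
    )


def run_all(
    specs: list[ScenarioSpec],
    countries: list[CountryRecord],
    layers: ThreatLayerTable,
    schemes: dict[str, ClassificationScheme],
    alphas: dict[str, AlphaParameter] | None = None,
) -> list[ScenarioResult]:
    """Run every scenario independently; results follow spec order.

    Any failure aborts the whole run with the scenario id attached — no
    partial, silently-incomplete output.
    """
    results = []
    for spec in specs:
        try:
            results.append(run_scenario(spec, countries, layers, schemes, alphas))
        except PrioritizationError as err:
            raise type(err)(f"scenario {spec.scenario_id!r}: {err}") from err
    return results
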