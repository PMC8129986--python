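"""Enabling-condition screening: conjunctive threshold / flag rules.

Screening is a decision tree, not a weighted score: a candidate either meets
every enabling condition or it is excluded, annotated with the first rule it
failed. No weighting or summing of conditions is offered — composing
heterogeneous enabling factors into an arbitrary score hides the reasons a
candidate was kept or dropped, and screening must stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

from .models import ConfigurationError, CountryRecord

_NUMERIC_OPS = {"ge", "le", "eq"}
_BOOL_OPS = {"is_true", "is_false"}
_OP_SYMBOL = {"ge": ">=", "le": "<=", "eq": "=", "is_true": "is true", "is_false": "is false"}

#: CountryRecord attributes addressable directly by rules.
_ATTR_FIELDS = ("debt_to_gdp", "p_success", "cost")


def _field_value(record: CountryRecord, name: str):
    if name in _ATTR_FIELDS:
        return getattr(record, name)
    if name in record.benefits:
        return record.benefits[name]
    if name in record.extras:
        return record.extras[name]
    raise ConfigurationError(
        f"screening field {name!r} not found on country {record.country_id!r} "
        "(not an attribute, benefit, or extras key)"
    )


@dataclass(frozen=True)
class FilterRule:
    """One enabling-condition test on a country field.

    ``op`` is one of ``ge``/``le``/``eq`` (numeric, requires ``threshold``) or
    ``is_true``/``is_false`` (boolean flags, no threshold). Numeric comparisons
    are inclusive, matching thresholds phrased as "60% or higher".
    """

    field: str
    op: str
    threshold: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.op not in _NUMERIC_OPS | _BOOL_OPS:
            raise ConfigurationError(f"unknown comparator {self.op!r}")
        if self.op in _NUMERIC_OPS:
            if self.threshold is None or not math.isfinite(float(self.threshold)):
                raise ConfigurationError(
                    f"comparator {self.op!r} on {self.field!r} requires a finite threshold"
                )
        elif self.threshold is not None:
            raise ConfigurationError(f"boolean comparator {self.op!r} takes no threshold")
        if not self.label:
            sym = _OP_SYMBOL[self.op]
            text = (
                f"{self.field} {sym} {self.threshold}"
                if self.op in _NUMERIC_OPS
                else f"{self.field} {sym}"
            )
            object.__setattr__(self, "label", text)

    def passes(self, record: CountryRecord) -> bool:
        value = _field_value(record, self.field)
        if self.op in _NUMERIC_OPS:
            try:
                v = float(value)
            except (TypeError, ValueError):
                raise ConfigurationError(
                    f"field {self.field!r} on {record.country_id!r} is not numeric "
                    f"(got {value!r}) but comparator {self.op!r} needs a number"
                ) from None
            t = float(self.threshold)  # type: ignore[arg-type]
            return {"ge": v >= t, "le": v <= t, "eq": v == t}[self.op]
        if not isinstance(value, (bool,)) and value not in (0, 1):
            raise ConfigurationError(
                f"field {self.field!r} on {record.country_id!r} is not boolean "
                f"(got {value!r}) but comparator {self.op!r} needs a flag"
            )
        flag = bool(value)
        return flag if self.op == "is_true" else not flag

    def first_failure(self, record: CountryRecord) -> str | None:
        """Label of the failing rule, or None if the record passes."""
        return None if self.passes(record) else self.label


@dataclass(frozen=True)
class ConjunctionRule:
    """AND-composition of rules; a record passes iff it passes every rule.

    The exclusion annotation cites the first failing rule in list order, so
    the rule order shapes the audit trail but never the pass-set.
    """

    rules: tuple[FilterRule, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.rules:
            raise ConfigurationError("cannot compose an empty rule list")
        if not self.label:
            object.__setattr__(self, "label", " AND ".join(r.label for r in self.rules))

    def passes(self, record: CountryRecord) -> bool:
        return all(r.passes(record) for r in self.rules)

    def first_failure(self, record: CountryRecord) -> str | None:
        for r in self.rules:
            if not r.passes(record):
                return r.label
        return None


def compose_rules(rules: list[FilterRule]) -> ConjunctionRule:
    """Conjoin rules; excluded candidates are annotated with their first failure."""
    return ConjunctionRule(rules=tuple(rules))


@dataclass
class ScreeningResult:
    """Outcome of applying one rule (or conjunction) to a candidate list."""

    rule_labels: list[str]
    passed: list[str]
    excluded: dict[str, str] = field(default_factory=dict)


def apply_rule(
    records: list[CountryRecord], rule: FilterRule | ConjunctionRule | None
) -> ScreeningResult:
    """Screen candidates; ``rule=None`` means no enabling condition (all pass).

    The pass list preserves input order; each excluded country maps to the
    label of the first rule it failed. Unknown fields raise
    :class:`ConfigurationError` — a candidate is never silently dropped.
    """
    if rule is None:
        return ScreeningResult(rule_labels=[], passed=[r.country_id for r in records])
    labels = [r.label for r in rule.rules] if isinstance(rule, ConjunctionRule) else [rule.label]
    passed: list[str] = []
    excluded: dict[str, str] = {}
    for rec in records:
        failure = rule.first_failure(rec)
        if failure is None:
            passed.append(rec.country_id)
        else:
            excluded[rec.country_id] = failure
    return ScreeningResult(rule_labels=labels, passed=passed, excluded=excluded)


def rule_from_dict(spec: dict) -> FilterRule:
    """Build a rule from a config mapping like ``{"field": "debt_to_gdp", "op": "ge", "threshold": 0.6}``."""
    unknown = set(spec) - {"field", "op", "threshold", "label"}
    if unknown:
        raise ConfigurationError(f"unknown rule key(s): {sorted(unknown)}")
    if "field" not in spec or "op" not in spec:
        raise ConfigurationError("a rule needs at least 'field' and 'op'")
    return FilterRule(
        field=spec["field"],
        op=spec["op"],
        threshold=spec.get("threshold"),
        label=spec.get("label", ""),
    )
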