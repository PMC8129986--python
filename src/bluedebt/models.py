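"""Domain types for debt-conversion prioritization.

The objects here carry the inputs of a threat-adjusted cost-effectiveness
analysis over candidate countries: per-country benefit fields (EEZ area,
coral-reef area, ...), a table of normalized human-impact layer means per
country, and a classification scheme partitioning those layers into threats
a marine-protection action can abate and threats it cannot.

Validation is eager and loud: every invariant is checked at construction so
that a prioritization run can never proceed on silently-corrupt inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class PrioritizationError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PrioritizationError):
    """An input value violates a domain invariant (range, uniqueness, type)."""


class ConfigurationError(PrioritizationError):
    """A run configuration references unknown fields or is internally inconsistent."""


class CoverageError(PrioritizationError):
    """A classification scheme does not cover every threat layer in play."""


class DomainError(PrioritizationError):
    """An arithmetic precondition of the scoring formula is violated."""


#: Benefit columns every country table must provide (km^2).
REQUIRED_BENEFITS = ("eez_area_km2", "coral_area_km2")

ABATABLE = "abatable"
UNABATABLE = "unabatable"
THREAT_CLASSES = (ABATABLE, UNABATABLE)


def _require_finite(value: float, what: str) -> float:
    v = float(value)
    if not math.isfinite(v):
        raise ValidationError(f"{what} must be finite, got {value!r}")
    return v


@dataclass
class CountryRecord:
    """One candidate country for a debt-conversion deal.

    Parameters
    ----------
    country_id :
        Short unique code (ISO-3 style).
    name :
        Display name.
    debt_to_gdp :
        Sovereign debt / GDP as a ratio (0.60 means 60%). Must be >= 0.
    benefits :
        Mapping benefit-field name -> non-negative area (km^2). Must contain
        ``eez_area_km2`` and ``coral_area_km2``; additional benefit fields are
        allowed and addressable by name.
    p_success :
        Probability the conservation action succeeds, in [0, 1]. Defaults to 1
        (the convention used when no realistic estimates exist across candidates).
    cost :
        Total cost of taking the action, > 0 in consistent currency-equivalent
        units. Defaults to 1.
    extras :
        Optional enabling-condition fields (numeric or boolean), e.g. a
        governance index or a sovereignty flag.
    """

    country_id: str
    name: str
    debt_to_gdp: float
    benefits: dict[str, float]
    p_success: float = 1.0
    cost: float = 1.0
    extras: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.country_id:
            raise ValidationError("country_id must be a non-empty string")
        self.debt_to_gdp = _require_finite(self.debt_to_gdp, f"{self.country_id}: debt_to_gdp")
        if self.debt_to_gdp < 0:
            raise ValidationError(
                f"{self.country_id}: debt_to_gdp must be >= 0, got {self.debt_to_gdp}"
            )
        for key in REQUIRED_BENEFITS:
            if key not in self.benefits:
                raise ValidationError(f"{self.country_id}: missing required benefit field {key!r}")
        for key, value in self.benefits.items():
            v = _require_finite(value, f"{self.country_id}: benefit {key!r}")
            if v < 0:
                raise ValidationError(f"{self.country_id}: benefit {key!r} must be >= 0, got {v}")
            self.benefits[key] = v
        self.p_success = _require_finite(self.p_success, f"{self.country_id}: p_success")
        if not 0.0 <= self.p_success <= 1.0:
            raise ValidationError(
                f"{self.country_id}: p_success must be in [0, 1], got {self.p_success}"
            )
        self.cost = _require_finite(self.cost, f"{self.country_id}: cost")
        if self.cost <= 0:
            raise ValidationError(f"{self.country_id}: cost must be > 0, got {self.cost}")


def check_unique_ids(records: list[CountryRecord]) -> None:
    """Raise :class:`ValidationError` naming any duplicated country_id."""
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.country_id] = seen.get(rec.country_id, 0) + 1
    dupes = sorted(cid for cid, n in seen.items() if n > 1)
    if dupes:
        raise ValidationError(f"duplicate country_id values: {', '.join(dupes)}")


@dataclass
class ThreatLayerTable:
    """Per-country mean values of normalized human-impact layers.

    Each value is the mean of one normalized impact layer over a country's
    EEZ, so it lies in [0, 1]. The table is rectangular by construction:
    every country listed must have a value for every layer — a missing cell
    is a hard error, never an implicit zero.

    Parameters
    ----------
    layer_names :
        Layer identifiers, in a fixed order (file order for wide input,
        first-appearance order for long input).
    values :
        Mapping ``(country_id, layer_name) -> mean impact in [0, 1]``.
    """

    layer_names: list[str]
    values: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValidationError("layer_names contains duplicates")
        layer_set = set(self.layer_names)
        countries: list[str] = []
        seen = set()
        for (cid, layer), value in self.values.items():
            if layer not in layer_set:
                raise ValidationError(f"value given for unknown layer {layer!r} (country {cid})")
            v = _require_finite(value, f"threat value ({cid}, {layer})")
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"threat value out of range [0, 1] at (country={cid}, layer={layer}): {v}"
                )
            self.values[(cid, layer)] = v
            if cid not in seen:
                seen.add(cid)
                countries.append(cid)
        for cid in countries:
            missing = [ly for ly in self.layer_names if (cid, ly) not in self.values]
            if missing:
                raise ValidationError(
                    f"missing threat cell(s) for country {cid!r}: {', '.join(missing)}"
                )
        self._country_ids = countries

    @property
    def country_ids(self) -> list[str]:
        """Countries present, in first-appearance order."""
        return list(self._country_ids)

    def value(self, country_id: str, layer_name: str) -> float:
        try:
            return self.values[(country_id, layer_name)]
        except KeyError:
            raise ValidationError(
                f"no threat value for (country={country_id}, layer={layer_name})"
            ) from None


@dataclass
class ClassificationScheme:
    """A named partition of threat layers into abatable and unabatable classes.

    Abatable threats (fishing, benthic structures, direct human impacts) are
    those a marine-protection action can reduce; unabatable threats (e.g.
    climate-driven heat stress) discount the expected benefit instead.
    """

    scheme_id: str
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if not self.scheme_id:
            raise ValidationError("scheme_id must be non-empty")
        for layer, cls in self.assignment.items():
            if cls not in THREAT_CLASSES:
                raise ValidationError(
                    f"scheme {self.scheme_id!r}: layer {layer!r} has unknown class {cls!r} "
                    f"(expected one of {THREAT_CLASSES})"
                )
        classes = set(self.assignment.values())
        if classes != set(THREAT_CLASSES):
            raise ValidationError(
                f"scheme {self.scheme_id!r} must assign at least one layer to each of "
                f"{THREAT_CLASSES}; got classes {sorted(classes)}"
            )

    @property
    def abatable_layers(self) -> list[str]:
        return [l for l, c in self.assignment.items() if c == ABATABLE]

    @property
    def unabatable_layers(self) -> list[str]:
        return [l for l, c in self.assignment.items() if c == UNABATABLE]

    def validate_covers(self, layer_names: list[str]) -> None:
        """Raise :class:`CoverageError` if any layer lacks a class assignment."""
        missing = [l for l in layer_names if l not in self.assignment]
        if missing:
            raise CoverageError(
                f"scheme {self.scheme_id!r} does not classify layer(s): {', '.join(missing)}"
            )


@dataclass
class ThreatSummary:
    """Additive abatable / unabatable threat burdens for one country under one scheme.

    ``i_abatable`` and ``i_unabatable`` are sums (not means) of the per-layer
    mean impacts, so with many [0, 1] layers each burden can exceed 1; the
    unabatable burden is rescaled by α before entering the score. Their sum is
    a scheme-independent constant for a country (conservation of threat mass).
    """

    country_id: str
    scheme_id: str
    i_abatable: float
    i_unabatable: float

    def __post_init__(self) -> None:
        for name in ("i_abatable", "i_unabatable"):
            v = _require_finite(getattr(self, name), f"{self.country_id}: {name}")
            if v < 0:
                raise ValidationError(f"{self.country_id}: {name} must be >= 0, got {v}")


@dataclass
class AlphaParameter:
    """Scaling multiplier keeping the unabatable-threat discount non-negative.

    Under the ``pool_max_reciprocal`` policy α = 1 / max(I_u) over the
    candidate pool, so (1 − α·I_u) ∈ [0, 1] for every pool member, with
    equality to 0 at the country of maximal unabatable burden. A degenerate
    pool with max(I_u) = 0 maps to α = 0 (every discount is then exactly 1).
    """

    value: float
    policy: str
    pool_id: str = "pool"

    def __post_init__(self) -> None:
        v = _require_finite(self.value, "alpha value")
        if v < 0:
            raise ValidationError(f"alpha must be >= 0, got {v}")
        if self.policy not in ("pool_max_reciprocal", "fixed"):
            raise ValidationError(f"unknown alpha policy {self.policy!r}")
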