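"""Additive threat burdens and the non-negativity scaling parameter α.

Threats are assumed additive: a country's abatable burden I_a is the sum of
its mean impacts over the abatable layers, and likewise I_u over the
unabatable layers. Because many [0, 1] layers are summed, I_u routinely
exceeds 1, so the discount factor (1 − α·I_u) needs the multiplier α to stay
non-negative. The pool-derived choice α = 1/max(I_u) makes the discount hit
exactly 0 at the most-burdened country and stay in [0, 1] everywhere else.
"""

from __future__ import annotations

from .models import (
    AlphaParameter,
    ClassificationScheme,
    ConfigurationError,
    ThreatLayerTable,
    ThreatSummary,
    ValidationError,
)


def summarize_threats(
    layers: ThreatLayerTable,
    scheme: ClassificationScheme,
    country_ids: list[str] | None = None,
) -> list[ThreatSummary]:
    """Compute (I_a, I_u) per country under one classification scheme.

    ``country_ids`` defaults to every country in the table, in table order.
    The scheme must classify every layer of the table (coverage is checked,
    never assumed). For any country, I_a + I_u equals the sum of all its layer
    means — a constant across schemes partitioning the same layer set.
    """
    scheme.validate_covers(layers.layer_names)
    if country_ids is None:
        country_ids = layers.country_ids
    present = set(layers.country_ids)
    summaries = []
    for cid in country_ids:
        if cid not in present:
            raise ValidationError(f"country {cid!r} has no rows in the threat-layer table")
        i_a = sum(layers.value(cid, l) for l in layers.layer_names
                  if scheme.assignment[l] == "abatable")
        i_u = sum(layers.value(cid, l) for l in layers.layer_names
                  if scheme.assignment[l] == "unabatable")
        summaries.append(
            ThreatSummary(country_id=cid, scheme_id=scheme.scheme_id,
                          i_abatable=i_a, i_unabatable=i_u)
        )
    return summaries


def compute_alpha(
    summaries: list[ThreatSummary],
    policy: str = "pool_max_reciprocal",
    fixed_value: float | None = None,
    pool_id: str = "pool",
) -> AlphaParameter:
    """Derive α over a candidate pool.

    ``pool_max_reciprocal``: α = 1 / max(I_u) over the pool; if every I_u is 0
    the convention α = 0 applies and every discount reduces to 1.
    ``fixed``: use ``fixed_value``, rejected if it would drive any pool
    member's discount negative (the offending country is named).
    """
    if not summaries:
        raise ConfigurationError("cannot derive alpha from an empty candidate pool")
    max_iu = max(s.i_unabatable for s in summaries)
    if policy == "pool_max_reciprocal":
        value = 0.0 if max_iu == 0 else 1.0 / max_iu
        return AlphaParameter(value=value, policy=policy, pool_id=pool_id)
    if policy == "fixed":
        if fixed_value is None or fixed_value < 0:
            raise ConfigurationError("fixed alpha policy requires fixed_value >= 0")
        worst = max(summaries, key=lambda s: s.i_unabatable)
        if 1.0 - fixed_value * worst.i_unabatable < 0:
            raise ConfigurationError(
                f"fixed alpha {fixed_value} gives a negative discount for "
                f"{worst.country_id!r} (I_u = {worst.i_unabatable:.6g})"
            )
        return AlphaParameter(value=float(fixed_value), policy=policy, pool_id=pool_id)
    raise ConfigurationError(f"unknown alpha policy {policy!r}")
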