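"""Threat-adjusted cost-effectiveness scoring and deterministic ranking.

The score of a candidate country is

    ce = B * I_a * (1 - alpha * I_u) * P / C

where B is the benefit (EEZ or coral-reef area, km^2), I_a and I_u the
additive abatable / unabatable threat burdens, alpha the pool-derived
scaling multiplier, P the probability of success and C the cost. The
``expected benefit`` B * I_a * (1 - alpha * I_u) is what remains of the raw
benefit once only the abatable share of the threat load is actionable and
the unabatable load discounts effectiveness.

A candidate with I_a = 0 scores 0: there is nothing for a protection-type
action to abate. Such candidates are flagged so users can distinguish "no
benefit" from "no abatable threat".
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import AlphaParameter, CountryRecord, DomainError, ThreatSummary

#: Negative-discount slack absorbing float rounding of alpha = 1/max(I_u);
#: anything below this is a genuine precondition violation, never clamped.
_DISCOUNT_FLOAT_TOL = 1e-9


def discount_factor(i_u: float, alpha: AlphaParameter) -> float:
    """(1 − α·I_u), guaranteed non-negative for pool members under the pool rule.

    A discount more negative than float tolerance means I_u exceeds the pool
    maximum the alpha was derived from (or a fixed alpha is too large):
    a :class:`DomainError`, never a silent clamp.
    """
    d = 1.0 - alpha.value * i_u
    if d < -_DISCOUNT_FLOAT_TOL:
        raise DomainError(
            f"negative discount (1 - {alpha.value:.6g} * {i_u:.6g}) = {d:.3g}; "
            "I_u exceeds the pool maximum this alpha was derived for"
        )
    return max(d, 0.0)


def expected_benefit(b: float, i_a: float, i_u: float, alpha: AlphaParameter) -> float:
    """B · I_a · (1 − α·I_u): the benefit surviving the threat adjustment."""
    return b * i_a * discount_factor(i_u, alpha)


def ce_score(
    b: float,
    i_a: float,
    i_u: float,
    alpha: AlphaParameter,
    p_success: float = 1.0,
    cost: float = 1.0,
) -> float:
    """Full cost-effectiveness score B·I_a·(1−α·I_u)·P / C."""
    if cost <= 0:
        raise DomainError(f"cost must be > 0, got {cost}")
    if not 0.0 <= p_success <= 1.0:
        raise DomainError(f"p_success must be in [0, 1], got {p_success}")
    return expected_benefit(b, i_a, i_u, alpha) * p_success / cost


@dataclass
class ScoredCandidate:
    """One country's scored entry within a scenario."""

    country_id: str
    benefit_field: str
    b: float
    i_abatable: float
    i_unabatable: float
    discount: float
    expected_benefit: float
    p_success: float
    cost: float
    ce_score: float
    rank: int | None = None

    @property
    def no_abatable_threat(self) -> bool:
        """True when the zero score stems from I_a = 0 rather than zero benefit."""
        return self.i_abatable == 0


def score_pool(
    records: list[CountryRecord],
    summaries: list[ThreatSummary],
    benefit_field: str,
    alpha: AlphaParameter,
    constant_p: bool = True,
    constant_c: bool = True,
) -> list[ScoredCandidate]:
    """Score every record against its threat summary (matched by country_id).

    With ``constant_p`` / ``constant_c`` (the default) P and C are fixed at 1
    and priorities are driven solely by the expected benefit; otherwise the
    record's own ``p_success`` / ``cost`` columns enter the score.
    """
    by_id = {s.country_id: s for s in summaries}
    scored = []
    for rec in records:
        s = by_id[rec.country_id]
        b = rec.benefits[benefit_field]
        p = 1.0 if constant_p else rec.p_success
        c = 1.0 if constant_c else rec.cost
        d = discount_factor(s.i_unabatable, alpha)
        eb = b * s.i_abatable * d
        scored.append(
            ScoredCandidate(
                country_id=rec.country_id,
                benefit_field=benefit_field,
                b=b,
                i_abatable=s.i_abatable,
                i_unabatable=s.i_unabatable,
                discount=d,
                expected_benefit=eb,
                p_success=p,
                cost=c,
                ce_score=ce_score(b, s.i_abatable, s.i_unabatable, alpha, p, c),
            )
        )
    return scored


def rank_pool(candidates: list[ScoredCandidate]) -> list[ScoredCandidate]:
    """Order by descending score, ties broken by ascending country_id.

    Ranks are 1..n with no gaps; tied scores receive distinct consecutive
    ranks in tie-break order, keeping the output fully reproducible.
    """
    ordered = sorted(candidates, key=lambda c: (-c.ce_score, c.country_id))
    for pos, cand in enumerate(ordered, start=1):
        cand.rank = pos
    return ordered
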