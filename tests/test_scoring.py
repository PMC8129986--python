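"""Cost-effectiveness scoring: hand-checked values, monotonicity, ranking."""

import numpy as np
import pytest

from bluedebt import (
    AlphaParameter,
    DomainError,
    ThreatSummary,
    ce_score,
    expected_benefit,
    rank_pool,
    score_pool,
)
from bluedebt.scoring import ScoredCandidate
from tests.conftest import make_country


def alpha_of(value):
    return AlphaParameter(value=value, policy="fixed")


def test_expected_benefit_hand_evaluation():
    # 100 * 0.5 * (1 - 0.18*3.0) = 100 * 0.5 * 0.46 = 23.0
    assert expected_benefit(100.0, 0.5, 3.0, alpha_of(0.18)) == pytest.approx(23.0)


def test_expected_benefit_zero_at_pool_max():
    alpha = alpha_of(1.0 / 4.0)
    assert expected_benefit(1e6, 0.9, 4.0, alpha) == pytest.approx(0.0, abs=1e-9)


def test_expected_benefit_no_unabatable_discount():
    assert expected_benefit(200.0, 0.4, 0.0, alpha_of(0.18)) == pytest.approx(80.0)


def test_negative_discount_is_an_error_never_clamped():
    with pytest.raises(DomainError):
        expected_benefit(100.0, 0.5, 10.0, alpha_of(0.18))


def test_ce_score_reduces_to_expected_benefit_when_p_and_c_are_one():
    eb = expected_benefit(100.0, 0.5, 3.0, alpha_of(0.18))
    assert ce_score(100.0, 0.5, 3.0, alpha_of(0.18), 1.0, 1.0) == pytest.approx(eb)


def test_ce_score_homogeneity_and_zero_probability():
    a = alpha_of(0.1)
    assert ce_score(100, 0.5, 1.0, a, 1.0, 2.0) == pytest.approx(
        ce_score(100, 0.5, 1.0, a, 1.0, 1.0) / 2
    )
    assert ce_score(100, 0.5, 1.0, a, 0.0, 1.0) == 0.0


def test_ce_score_rejects_nonpositive_cost():
    with pytest.raises(DomainError):
        ce_score(1.0, 1.0, 0.0, alpha_of(0.0), 1.0, 0.0)


def test_strict_monotonicity_in_every_parameter():
    a = alpha_of(0.1)
    base = ce_score(100, 0.5, 2.0, a, 0.8, 2.0)
    assert ce_score(110, 0.5, 2.0, a, 0.8, 2.0) > base  # increasing in B
    assert ce_score(100, 0.6, 2.0, a, 0.8, 2.0) > base  # increasing in I_a
    assert ce_score(100, 0.5, 2.0, a, 0.9, 2.0) > base  # increasing in P
    assert ce_score(100, 0.5, 2.0, a, 0.8, 3.0) < base  # decreasing in C
    assert ce_score(100, 0.5, 3.0, a, 0.8, 2.0) < base  # decreasing in I_u


def test_zero_abatable_threat_scores_zero_and_is_flagged():
    cand = ScoredCandidate(
        country_id="AAA", benefit_field="eez_area_km2", b=1000.0, i_abatable=0.0,
        i_unabatable=1.0, discount=0.9, expected_benefit=0.0, p_success=1.0,
        cost=1.0, ce_score=0.0,
    )
    assert cand.no_abatable_threat
    assert expected_benefit(1000.0, 0.0, 1.0, alpha_of(0.1)) == 0.0


def test_rank_pool_tie_break_by_country_id():
    def cand(cid, score):
        return ScoredCandidate(country_id=cid, benefit_field="b", b=1, i_abatable=1,
                               i_unabatable=0, discount=1, expected_benefit=score,
                               p_success=1, cost=1, ce_score=score)

    ranked = rank_pool([cand("A", 5.0), cand("B", 9.0), cand("C", 5.0)])
    assert [c.country_id for c in ranked] == ["B", "A", "C"]
    assert [c.rank for c in ranked] == [1, 2, 3]


def test_rank_pool_single_and_empty():
    assert rank_pool([]) == []
    only = ScoredCandidate(country_id="X", benefit_field="b", b=1, i_abatable=1,
                           i_unabatable=0, discount=1, expected_benefit=1,
                           p_success=1, cost=1, ce_score=1.0)
    assert rank_pool([only])[0].rank == 1


def test_ranking_matches_independent_recomputation():
    """Brute-force oracle: ranking equals a sort of independently recomputed
    B*I_a*(1-alpha*I_u)*P/C values."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(2, 15))
        recs = [make_country(f"C{i:03d}", eez=float(rng.uniform(10, 1e6))) for i in range(n)]
        summaries = [
            ThreatSummary(country_id=r.country_id, scheme_id="s",
                          i_abatable=float(rng.uniform(0, 3)),
                          i_unabatable=float(rng.uniform(0, 4)))
            for r in recs
        ]
        alpha = AlphaParameter(
            value=1.0 / max(s.i_unabatable for s in summaries), policy="pool_max_reciprocal"
        )
        ranked = rank_pool(score_pool(recs, summaries, "eez_area_km2", alpha))
        by_id = {s.country_id: s for s in summaries}
        oracle = {
            r.country_id: r.benefits["eez_area_km2"] * by_id[r.country_id].i_abatable
            * (1 - alpha.value * by_id[r.country_id].i_unabatable)
            for r in recs
        }
        expected_order = sorted(oracle, key=lambda cid: (-oracle[cid], cid))
        assert [c.country_id for c in ranked] == expected_order
        for c in ranked:
            assert c.ce_score == pytest.approx(max(oracle[c.country_id], 0.0), abs=1e-9)


def test_rank_invariance_under_common_benefit_rescale():
    rng = np.random.default_rng(5)
    recs = [make_country(f"C{i:03d}", eez=float(rng.uniform(10, 1e6))) for i in range(12)]
    summaries = [
        ThreatSummary(country_id=r.country_id, scheme_id="s",
                      i_abatable=float(rng.uniform(0.1, 3)),
                      i_unabatable=float(rng.uniform(0, 4)))
        for r in recs
    ]
    alpha = AlphaParameter(value=1.0 / max(s.i_unabatable for s in summaries),
                           policy="pool_max_reciprocal")
    order1 = [c.country_id for c in rank_pool(score_pool(recs, summaries, "eez_area_km2", alpha))]
    scaled = [
        make_country(r.country_id, eez=r.benefits["eez_area_km2"] * 37.5) for r in recs
    ]
    order2 = [c.country_id for c in rank_pool(score_pool(scaled, summaries, "eez_area_km2", alpha))]
    assert order1 == order2


def test_threat_reshuffling_can_demote_the_largest_benefit():
    """A large-EEZ country with a heavy unabatable burden drops below a
    smaller country whose threats are mostly abatable."""
    recs = [make_country("BIG", eez=2.0e6), make_country("SML", eez=8.0e5)]
    summaries = [
        ThreatSummary(country_id="BIG", scheme_id="s", i_abatable=0.5, i_unabatable=4.0),
        ThreatSummary(country_id="SML", scheme_id="s", i_abatable=2.0, i_unabatable=1.0),
    ]
    alpha = AlphaParameter(value=0.25, policy="pool_max_reciprocal")
    ranked = rank_pool(score_pool(recs, summaries, "eez_area_km2", alpha))
    assert ranked[0].country_id == "SML"  # argmax of B is not argmax of score
    assert max(recs, key=lambda r: r.benefits["eez_area_km2"]).country_id == "BIG"
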