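"""Scenario-matrix construction and end-to-end execution."""

import pytest

from bluedebt import (
    ConfigurationError,
    FilterRule,
    ScenarioSpec,
    apply_rule,
    build_matrix,
    compute_alpha,
    rank_pool,
    run_all,
    run_scenario,
    score_pool,
    shared_alphas,
    summarize_threats,
)
from tests.conftest import make_country


def ge(threshold):
    return FilterRule(field="debt_to_gdp", op="ge", threshold=threshold)


PAPER_FILTERS = [None, ge(0.4), ge(0.6), ge(0.8)]


def test_matrix_counts(scheme_pair):
    a, b = scheme_pair
    assert len(build_matrix(PAPER_FILTERS, ["eez_area_km2", "coral_area_km2"], [a, b])) == 16
    assert len(build_matrix([None], ["eez_area_km2"], [a])) == 1
    specs = build_matrix([None, ge(0.5)], ["x", "y", "z"], [a, b])
    assert len(specs) == 6 * 2
    ids = [s.scenario_id for s in specs]
    assert len(set(ids)) == len(ids)


def test_matrix_rejects_empty_axes_and_duplicate_ids(scheme_pair):
    a, _ = scheme_pair
    with pytest.raises(ConfigurationError):
        build_matrix([], ["eez_area_km2"], [a])
    with pytest.raises(ConfigurationError, match="duplicate"):
        build_matrix([ge(0.6), ge(0.6)], ["eez_area_km2"], [a])


def test_matrix_order_filters_outer_schemes_inner(scheme_pair):
    a, b = scheme_pair
    specs = build_matrix([None, ge(0.6)], ["eez_area_km2", "coral_area_km2"], [a, b])
    assert [s.scenario_id for s in specs[:4]] == [
        "all|eez_area_km2|A", "all|eez_area_km2|B",
        "all|coral_area_km2|A", "all|coral_area_km2|B",
    ]


def test_run_scenario_equals_manual_composition(five_countries, five_layers, scheme_pair):
    """Integration oracle: the engine's output matches hand-chaining
    screening -> threat summaries -> scoring -> ranking."""
    scheme_a, scheme_b = scheme_pair
    schemes = {"A": scheme_a, "B": scheme_b}
    alphas = shared_alphas(five_countries, five_layers, [scheme_a, scheme_b])
    spec = ScenarioSpec(scenario_id="s", filter=ge(0.6), benefit_field="eez_area_km2",
                        scheme_id="A", top_k=2)
    result = run_scenario(spec, five_countries, five_layers, schemes, alphas)

    passed = set(apply_rule(five_countries, ge(0.6)).passed)
    pool = [c for c in five_countries if c.country_id in passed]
    summaries = summarize_threats(five_layers, scheme_a, [c.country_id for c in pool])
    manual = rank_pool(score_pool(pool, summaries, "eez_area_km2", alphas["A"]))

    assert result.pool_size == len(pool)
    assert [c.country_id for c in result.scored] == [c.country_id for c in manual]
    for got, want in zip(result.scored, manual):
        assert got.ce_score == pytest.approx(want.ce_score)
    assert result.top_k_set == set(c.country_id for c in manual[:2])


def test_identical_threat_profiles_rank_by_benefit_alone(five_layers, scheme_pair):
    """With identical layer values the threat terms are a common factor and
    the ranking reduces to the benefit ordering (shared α keeps it > 0)."""
    scheme_a, _ = scheme_pair
    from bluedebt import AlphaParameter, ThreatLayerTable

    pool = [make_country(c, debt=0.7, eez=area) for c, area in
            [("AAA", 100.0), ("BBB", 500.0), ("CCC", 300.0)]]
    values = {(c.country_id, l): v for c in pool
              for l, v in [("fishing", 0.4), ("shipping", 0.2), ("heat", 0.6)]}
    layers = ThreatLayerTable(layer_names=["fishing", "shipping", "heat"], values=values)
    spec = ScenarioSpec(scenario_id="s", filter=None, benefit_field="eez_area_km2",
                        scheme_id="A")
    shared = {"A": AlphaParameter(value=0.5, policy="fixed")}  # discount 0.7 for all
    res = run_scenario(spec, pool, layers, {"A": scheme_a}, shared)
    assert [c.country_id for c in res.scored] == ["BBB", "CCC", "AAA"]
    assert all(c.discount == pytest.approx(0.7) for c in res.scored)


def test_top_k_equal_to_pool_size_returns_whole_pool(five_countries, five_layers, scheme_pair):
    scheme_a, _ = scheme_pair
    spec = ScenarioSpec(scenario_id="s", filter=None, benefit_field="eez_area_km2",
                        scheme_id="A", top_k=5)
    res = run_scenario(spec, five_countries, five_layers, {"A": scheme_a})
    assert res.top_k_set == {c.country_id for c in five_countries}


def test_empty_post_screening_pool_warns_not_errors(five_countries, five_layers,
                                                    scheme_pair, caplog):
    scheme_a, _ = scheme_pair
    spec = ScenarioSpec(scenario_id="s", filter=ge(5.0), benefit_field="eez_area_km2",
                        scheme_id="A")
    with caplog.at_level("WARNING"):
        res = run_scenario(spec, five_countries, five_layers, {"A": scheme_a})
    assert res.pool_size == 0 and res.scored == []
    assert any("empty pool" in m for m in caplog.messages)


def test_unknown_benefit_field_aborts_with_scenario_context(five_countries, five_layers,
                                                            scheme_pair):
    scheme_a, _ = scheme_pair
    spec = ScenarioSpec(scenario_id="bad", filter=None, benefit_field="mangrove_km2",
                        scheme_id="A")
    with pytest.raises(ConfigurationError, match="bad"):
        run_all([spec], five_countries, five_layers, {"A": scheme_a})


def test_run_all_results_follow_spec_order_independently(five_countries, five_layers,
                                                         scheme_pair):
    scheme_a, scheme_b = scheme_pair
    schemes = {"A": scheme_a, "B": scheme_b}
    alphas = shared_alphas(five_countries, five_layers, [scheme_a, scheme_b])
    specs = build_matrix([None, ge(0.6)], ["eez_area_km2", "coral_area_km2"],
                         [scheme_a, scheme_b])
    fwd = run_all(specs, five_countries, five_layers, schemes, alphas)
    rev = run_all(specs[::-1], five_countries, five_layers, schemes, alphas)
    assert [r.scenario_id for r in fwd] == [r.scenario_id for r in rev][::-1]
    by_id_rev = {r.scenario_id: r for r in rev}
    for r in fwd:
        twin = by_id_rev[r.scenario_id]
        assert [c.country_id for c in r.scored] == [c.country_id for c in twin.scored]
        assert r.alpha_used == twin.alpha_used


def test_shared_alpha_gives_identical_discounts_across_scenarios(five_countries, five_layers,
                                                                 scheme_pair):
    """Under the shared-α default a country keeps the same (I_a, I_u, discount)
    in every scenario using the same scheme."""
    scheme_a, scheme_b = scheme_pair
    schemes = {"A": scheme_a, "B": scheme_b}
    alphas = shared_alphas(five_countries, five_layers, [scheme_a, scheme_b])
    res_all = run_scenario(
        ScenarioSpec(scenario_id="x", filter=None, benefit_field="eez_area_km2",
                     scheme_id="A"),
        five_countries, five_layers, schemes, alphas)
    res_filtered = run_scenario(
        ScenarioSpec(scenario_id="y", filter=ge(0.6), benefit_field="coral_area_km2",
                     scheme_id="A"),
        five_countries, five_layers, schemes, alphas)
    all_by_id = {c.country_id: c for c in res_all.scored}
    for c in res_filtered.scored:
        twin = all_by_id[c.country_id]
        assert (c.i_abatable, c.i_unabatable, c.discount) == (
            twin.i_abatable, twin.i_unabatable, twin.discount)


def test_per_scheme_shared_alpha_satisfies_nonnegativity(five_countries, five_layers,
                                                         scheme_pair):
    """Each scheme's shared α is derived from that scheme's own pool maximum,
    so no scenario can see a negative discount."""
    scheme_a, scheme_b = scheme_pair
    alphas = shared_alphas(five_countries, five_layers, [scheme_a, scheme_b])
    for scheme in (scheme_a, scheme_b):
        summaries = summarize_threats(five_layers, scheme)
        alpha = alphas[scheme.scheme_id]
        discounts = [1 - alpha.value * s.i_unabatable for s in summaries]
        assert min(discounts) == pytest.approx(0.0, abs=1e-12)
        assert all(d >= -1e-12 for d in discounts)
    # and the two schemes genuinely need different α values here
    assert alphas["A"].value != alphas["B"].value
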