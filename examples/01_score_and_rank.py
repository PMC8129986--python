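"""Score and rank a tiny hand-built candidate pool.

Builds four countries with known benefits and threat burdens, derives the
scaling parameter alpha from the pool, and prints the threat-adjusted
cost-effectiveness ranking. Note how the country with the largest EEZ is
not the top priority once its heavy unabatable burden is discounted.
"""

from bluedebt import (
    ClassificationScheme,
    CountryRecord,
    ThreatLayerTable,
    compute_alpha,
    rank_pool,
    score_pool,
    summarize_threats,
)

countries = [
    CountryRecord("MRU", "Big-EEZ Atoll State", 0.65,
                  {"eez_area_km2": 1.9e6, "coral_area_km2": 800.0}),
    CountryRecord("MDV", "Mid-EEZ Reef State", 0.70,
                  {"eez_area_km2": 0.9e6, "coral_area_km2": 4000.0}),
    CountryRecord("BLZ", "Coastal Reef State", 0.80,
                  {"eez_area_km2": 0.3e6, "coral_area_km2": 1400.0}),
    CountryRecord("CPV", "Volcanic Island State", 1.00,
                  {"eez_area_km2": 0.8e6, "coral_area_km2": 50.0}),
]

layers = ThreatLayerTable(
    layer_names=["fishing", "shipping", "heat_stress", "acidification"],
    values={
        # the big-EEZ state carries the heaviest unabatable (climate) load
        ("MRU", "fishing"): 0.30, ("MRU", "shipping"): 0.20,
        ("MRU", "heat_stress"): 0.90, ("MRU", "acidification"): 0.85,
        ("MDV", "fishing"): 0.60, ("MDV", "shipping"): 0.30,
        ("MDV", "heat_stress"): 0.60, ("MDV", "acidification"): 0.50,
        ("BLZ", "fishing"): 0.70, ("BLZ", "shipping"): 0.10,
        ("BLZ", "heat_stress"): 0.50, ("BLZ", "acidification"): 0.40,
        ("CPV", "fishing"): 0.50, ("CPV", "shipping"): 0.40,
        ("CPV", "heat_stress"): 0.40, ("CPV", "acidification"): 0.30,
    },
)

scheme = ClassificationScheme(
    scheme_id="base",
    assignment={"fishing": "abatable", "shipping": "abatable",
                "heat_stress": "unabatable", "acidification": "unabatable"},
)

summaries = summarize_threats(layers, scheme)
alpha = compute_alpha(summaries)  # 1 / max(I_u) over this pool
print(f"alpha = 1/max(I_u) = {alpha.value:.4f}\n")

ranked = rank_pool(score_pool(countries, summaries, "eez_area_km2", alpha))
print(f"{'rank':>4} {'id':>4} {'B (km^2)':>12} {'I_a':>5} {'I_u':>5} "
      f"{'discount':>8} {'ce score':>14}")
for c in ranked:
    print(f"{c.rank:>4} {c.country_id:>4} {c.b:>12.3g} {c.i_abatable:>5.2f} "
          f"{c.i_unabatable:>5.2f} {c.discount:>8.3f} {c.ce_score:>14.4g}")

print(
    "\nThe ce score is B * I_a * (1 - alpha*I_u); MRU has the largest EEZ but"
    "\nits discount is 0 (it defines max I_u), so smaller, mostly-abatable"
    "\npools of threat rise above it."
)
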