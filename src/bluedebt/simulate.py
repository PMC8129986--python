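"""Seeded generator of synthetic candidate-country data.

The generator emulates the statistical structure the prioritization assumes,
so every stage of the pipeline runs without downloading any global dataset:

* debt-to-GDP ratios uniform over a range spanning the 40/60/80% screening
  thresholds, so every filter of the default scenario matrix bites;
* heavy-tailed (log-normal) EEZ and coral-reef areas, with a configurable
  fraction of countries having no coral at all;
* 19 normalized threat layers drawn from Beta distributions parameterized by
  (mean, concentration): unabatable layers (climate-driven and land-based
  pressures) have high means and low between-country variability, abatable
  layers (fishing, benthic structures, direct human impacts) lower means and
  more variability — the contrast that makes abatable threats, not
  unabatable ones, drive the ranking;
* a shipping layer emitted once and classified abatable in scheme A but
  unabatable in scheme B, the classification-sensitivity pair.

All draws come from one ``numpy.random.Generator`` (PCG64) seeded from the
config, in a fixed order, so identical configs reproduce identical data
across runs and platforms. The defaults are fixed study conditions, not
tuning knobs: 53 candidates, and unabatable layer means summing to ≈5.2 so
the pool's maximum unabatable burden sits near 5.6 (whence α ≈ 0.18).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .models import (
    ABATABLE,
    UNABATABLE,
    ClassificationScheme,
    CountryRecord,
    ThreatLayerTable,
    ValidationError,
)
from .threats import compute_alpha, summarize_threats

SHIPPING_LAYER = "shipping"


@dataclass(frozen=True)
class LayerSpec:
    """One threat layer of the catalog: Beta(mean, concentration) per country.

    The Beta shape parameters are a = mean*concentration and
    b = (1-mean)*concentration, so the mean is exact and the variance is
    mean*(1-mean)/(concentration+1): larger concentration, tighter layer.
    """

    name: str
    threat_class: str
    mean: float
    concentration: float


def default_layer_catalog() -> list[LayerSpec]:
    """19-layer catalog patterned on global cumulative human-impact layers.

    Abatable: five commercial-fishing gears, artisanal fishing, benthic
    structures, shipping, four direct human / ocean-based pressures
    (11 layers, means 0.10–0.35, concentration 6 → between-country CV ≈ 0.6–1).
    Unabatable: four climate-driven and four land-based pressures (8 layers,
    means 0.60–0.70, concentration 60 → CV ≈ 0.09), summing to 5.20.
    """
    abatable = [
        ("demersal_destructive_fishing", 0.30, 6.0),
        ("demersal_nondest_high_bycatch", 0.25, 6.0),
        ("demersal_nondest_low_bycatch", 0.20, 6.0),
        ("pelagic_high_bycatch", 0.35, 6.0),
        ("pelagic_low_bycatch", 0.30, 6.0),
        ("artisanal_fishing", 0.25, 6.0),
        ("benthic_structures", 0.10, 6.0),
        (SHIPPING_LAYER, 0.30, 6.0),
        ("direct_human", 0.15, 6.0),
        ("light_pollution", 0.12, 6.0),
        ("ocean_based_pollution", 0.20, 6.0),
    ]
    unabatable = [
        ("sst_anomaly", 0.70, 60.0),
        ("ocean_acidification", 0.68, 60.0),
        ("sea_level_rise", 0.66, 60.0),
        ("uv_radiation", 0.64, 60.0),
        ("nutrient_runoff", 0.62, 60.0),
        ("organic_chemical_pollution", 0.60, 60.0),
        ("inorganic_pollution", 0.66, 60.0),
        ("invasive_species", 0.64, 60.0),
    ]
    return [LayerSpec(n, ABATABLE, m, c) for n, m, c in abatable] + [
        LayerSpec(n, UNABATABLE, m, c) for n, m, c in unabatable
    ]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic candidate pool."""

    n_countries: int = 53
    seed: int = 0
    layer_catalog: list[LayerSpec] = field(default_factory=default_layer_catalog)
    debt_ratio_range: tuple[float, float] = (0.10, 1.20)
    eez_log_mean: float = 12.2  # exp(12.2) ≈ 2.0e5 km² median EEZ
    eez_log_sd: float = 1.4
    coral_log_mean: float = 6.0  # exp(6.0) ≈ 400 km² median reef area
    coral_log_sd: float = 1.5
    coral_zero_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValidationError(f"n_countries must be >= 1, got {self.n_countries}")
        lo, hi = self.debt_ratio_range
        if not (0 <= lo < hi):
            raise ValidationError(f"debt_ratio_range must be ordered and >= 0, got {lo, hi}")
        if not 0.0 <= self.coral_zero_fraction <= 1.0:
            raise ValidationError("coral_zero_fraction must be in [0, 1]")
        names = [l.name for l in self.layer_catalog]
        if len(set(names)) != len(names):
            raise ValidationError("layer_catalog contains duplicate layer names")
        for spec in self.layer_catalog:
            if not 0.0 < spec.mean < 1.0:
                raise ValidationError(f"layer {spec.name!r}: mean must be in (0, 1)")
            if spec.concentration <= 0:
                raise ValidationError(f"layer {spec.name!r}: concentration must be > 0")
            if spec.threat_class not in (ABATABLE, UNABATABLE):
                raise ValidationError(f"layer {spec.name!r}: bad class {spec.threat_class!r}")
        if not any(l.threat_class == ABATABLE for l in self.layer_catalog) or not any(
            l.threat_class == UNABATABLE for l in self.layer_catalog
        ):
            raise ValidationError("layer_catalog needs at least one layer of each class")


def base_schemes(catalog: list[LayerSpec]) -> tuple[ClassificationScheme, ClassificationScheme]:
    """The classification-sensitivity pair: shipping abatable (A) vs unabatable (B)."""
    base = {l.name: l.threat_class for l in catalog}
    scheme_a = ClassificationScheme(scheme_id="shipping-abatable", assignment=dict(base))
    flipped = dict(base)
    if SHIPPING_LAYER in flipped:
        flipped[SHIPPING_LAYER] = UNABATABLE
    scheme_b = ClassificationScheme(scheme_id="shipping-unabatable", assignment=flipped)
    return scheme_a, scheme_b


def generate(
    config: GeneratorConfig,
) -> tuple[list[CountryRecord], ThreatLayerTable, tuple[ClassificationScheme, ClassificationScheme]]:
    """Draw a candidate pool, its threat-layer table, and the scheme pair.

    Deterministic given the config (including its seed); every layer value is
    in [0, 1], areas are non-negative, debt ratios lie in the configured
    range, and the output passes the same validation as loaded real data.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_countries
    ids = [f"C{i + 1:03d}" for i in range(n)]

    lo, hi = config.debt_ratio_range
    debt = rng.uniform(lo, hi, size=n)
    eez = np.exp(rng.normal(config.eez_log_mean, config.eez_log_sd, size=n))
    coral = np.exp(rng.normal(config.coral_log_mean, config.coral_log_sd, size=n))
    coral *= rng.random(n) >= config.coral_zero_fraction

    values: dict[tuple[str, str], float] = {}
    for spec in config.layer_catalog:
        a = spec.mean * spec.concentration
        b = (1.0 - spec.mean) * spec.concentration
        draws = rng.beta(a, b, size=n)
        for cid, v in zip(ids, draws):
            values[(cid, spec.name)] = float(v)

    records = [
        CountryRecord(
            country_id=cid,
            name=f"Country {cid[1:]}",
            debt_to_gdp=float(debt[i]),
            benefits={"eez_area_km2": float(eez[i]), "coral_area_km2": float(coral[i])},
        )
        for i, cid in enumerate(ids)
    ]
    table = ThreatLayerTable(
        layer_names=[l.name for l in config.layer_catalog], values=values
    )
    return records, table, base_schemes(config.layer_catalog)


def mean_discount_loss(config: GeneratorConfig) -> float:
    """mean(α·I_u) over a pool generated from ``config``, with α = 1/max(I_u).

    This is the average fraction of the expected benefit removed by the
    unabatable-threat discount; the scheme used is the catalog's own
    classification (scheme A).
    """
    _, table, (scheme_a, _) = generate(config)
    summaries = summarize_threats(table, scheme_a)
    alpha = compute_alpha(summaries)
    return float(np.mean([alpha.value * s.i_unabatable for s in summaries]))


def _scaled(config: GeneratorConfig, factor: float) -> GeneratorConfig:
    catalog = [
        replace(l, mean=min(l.mean * factor, 0.999)) if l.threat_class == UNABATABLE else l
        for l in config.layer_catalog
    ]
    return replace(config, layer_catalog=catalog)


def calibrate_discount(
    config: GeneratorConfig,
    target_mean_discount_loss: float = 0.54,
    tolerance: float = 0.10,
    max_iter: int = 60,
) -> tuple[GeneratorConfig, float]:
    """Scale unabatable layer means until mean(α·I_u) ≈ target.

    Because α = 1/max(I_u) is itself pool-derived, uniformly rescaling the
    unabatable burdens leaves α·I_u unchanged *except* through the Beta
    variance: with concentration held fixed, a smaller mean has a larger
    coefficient of variation, spreading I_u across countries and pulling the
    pool mean away from the pool max. mean(α·I_u) is therefore monotone in
    the scale factor and a deterministic bisection (same seed every
    evaluation) finds it. Returns ``(adjusted_config, achieved_value)``;
    raises :class:`ValidationError` with the closest achieved value when the
    target is outside the attainable range.
    """
    if not 0.0 < target_mean_discount_loss < 1.0:
        raise ValidationError("target_mean_discount_loss must be in (0, 1)")
    current = mean_discount_loss(config)
    if abs(current - target_mean_discount_loss) <= tolerance:
        return config, current

    lo, hi = 1e-3, 1.0
    max_mean = max(
        (l.mean for l in config.layer_catalog if l.threat_class == UNABATABLE), default=0.0
    )
    if max_mean > 0:
        hi = min(10.0, 0.999 / max_mean)  # keep scaled means inside (0, 1)
    f_lo = mean_discount_loss(_scaled(config, lo))
    f_hi = mean_discount_loss(_scaled(config, hi))
    lo_v, hi_v = min(f_lo, f_hi), max(f_lo, f_hi)
    if not lo_v <= target_mean_discount_loss <= hi_v:
        closest = f_lo if abs(f_lo - target_mean_discount_loss) < abs(
            f_hi - target_mean_discount_loss
        ) else f_hi
        raise ValidationError(
            f"target mean discount loss {target_mean_discount_loss} unattainable by scaling "
            f"(achievable range ≈ [{lo_v:.3f}, {hi_v:.3f}]; closest achieved {closest:.3f})"
        )
    increasing = f_hi >= f_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = mean_discount_loss(_scaled(config, mid))
        if abs(f_mid - target_mean_discount_loss) <= tolerance / 4:
            return _scaled(config, mid), f_mid
        if (f_mid < target_mean_discount_loss) == increasing:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    achieved = mean_discount_loss(_scaled(config, mid))
    if abs(achieved - target_mean_discount_loss) <= tolerance:
        return _scaled(config, mid), achieved
    raise ValidationError(
        f"calibration did not converge: target {target_mean_discount_loss}, "
        f"achieved {achieved:.3f}"
    )
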