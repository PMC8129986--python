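import pytest

from bluedebt import (
    ClassificationScheme,
    CountryRecord,
    ThreatLayerTable,
)


def make_country(cid, debt=0.6, eez=1000.0, coral=50.0, **kwargs):
    return CountryRecord(
        country_id=cid,
        name=f"Country {cid}",
        debt_to_gdp=debt,
        benefits={"eez_area_km2": eez, "coral_area_km2": coral},
        **kwargs,
    )


@pytest.fixture
def five_countries():
    """Small fixed pool spanning the debt thresholds with distinct benefits."""
    return [
        make_country("AAA", debt=0.30, eez=5.0e5, coral=100.0),
        make_country("BBB", debt=0.50, eez=2.0e6, coral=900.0),
        make_country("CCC", debt=0.65, eez=1.2e6, coral=20.0),
        make_country("DDD", debt=0.85, eez=3.0e5, coral=500.0),
        make_country("EEE", debt=1.05, eez=8.0e5, coral=0.0),
    ]


@pytest.fixture
def five_layers():
    """3 layers x 5 countries, values chosen by hand for easy arithmetic."""
    values = {
        ("AAA", "fishing"): 0.20, ("AAA", "shipping"): 0.10, ("AAA", "heat"): 0.50,
        ("BBB", "fishing"): 0.60, ("BBB", "shipping"): 0.40, ("BBB", "heat"): 0.90,
        ("CCC", "fishing"): 0.30, ("CCC", "shipping"): 0.20, ("CCC", "heat"): 0.70,
        ("DDD", "fishing"): 0.80, ("DDD", "shipping"): 0.05, ("DDD", "heat"): 0.60,
        ("EEE", "fishing"): 0.10, ("EEE", "shipping"): 0.30, ("EEE", "heat"): 0.80,
    }
    return ThreatLayerTable(layer_names=["fishing", "shipping", "heat"], values=values)


@pytest.fixture
def scheme_pair():
    """Shipping abatable (A) vs. shipping unabatable (B)."""
    a = ClassificationScheme(
        scheme_id="A",
        assignment={"fishing": "abatable", "shipping": "abatable", "heat": "unabatable"},
    )
    b = ClassificationScheme(
        scheme_id="B",
        assignment={"fishing": "abatable", "shipping": "unabatable", "heat": "unabatable"},
    )
    return a, b
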