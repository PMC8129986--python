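"""Readers and writers for country tables, threat layers, schemes and results.

All tabular I/O goes through pandas; schemes and reports are plain JSON. The
writers are deterministic: re-running on identical inputs reproduces
byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from .models import (
    REQUIRED_BENEFITS,
    ClassificationScheme,
    CountryRecord,
    PrioritizationError,
    ThreatLayerTable,
    ValidationError,
    check_unique_ids,
)

if TYPE_CHECKING:  # pragma: no cover
    from .compare import ComparisonReport
    from .scenarios import ScenarioResult

log = logging.getLogger(__name__)

_COUNTRY_REQUIRED = ("country_id", "debt_to_gdp") + REQUIRED_BENEFITS
_COUNTRY_SPECIAL = set(_COUNTRY_REQUIRED) | {"name", "p_success", "cost"}

def _full_precision(v: float) -> str:
    """Shortest round-trip decimal form of a float (repr of the Python float)."""
    return repr(float(v))


#: Column order of one scenario's ranked results CSV.
RESULT_COLUMNS = [
    "rank", "country_id", "B", "I_a", "I_u", "discount",
    "expected_benefit", "p_success", "cost", "ce_score",
]


def _to_float(raw: object, row: object, col: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"unparseable numeric value {raw!r} at row {row}, column {col!r}"
        ) from None


def load_country_table(
    path: str | Path, format: str = "csv", percent: bool = False
) -> list[CountryRecord]:
    """Read and validate a candidate-country table.

    Required columns: ``country_id``, ``debt_to_gdp``, ``eez_area_km2``,
    ``coral_area_km2``. Optional: ``name``, ``p_success``, ``cost``; any other
    column becomes an ``extras`` field addressable by screening rules. Missing
    ``p_success`` / ``cost`` are filled with 1 and the fill is logged.

    With ``percent=True`` the ``debt_to_gdp`` column is read as a percentage
    and divided by 100 (60 -> 0.60); the stored value is always a ratio.
    """
    if format != "csv":
        raise ValidationError(f"unsupported country-table format {format!r}")
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"country table not found: {path}")
    df = pd.read_csv(path, dtype={"country_id": str}, float_precision="round_trip")
    missing = [c for c in _COUNTRY_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"country table {path} missing column(s): {', '.join(missing)}")
    for col, default in (("p_success", 1.0), ("cost", 1.0)):
        if col not in df.columns:
            log.info("column %r absent in %s; filling default %s for all rows", col, path, default)
            df[col] = default
    extras_cols = [c for c in df.columns if c not in _COUNTRY_SPECIAL]

    records: list[CountryRecord] = []
    for idx, row in df.iterrows():
        cid = str(row["country_id"])
        debt = _to_float(row["debt_to_gdp"], idx, "debt_to_gdp")
        if percent:
            debt /= 100.0
        benefits = {k: _to_float(row[k], idx, k) for k in REQUIRED_BENEFITS}
        extras: dict[str, object] = {}
        for col in extras_cols:
            val = row[col]
            if pd.isna(val):
                continue
            extras[col] = bool(val) if isinstance(val, (bool,)) else val
        try:
            records.append(
                CountryRecord(
                    country_id=cid,
                    name=str(row["name"]) if "name" in df.columns and pd.notna(row.get("name")) else cid,
                    debt_to_gdp=debt,
                    benefits=benefits,
                    p_success=_to_float(row["p_success"], idx, "p_success"),
                    cost=_to_float(row["cost"], idx, "cost"),
                    extras=extras,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {idx} ({cid}): {err}") from None
    check_unique_ids(records)
    return records


def write_country_table(records: list[CountryRecord], path: str | Path) -> None:
    """Write a country table that :func:`load_country_table` reads back losslessly."""
    extras_keys: list[str] = []
    for rec in records:
        for k in rec.extras:
            if k not in extras_keys:
                extras_keys.append(k)
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "country_id": rec.country_id,
            "name": rec.name,
            "debt_to_gdp": rec.debt_to_gdp,
            **rec.benefits,
            "p_success": rec.p_success,
            "cost": rec.cost,
        }
        for k in extras_keys:
            row[k] = rec.extras.get(k)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_full_precision)


def load_threat_layers(path: str | Path, layout: str = "wide") -> ThreatLayerTable:
    """Read per-country threat-layer means in wide or long layout.

    Wide: one row per country (``country_id`` column), one column per layer,
    layer order = file column order. Long: columns ``country_id``,
    ``layer_name``, ``value``; layer order = first appearance. Values must lie
    in [0, 1]; a missing cell is a validation error (no imputation).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"threat-layer table not found: {path}")
    df = pd.read_csv(path, dtype={"country_id": str}, float_precision="round_trip")
    values: dict[tuple[str, str], float] = {}
    if layout == "wide":
        if "country_id" not in df.columns:
            raise ValidationError(f"{path}: wide layout requires a country_id column")
        layer_names = [c for c in df.columns if c != "country_id"]
        for idx, row in df.iterrows():
            cid = str(row["country_id"])
            for layer in layer_names:
                raw = row[layer]
                if pd.isna(raw):
                    raise ValidationError(
                        f"missing threat cell at (country={cid}, layer={layer}) in {path}"
                    )
                values[(cid, layer)] = _to_float(raw, idx, layer)
    elif layout == "long":
        needed = ("country_id", "layer_name", "value")
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: long layout missing column(s): {', '.join(missing)}")
        layer_names = []
        for idx, row in df.iterrows():
            cid, layer = str(row["country_id"]), str(row["layer_name"])
            if layer not in layer_names:
                layer_names.append(layer)
            if (cid, layer) in values:
                raise ValidationError(
                    f"duplicate threat cell (country={cid}, layer={layer}) in {path}"
                )
            values[(cid, layer)] = _to_float(row["value"], idx, "value")
    else:
        raise ValidationError(f"unknown threat-layer layout {layout!r}")
    return ThreatLayerTable(layer_names=layer_names, values=values)


def load_classification(path: str | Path) -> ClassificationScheme:
    """Read a threat classification from JSON or CSV.

    JSON: ``{"scheme_id": ..., "assignment": {layer: "abatable"|"unabatable"}}``.
    CSV: columns ``layer_name``, ``threat_class`` (scheme_id = file stem).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"classification file not found: {path}")
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        if "assignment" not in payload:
            raise ValidationError(f"{path}: missing 'assignment' mapping")
        return ClassificationScheme(
            scheme_id=str(payload.get("scheme_id", path.stem)),
            assignment={str(k): str(v) for k, v in payload["assignment"].items()},
        )
    df = pd.read_csv(path)
    missing = [c for c in ("layer_name", "threat_class") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s): {', '.join(missing)}")
    assignment = {str(r.layer_name): str(r.threat_class) for r in df.itertuples()}
    return ClassificationScheme(scheme_id=path.stem, assignment=assignment)


def write_classification(scheme: ClassificationScheme, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {"scheme_id": scheme.scheme_id, "assignment": scheme.assignment},
            indent=2, sort_keys=True,
        )
        + "\n"
    )


def _sanitize(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)


def scenario_frame(result: "ScenarioResult") -> pd.DataFrame:
    """One scenario's ranked candidates as a DataFrame in the results-CSV schema."""
    rows = [
        {
            "rank": c.rank,
            "country_id": c.country_id,
            "B": c.b,
            "I_a": c.i_abatable,
            "I_u": c.i_unabatable,
            "discount": c.discount,
            "expected_benefit": c.expected_benefit,
            "p_success": c.p_success,
            "cost": c.cost,
            "ce_score": c.ce_score,
        }
        for c in result.scored
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(
    results: list["ScenarioResult"],
    report: "ComparisonReport | None",
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Write one ranked CSV per scenario, the comparison report, and a run manifest.

    Returns the manifest (also written to ``manifest.json``). Output is a pure
    function of the inputs, so re-running reproduces byte-identical files.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise PrioritizationError(f"cannot create output directory {out}: {err}") from err
    if not results:
        log.warning("no scenario results to write; emitting manifest only")
    files: list[str] = []
    alphas: dict[str, float] = {}
    for res in results:
        fname = f"scenario_{_sanitize(res.scenario_id)}.csv"
        scenario_frame(res).to_csv(out / fname, index=False, float_format=_full_precision)
        files.append(fname)
        alphas[res.scenario_id] = res.alpha_used
    if report is not None:
        (out / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        files.append("report.json")
    manifest = {
        "scenario_files": files[: len(results)],
        "report_file": "report.json" if report is not None else None,
        "alpha_by_scenario": alphas,
        "scheme_ids": sorted({r.scheme_id for r in results}),
        "pool_sizes": {r.scenario_id: r.pool_size for r in results},
        "seed": seed,
        "config": config,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
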