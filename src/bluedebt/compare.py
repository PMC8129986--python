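"""Robustness of priorities across scenarios: Jaccard overlap and membership.

Two scenarios agree to the extent their top-k priority sets overlap; the
Jaccard index |A∩B| / |A∪B| quantifies that on [0, 1]. Scenarios whose
candidate pool is smaller than k cannot fill a top-k set and are excluded
from the comparison (with the reason recorded) rather than compared on
unequal footing. Membership counts — in how many solution sets each country
appears — show which priorities are robust to the scenario construction and
which are artifacts of one particular choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import ConfigurationError, DomainError
from .scenarios import ScenarioResult


def jaccard_index(a: set[str], b: set[str]) -> float:
    """|a ∩ b| / |a ∪ b|. Both-empty input is undefined and raises."""
    if not a and not b:
        raise DomainError("Jaccard index of two empty sets is undefined")
    return len(a & b) / len(a | b)


def attainable_jaccard(k: int) -> list[float]:
    """All Jaccard values two distinct size-k sets can attain: i/(2k−i), i=0..k."""
    return [i / (2 * k - i) for i in range(k + 1)]


@dataclass
class ComparisonReport:
    """Pairwise Jaccard matrix over top-k sets plus membership frequencies."""

    compared_scenarios: list[str]
    excluded_scenarios: list[dict[str, str]]
    k: int
    jaccard: list[list[float]]
    jaccard_min: float
    jaccard_max: float
    jaccard_mean: float
    union_set: list[str]
    #: country_id -> {"count": sets containing it, "fraction": count / #compared}
    membership: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "compared_scenarios": self.compared_scenarios,
            "excluded_scenarios": self.excluded_scenarios,
            "k": self.k,
            "jaccard": self.jaccard,
            "jaccard_min": self.jaccard_min,
            "jaccard_max": self.jaccard_max,
            "jaccard_mean": self.jaccard_mean,
            "union_set": self.union_set,
            "membership": self.membership,
        }


def compare_topk(results: list[ScenarioResult], k: int) -> ComparisonReport:
    """Pairwise Jaccard over the top-k sets of comparable scenarios.

    A scenario with ``pool_size < k`` is excluded (reason ``pool_size<k``);
    at least two scenarios must remain. Membership counts are taken over the
    compared scenarios only, so the union scope of the report is explicit.
    """
    ids = [r.scenario_id for r in results]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate scenario ids in comparison input")
    compared = [r for r in results if r.pool_size >= k]
    excluded = [
        {"scenario_id": r.scenario_id, "reason": f"pool_size<{k} (pool_size={r.pool_size})"}
        for r in results
        if r.pool_size < k
    ]
    if len(compared) < 2:
        raise ConfigurationError(
            f"need at least 2 scenarios with pool_size >= k={k} to compare; "
            f"have {len(compared)} ({len(excluded)} excluded)"
        )
    sets = [r.top_set(k) for r in compared]
    n = len(sets)
    matrix = [[1.0] * n for _ in range(n)]
    off_diag: list[float] = []
    for i in range(n):
        for j in range(i + 1, n):
            v = jaccard_index(sets[i], sets[j])
            matrix[i][j] = matrix[j][i] = v
            off_diag.append(v)
    union = sorted(set().union(*sets))
    membership = {
        cid: {
            "count": sum(cid in s for s in sets),
            "fraction": sum(cid in s for s in sets) / n,
        }
        for cid in union
    }
    return ComparisonReport(
        compared_scenarios=[r.scenario_id for r in compared],
        excluded_scenarios=excluded,
        k=k,
        jaccard=matrix,
        jaccard_min=min(off_diag),
        jaccard_max=max(off_diag),
        jaccard_mean=sum(off_diag) / len(off_diag),
        union_set=union,
        membership=membership,
    )


def _round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4), matching report-style percentages."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def membership_summary(report: ComparisonReport):
    """Membership table and count distribution for the rendered report.

    Returns ``(rows, distribution)``: rows are ``(country_id, count, fraction)``
    sorted by count descending then country_id; the distribution maps each
    count value to the number and percentage of union-set countries with that
    count (raw and whole-percent, rounded half away from zero).
    """
    rows = sorted(
        ((cid, int(m["count"]), m["fraction"]) for cid, m in report.membership.items()),
        key=lambda r: (-r[1], r[0]),
    )
    total = len(rows)
    distribution: dict[int, dict[str, float]] = {}
    for _, count, _ in rows:
        distribution.setdefault(count, {"n": 0})["n"] += 1
    for count, entry in distribution.items():
        pct = 100.0 * entry["n"] / total
        entry["pct_raw"] = pct
        entry["pct"] = _round_half_away(pct)
    return rows, distribution


def render_report(report: ComparisonReport) -> str:
    """Human-readable summary: Jaccard to 2 decimals, membership in whole percent."""
    lines = [
        f"Compared {len(report.compared_scenarios)} scenarios at k={report.k}; "
        f"{len(report.excluded_scenarios)} excluded.",
    ]
    for exc in report.excluded_scenarios:
        lines.append(f"  excluded: {exc['scenario_id']} ({exc['reason']})")
    lines.append(
        f"Jaccard overlap of top-{report.k} sets: "
        f"min={report.jaccard_min:.2f} mean={report.jaccard_mean:.2f} max={report.jaccard_max:.2f}"
    )
    rows, distribution = membership_summary(report)
    lines.append(f"Union of top-{report.k} sets: {len(rows)} countries")
    for count in sorted(distribution, reverse=True):
        d = distribution[count]
        lines.append(
            f"  in {count} solution set(s): {int(d['n'])} countries ({int(d['pct'])}%)"
        )
    return "\n".join(lines)
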