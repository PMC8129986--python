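"""Bar-chart export of original vs. threat-adjusted expected benefit."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .scenarios import ScenarioResult


def benefit_comparison_chart(
    result: ScenarioResult, path: str | Path, top_n: int = 10
) -> None:
    """Plot original benefit B against expected benefit B·I_a·(1−α·I_u).

    Shows how accounting for threats reshuffles priorities: a country with a
    large raw benefit but a heavy unabatable burden can drop below smaller
    countries whose threat load is mostly abatable. The top ``top_n``
    candidates by expected benefit are drawn.
    """
    top = result.scored[:top_n]
    labels = [c.country_id for c in top]
    x = range(len(top))
    fig, ax = plt.subplots(figsize=(8, 4.5))
    width = 0.4
    ax.bar([i - width / 2 for i in x], [c.b for c in top], width, label="original benefit (B)")
    ax.bar(
        [i + width / 2 for i in x],
        [c.expected_benefit for c in top],
        width,
        label="expected benefit (B·I_a·(1−α·I_u))",
    )
    ax.set_xticks(list(x))
    ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_ylabel(f"{top[0].benefit_field if top else 'benefit'} (km²)")
    ax.set_title(f"Scenario {result.scenario_id}: benefit before vs. after threat adjustment")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
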