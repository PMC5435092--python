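"""Optional figures: per-age strategy curves and a 3-set Venn diagram."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Circle

from .comorbidity import VennCounts

_STRATEGY_STYLE = {1: "C0--", 2: "C1-", 3: "C2--", 4: "C3-"}


def plot_prevalence_curves(prevalence, disorder: str, path: str | Path) -> Path:
    """Plot per-age prevalence for one disorder, one curve per strategy."""
    sub = prevalence[prevalence["disorder"] == disorder]
    fig, ax = plt.subplots(figsize=(6, 4))
    for strategy, grp in sub.groupby("strategy"):
        grp = grp.sort_values("age")
        ax.plot(
            grp["age"],
            grp["percent"],
            _STRATEGY_STYLE.get(int(strategy), "k-"),
            label=f"strategy {strategy}",
        )
    ax.set_xlabel("age (years)")
    ax.set_ylabel("prevalence (%)")
    ax.set_title(disorder)
    ax.set_xticks(range(0, 19, 2))
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_venn(venn: VennCounts, path: str | Path) -> Path:
    """Three-circle Venn diagram of period co-occurrence, counts annotated."""
    fig, ax = plt.subplots(figsize=(6, 6))
    centers = {"eczema": (-0.35, 0.25), "asthma": (0.35, 0.25), "rhinitis": (0.0, -0.4)}
    colors = {"eczema": "C0", "asthma": "C1", "rhinitis": "C2"}
    for name, (x, y) in centers.items():
        ax.add_patch(Circle((x, y), 0.65, alpha=0.3, color=colors[name]))
        ax.text(x, y + 0.72, f"{name} ({venn.marginal(name)})", ha="center")
    labels = {
        (-0.55, 0.35): venn.eczema_only,
        (0.55, 0.35): venn.asthma_only,
        (0.0, -0.65): venn.rhinitis_only,
        (0.0, 0.45): venn.eczema_asthma,
        (-0.35, -0.15): venn.eczema_rhinitis,
        (0.35, -0.15): venn.asthma_rhinitis,
        (0.0, 0.05): venn.all_three,
    }
    for (x, y), count in labels.items():
        ax.text(x, y, str(count), ha="center", va="center")
    ax.text(-1.1, -1.05, f"no atopic disorder: {venn.none} / total {venn.total}")
    ax.set_xlim(-1.2, 1.2)
    ax.set_ylim(-1.2, 1.2)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
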