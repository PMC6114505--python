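"""Optional figures mirroring the standard compendium-overview panels.

Imported lazily by the pipeline so headless runs without matplotlib
installed (or without a display) never touch a plotting backend unless
figures were requested.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .io import CATEGORIES


def _get_pyplot():
    import matplotlib

    matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt

    return plt


def make_all_figures(out_dir, profile_counts, category_dist, replicate_hists,
                     by_cell, activity_report) -> list[str]:
    plt = _get_pyplot()
    out = Path(out_dir)
    made = []

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(profile_counts["cell_id"], profile_counts["count"])
    ax.set_ylabel("signature profiles")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(out / "fig_profile_counts.png", dpi=120)
    plt.close(fig)
    made.append("fig_profile_counts.png")

    fig, ax = plt.subplots(figsize=(7, 4))
    bottom = None
    for cat in CATEGORIES:
        vals = category_dist[cat]
        ax.bar(category_dist.index, vals, bottom=bottom, label=cat)
        bottom = vals if bottom is None else bottom + vals
    ax.set_ylabel("profiles")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "fig_category_distribution.png", dpi=120)
    plt.close(fig)
    made.append("fig_category_distribution.png")

    rep_frame = pd.DataFrame(
        {cell: hist.as_series() for cell, hist in replicate_hists.items()}
    )
    fig, ax = plt.subplots(figsize=(7, 4))
    rep_frame.plot.bar(ax=ax)
    ax.set_xlabel("replicates")
    ax.set_ylabel("profiles")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out / "fig_replicates.png", dpi=120)
    plt.close(fig)
    made.append("fig_replicates.png")

    ge_cols = [c for c in by_cell.columns if c.startswith("ge_")]
    fig, ax = plt.subplots(figsize=(7, 4))
    by_cell.set_index("cell_id")[ge_cols].plot.bar(ax=ax)
    ax.set_ylabel("profiles")
    fig.tight_layout()
    fig.savefig(out / "fig_deg_categories.png", dpi=120)
    plt.close(fig)
    made.append("fig_deg_categories.png")

    # four-segment activity plot per cell line, A (low dose / 6 h) -> B
    cells = list(activity_report["cell_id"])
    n = len(cells)
    if n:
        ncol = min(3, n)
        nrow = (n + ncol - 1) // ncol
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False)
        segs = [
            ("pct_low_50", "pct_high_50", "dose >=50", "green"),
            ("pct_low_100", "pct_high_100", "dose >=100", "blue"),
            ("pct_6h_50", "pct_24h_50", "time >=50", "red"),
            ("pct_6h_100", "pct_24h_100", "time >=100", "orange"),
        ]
        for i, row in activity_report.iterrows():
            ax = axes[i // ncol][i % ncol]
            for a_col, b_col, label, color in segs:
                ax.plot([0, 1], [row[a_col], row[b_col]], color=color, label=label)
            ax.set_title(str(row["cell_id"]), fontsize=8)
            ax.set_xticks([0, 1], ["A", "B"])
        axes[0][0].legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(out / "fig_activity_change.png", dpi=120)
        plt.close(fig)
        made.append("fig_activity_change.png")
    return made
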