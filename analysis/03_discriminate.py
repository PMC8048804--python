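#!/usr/bin/env python
"""Per-horse Youden-index sensitivity/specificity of every stride variable,
group medians, and the dot heat map (sensitivity = colour, specificity =
dot size).  Writes results/heatmap_{gait}.csv, results/heatmap_summary_{gait}.csv
and results/figures/heatmap_{gait}.png, and prints the top-ranked variables.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from lamegait.discrim import heatmap_table, youden_table


def plot_heatmap(grid: pd.DataFrame, summary: pd.DataFrame, path: Path, gait: str) -> None:
    order = summary["variable"].tolist()
    horses = sorted(grid["horse_id"].unique())
    fig, ax = plt.subplots(figsize=(6, 0.28 * len(order) + 1.5))
    for _, row in grid.iterrows():
        y = order.index(row["variable"])
        x = horses.index(row["horse_id"])
        ax.scatter(x, y, s=10 + 120 * row["specificity"], c=[[row["sensitivity"]]],
                   cmap="viridis", vmin=0, vmax=1, edgecolors="none")
    ax.set_xticks(range(len(horses)), horses, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    ax.set_title(f"{gait}: sensitivity (colour) / specificity (size)")
    ax.invert_yaxis()
    fig.colorbar(plt.cm.ScalarMappable(cmap="viridis"), ax=ax, label="sensitivity")
    fig.tight_layout()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--strides", type=Path, default=Path("results/strides.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    strides = pd.read_csv(args.strides)
    for gait, sub in strides.groupby("gait"):
        cells = youden_table(sub, sorted(sub["variable"].unique()))
        grid, summary = heatmap_table(cells)
        grid.to_csv(args.out / f"heatmap_{gait}.csv", index=False)
        summary.to_csv(args.out / f"heatmap_summary_{gait}.csv", index=False)
        plot_heatmap(grid, summary, args.out / "figures" / f"heatmap_{gait}.png", gait)
        print(f"\n{gait}: top variables by median Youden J")
        print(summary.head(8).to_string(index=False))


if __name__ == "__main__":
    main()
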