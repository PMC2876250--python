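#!/usr/bin/env python
"""Build the comparison table and group-mean figures.

Produces the per-layer report — absolute group means, signed percent
differences for the three contrasts (rearing; wheel running within each
rearing group) and post hoc significance strings — plus mean +/- SEM bar
charts per region.
"""

import argparse
from pathlib import Path

import matplotlib.pyplot as plt
import pandas as pd

from silverquant.reporting import build_table, plot_group_means
from silverquant.stats import region_analysis


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cells", type=Path, default=Path("results/group_cells.csv"))
    ap.add_argument("--animals", type=Path, default=Path("results/animal_means.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/comparison_table.csv"))
    ap.add_argument("--figures", type=Path, default=Path("results/figures"))
    args = ap.parse_args()

    cells = pd.read_csv(args.cells)
    animals = pd.read_csv(args.animals)
    posthoc = {
        region: region_analysis(animals, region).posthoc
        for region in ("DG", "CA3", "CA1", "EC")
    }
    # posthoc group keys arrive as tuples; CSV round-trips stringify them,
    # so the lookup here runs on the in-memory results
    for ph in posthoc.values():
        ph["group1"] = ph["group1"].apply(tuple)
        ph["group2"] = ph["group2"].apply(tuple)
    table = build_table(cells, posthoc)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(table.to_string(index=False))
    print(f"\ncomparison table -> {args.out}")

    args.figures.mkdir(parents=True, exist_ok=True)
    for region in ("DG", "CA3", "CA1", "EC", "SUB"):
        ax = plot_group_means(cells, region)
        fig_path = args.figures / f"group_means_{region}.png"
        ax.figure.tight_layout()
        ax.figure.savefig(fig_path, dpi=150)
        plt.close(ax.figure)
        print(f"figure -> {fig_path}")


if __name__ == "__main__":
    main()
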