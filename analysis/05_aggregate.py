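#!/usr/bin/env python
"""Aggregate section counts to animal-level means and group cells.

Animals are the sampling unit: section counts are averaged within animal
and layer first, then group means and SEMs are taken over animals.
"""

import argparse
from pathlib import Path

import pandas as pd

from silverquant.aggregate import animal_layer_means, group_summary


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--counts", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out-animals", type=Path, default=Path("results/animal_means.csv"))
    ap.add_argument("--out-cells", type=Path, default=Path("results/group_cells.csv"))
    args = ap.parse_args()

    records = pd.read_csv(args.counts)
    animals = animal_layer_means(records)
    cells = group_summary(animals)
    args.out_animals.parent.mkdir(parents=True, exist_ok=True)
    animals.to_csv(args.out_animals, index=False)
    cells.to_csv(args.out_cells, index=False)
    print(f"{len(animals)} animal x layer means -> {args.out_animals}")
    print(f"{len(cells)} group cells (mean +/- SEM over animals) -> {args.out_cells}")
    print(cells.head(8).to_string(index=False))


if __name__ == "__main__":
    main()
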