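#!/usr/bin/env python
"""Simulate a dark-field section montage with laminar measuring fields.

Builds one synthetic "section" image per requested region: for every
measuring field of the region a 600 x 50 patch of bright, well-separated
precipitates is rendered at a density taken from the published enriched-
reared group means, then pasted into a montage at its field anchor. Writes
the montage TIFFs, the field-placement table and the per-field ground
truth, which `02_count_fields.py` consumes.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from silverquant.fields import enumerate_fields
from silverquant.synthetic import (
    DEFAULT_GROUP_MEANS,
    ImageSimSpec,
    generate_image,
    write_image,
)

MARGIN = 10


def simulate_section(region: str, seed: int, noise_sigma: float):
    labels = enumerate_fields(region)
    h_canvas = MARGIN + len(labels) * (50 + MARGIN)
    canvas_rng = np.random.default_rng(seed)
    canvas = np.clip(
        canvas_rng.normal(0.05, noise_sigma, size=(h_canvas, 600 + 2 * MARGIN)),
        0, 1,
    )
    placements, truths = [], []
    for i, label in enumerate(labels):
        n_spots = int(DEFAULT_GROUP_MEANS[(label.region, label.layer, label.blade, "ER", "no")])
        spec = ImageSimSpec(n_spots=n_spots, noise_sigma=noise_sigma, seed=seed + i)
        patch, truth = generate_image(spec)
        r0, c0 = MARGIN + i * (50 + MARGIN), MARGIN
        canvas[r0 : r0 + 50, c0 : c0 + 600] = patch
        placements.append(
            {
                "section_id": f"{region}-s01",
                "region": label.region,
                "layer": label.layer,
                "blade": label.blade,
                "anchor_row": r0,
                "anchor_col": c0,
                "height": 50,
                "orientation_deg": 0.0,
            }
        )
        gt = truth.to_frame()
        gt.insert(0, "layer", label.layer)
        gt.insert(1, "blade", label.blade)
        gt["n_spots"] = n_spots
        truths.append(gt)
    return canvas, pd.DataFrame(placements), pd.concat(truths, ignore_index=True)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--regions", nargs="+", default=["DG", "CA1"])
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--noise-sigma", type=float, default=0.05)
    ap.add_argument("--image-dir", type=Path, default=Path("scratch/images"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    args.image_dir.mkdir(parents=True, exist_ok=True)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    all_placements, all_truths = [], []
    for i, region in enumerate(args.regions):
        canvas, placements, truth = simulate_section(
            region, seed=args.seed + 1000 * i, noise_sigma=args.noise_sigma
        )
        img_path = args.image_dir / f"section_{region}.tif"
        write_image(img_path, canvas)
        placements["image"] = str(img_path)
        truth.insert(0, "region", region)
        all_placements.append(placements)
        all_truths.append(truth)
        print(f"{region}: montage {canvas.shape} with {len(placements)} fields "
              f"and {truth['area_px'].count()} true precipitates -> {img_path}")
    pd.concat(all_placements, ignore_index=True).to_csv(
        args.out_dir / "placements.csv", index=False
    )
    pd.concat(all_truths, ignore_index=True).to_csv(
        args.out_dir / "ground_truth.csv", index=False
    )
    print(f"placement table and ground truth written to {args.out_dir}/")


if __name__ == "__main__":
    main()
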