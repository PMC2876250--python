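#!/usr/bin/env python
"""Benchmark the detector against ground truth over seeded images.

Measures recall and precision on 600 x 50 fields carrying 50-400
well-separated spots with the dimmest spot at SNR 5, plus exact-count
recovery on noise-free images, and writes a per-image table.
"""

import argparse
from pathlib import Path

from silverquant.validation import detection_benchmark, zero_noise_exactness


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-images", type=int, default=100)
    ap.add_argument("--noise-sigma", type=float, default=0.11)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/detection_validation.csv"))
    args = ap.parse_args()

    bench = detection_benchmark(
        n_images=args.n_images, seed=args.seed, noise_sigma=args.noise_sigma
    )
    exact = zero_noise_exactness(n_images=20, seed=args.seed)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    bench["per_image"].to_csv(args.out, index=False)
    print(
        f"{args.n_images} noisy fields (sigma={args.noise_sigma}): "
        f"recall {bench['recall']:.4f}, precision {bench['precision']:.4f} "
        f"over {bench['n_true']} true spots"
    )
    print(f"20 noise-free fields: {exact['exact_fraction']:.0%} counted exactly")
    print(f"per-image table written to {args.out}")


if __name__ == "__main__":
    main()
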