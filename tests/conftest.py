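import numpy as np
import pandas as pd
import pytest

from silverquant.synthetic import CohortSimSpec, generate_cohort


@pytest.fixture(scope="session")
def zero_noise_cohort() -> pd.DataFrame:
    """Cohort drawn with zero between-animal and between-section noise:
    every record equals its design cell's mean exactly."""
    spec = CohortSimSpec(animal_sd=0.0, section_sd=0.0, seed=11)
    return generate_cohort(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


def random_rect_mask(
    rng: np.random.Generator,
    shape: tuple[int, int] = (50, 600),
    n_rects: int = 50,
    max_side: int = 5,
    min_gap: int = 0,
) -> np.ndarray:
    """Random rectangles on a canvas; ``min_gap`` > 0 keeps them separated
    (Chebyshev edge-to-edge) so they form exactly ``n_rects`` components."""
    mask = np.zeros(shape, dtype=bool)
    placed: list[tuple[int, int, int, int]] = []
    attempts = 0
    while len(placed) < n_rects and attempts < 50_000:
        attempts += 1
        h = int(rng.integers(1, max_side + 1))
        w = int(rng.integers(1, max_side + 1))
        r = int(rng.integers(0, shape[0] - h + 1))
        c = int(rng.integers(0, shape[1] - w + 1))
        if min_gap:
            ok = all(
                not (
                    r - min_gap < pr + ph and pr - min_gap < r + h
                    and c - min_gap < pc + pw and pc - min_gap < c + w
                )
                for pr, pc, ph, pw in placed
            )
            if not ok:
                continue
        placed.append((r, c, h, w))
        mask[r : r + h, c : c + w] = True
    if len(placed) < n_rects:
        raise RuntimeError("could not place rectangles")
    return mask
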