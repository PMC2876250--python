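"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a route disjoint from the package's
implementation: BFS flood fill for component counting, explicit sum-coded
design-matrix least squares for Type III ANOVA, and Monte Carlo for the
studentized range distribution.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
import pandas as pd


def flood_fill_count(mask: np.ndarray, connectivity: int = 8) -> int:
    """Count connected components by explicit breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    count = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                count += 1
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    cr, cc = queue.popleft()
                    for dr, dc in steps:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            queue.append((nr, nc))
    return count


def _sum_coded_columns(values: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero contrast columns (last sorted level as reference)."""
    levels = sorted(values.unique())
    cols = np.zeros((len(values), len(levels) - 1))
    arr = values.to_numpy()
    for j, level in enumerate(levels[:-1]):
        cols[arr == level, j] = 1.0
        cols[arr == levels[-1], j] = -1.0
    return cols, levels


def type3_anova_oracle(
    data: pd.DataFrame, response: str, factors: list[str]
) -> pd.DataFrame:
    """Type III sums of squares by explicit design-matrix projection.

    Builds the sum-coded full-factorial design, computes the residual sum
    of squares of the full model and of each model with one term's columns
    deleted; SS(term) is the RSS increase. F uses the full-model MSE.
    """
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    main_cols = {f: _sum_coded_columns(data[f])[0] for f in factors}

    # term -> column block (interactions are elementwise products)
    blocks: dict[str, np.ndarray] = {}
    for order in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, order):
            cols = main_cols[combo[0]]
            for f in combo[1:]:
                cols = np.concatenate(
                    [cols[:, [i]] * main_cols[f] for i in range(cols.shape[1])],
                    axis=1,
                )
            blocks[":".join(combo)] = cols

    def rss(matrix: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(matrix, y, rcond=None)
        resid = y - matrix @ beta
        return float(resid @ resid)

    intercept = np.ones((n, 1))
    full = np.concatenate([intercept] + list(blocks.values()), axis=1)
    rss_full = rss(full)
    df_resid = n - full.shape[1]

    rows = {}
    for term, cols in blocks.items():
        others = [intercept] + [b for t, b in blocks.items() if t != term]
        ss = rss(np.concatenate(others, axis=1)) - rss_full
        df_term = cols.shape[1]
        ms = ss / df_term
        f_stat = ms / (rss_full / df_resid)
        rows[term] = (df_term, ss, ms, f_stat)
    rows["Residual"] = (df_resid, rss_full, rss_full / df_resid, np.nan)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["df", "sum_sq", "mean_sq", "F"]
    )


def studentized_range_sf_mc(
    q: float, k: int, df: int, n_draws: int = 10**6, seed: int = 0
) -> tuple[float, float]:
    """Monte Carlo upper tail of the studentized range; returns (p, SE)."""
    rng = np.random.default_rng(seed)
    means = rng.standard_normal((n_draws, k))
    ranges = means.max(axis=1) - means.min(axis=1)
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    hits = ranges / s > q
    p = hits.mean()
    return float(p), float(np.sqrt(p * (1 - p) / n_draws))
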