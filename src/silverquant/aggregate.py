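"""Collapse section-level counts to the animal- and group-level summaries.

The sampling unit for group statistics is the animal: section counts are
averaged within each animal and layer first, and group means / SEMs are
then taken over animals. Animals missing a layer simply drop out of that
cell (logged as a warning), producing the unequal group sizes the post hoc
test is built for.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .synthetic import DEFAULT_SECTIONS_PER_ANIMAL

logger = logging.getLogger(__name__)

LABEL_KEYS = ["region", "layer", "blade"]
GROUP_KEYS = ["rearing", "wheel"]


def _fill_blade(df: pd.DataFrame) -> pd.DataFrame:
    # groupby drops None keys; use a sentinel for the blade-less regions
    out = df.copy()
    out["blade"] = out["blade"].fillna("-")
    return out


def _restore_blade(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["blade"] = df["blade"].where(df["blade"] != "-", None)
    return df


def animal_layer_means(records: pd.DataFrame) -> pd.DataFrame:
    """Per-animal mean count over sections, for every measured layer.

    ``records`` is a tidy count table (one row per animal x section x
    layer). Section counts per animal outside the study's sampling design
    (14-20 sections in DG/CA3/CA1, 6-8 in subiculum/EC) are tolerated with
    a warning. Returns one row per animal x layer with ``mean_count`` and
    ``n_sections``.
    """
    if records is None or len(records) == 0:
        raise ValueError("no count records to aggregate")
    if (records["count"] < 0).any():
        raise ValueError("counts must be >= 0")
    df = _fill_blade(records)
    keys = ["animal_id"] + GROUP_KEYS + LABEL_KEYS
    agg = (
        df.groupby(keys, sort=False, dropna=False)["count"]
        .agg(mean_count="mean", n_sections="size")
        .reset_index()
    )
    for _, row in agg.iterrows():
        lo, hi = DEFAULT_SECTIONS_PER_ANIMAL.get(row["region"], (1, np.inf))
        if not (lo <= row["n_sections"] <= hi):
            logger.warning(
                "animal %s has %d sections in %s/%s (expected %s-%s)",
                row["animal_id"], row["n_sections"], row["region"], row["layer"],
                lo, hi,
            )
    return _restore_blade(agg)


def group_summary(animal_means: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SEM over animals for every (group, layer) cell.

    SEM is sd/sqrt(n) over animal means (ddof=1); cells with a single
    animal get ``NaN`` SEM and a warning. Returns one row per cell with
    ``mean``, ``sem`` and ``n`` (animals).
    """
    if animal_means is None or len(animal_means) == 0:
        raise ValueError("no animal means to summarize")
    df = _fill_blade(animal_means)
    keys = GROUP_KEYS + LABEL_KEYS
    cells = (
        df.groupby(keys, sort=False, dropna=False)["mean_count"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="size")
        .reset_index()
    )
    cells["sem"] = cells["sd"] / np.sqrt(cells["n"])
    singletons = cells["n"] < 2
    if singletons.any():
        for _, row in cells[singletons].iterrows():
            logger.warning(
                "cell (%s, %s, %s/%s) has n=1 animal; SEM undefined",
                row["rearing"], row["wheel"], row["region"], row["layer"],
            )
    cells = cells.drop(columns="sd")
    return _restore_blade(cells)
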