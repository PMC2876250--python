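"""Comparison tables and summary figures for the four-group design.

The report mirrors the study's presentation: per layer, the absolute group
mean counts, signed integer percent differences for three contrasts
(enriched vs deprived rearing; each rearing group before vs after wheel
running) and a significance column ("n.s.", a trend p printed numerically
below .10, or a threshold string at .05/.01/.001).
"""

from __future__ import annotations

import logging
import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .fields import REGION_ORDER, all_labels

logger = logging.getLogger(__name__)

__all__ = ["percent_difference", "significance_string", "build_table", "plot_group_means"]

#: The three reported contrasts: (baseline (rearing, wheel), comparison).
CONTRASTS = [
    (("ER", "no"), ("DR", "no"), "ER_vs_DR"),
    (("ER", "no"), ("ER", "yes"), "ER_vs_ERwheel"),
    (("DR", "no"), ("DR", "yes"), "DR_vs_DRwheel"),
]


def percent_difference(baseline: float, comparison: float) -> int:
    """Signed integer percent change of ``comparison`` relative to ``baseline``.

    Rounds half away from zero, matching the signed integers of the printed
    table. Note the asymmetry: the denominator is always the baseline, so
    swapping the arguments does not merely flip the sign.
    """
    if not baseline > 0:
        raise ValueError("baseline mean must be > 0")
    pct = 100.0 * (comparison - baseline) / baseline
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))


def significance_string(p: float | None) -> str:
    """Render an adjusted p the way the study prints it."""
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return ""
    if p < 0.001:
        return "<.001"
    if p < 0.01:
        return "<.01"
    if p < 0.05:
        return "<.05"
    if p < 0.10:  # trends are printed numerically, e.g. ".09"
        return f"{p:.2f}".lstrip("0")
    return "n.s."


def _lamina_key(layer: str, blade) -> str:
    return f"{layer}/{blade}" if blade not in (None, "", "-") else layer


def _posthoc_lookup(posthoc: pd.DataFrame | None):
    if posthoc is None:
        return lambda *a: None
    table = {}
    for _, row in posthoc.iterrows():
        key = frozenset((row["group1"], row["group2"]))
        table[key] = row["p_adj"]
    return lambda c1, c2: table.get(frozenset((c1, c2)))


def build_table(
    cells: pd.DataFrame,
    posthoc: dict[str, pd.DataFrame] | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-layer comparison table.

    ``cells`` is the group summary (one row per (rearing, wheel) x layer
    with ``mean``); ``posthoc`` maps region -> all-pairs HSD results whose
    cells are keyed ``(lamina, rearing, wheel)``. Rows follow the canonical
    region -> layer -> blade order; layers with a missing group are emitted
    with missing-value markers and a warning. Pure function of its inputs.
    """
    key = cells.set_index(
        ["region", "layer", cells["blade"].fillna("-"), "rearing", "wheel"]
    )["mean"]
    if isinstance(posthoc, pd.DataFrame):
        posthoc = {region: posthoc for region in REGION_ORDER}
    rows = []
    for label in all_labels():
        blade_key = label.blade or "-"
        lamina = _lamina_key(label.layer, label.blade)
        lookup = _posthoc_lookup((posthoc or {}).get(label.region))
        row: dict = {
            "region": label.region,
            "layer": label.layer,
            "blade": label.blade,
        }
        means = {}
        for rearing, wheel in [(r, w) for r, w, in (("ER", "no"), ("DR", "no"), ("ER", "yes"), ("DR", "yes"))]:
            idx = (label.region, label.layer, blade_key, rearing, wheel)
            means[(rearing, wheel)] = key.get(idx, np.nan)
        row["mean_ER"] = means[("ER", "no")]
        row["mean_DR"] = means[("DR", "no")]
        row["mean_ERwheel"] = means[("ER", "yes")]
        row["mean_DRwheel"] = means[("DR", "yes")]
        if any(np.isnan(v) for v in means.values()):
            logger.warning("missing group mean for %s; row left incomplete", label)
        for base, comp, name in CONTRASTS:
            b, c = means[base], means[comp]
            if np.isnan(b) or np.isnan(c):
                row[f"pct_{name}"] = np.nan
                row[f"p_{name}"] = np.nan
                row[f"sig_{name}"] = ""
                continue
            row[f"pct_{name}"] = percent_difference(b, c)
            p = lookup((lamina,) + base, (lamina,) + comp)
            row[f"p_{name}"] = np.nan if p is None else p
            row[f"sig_{name}"] = significance_string(p)
        rows.append(row)
    out = pd.DataFrame(rows)
    for col in out.columns:
        if col.startswith("pct_"):
            out[col] = out[col].astype("Int64")
    return out


def plot_group_means(cells: pd.DataFrame, region: str, ax=None):
    """Grouped bar summary (mean +/- SEM over animals) for one region."""
    sub = cells[cells["region"] == region].copy()
    if len(sub) == 0:
        raise ValueError(f"no cells for region {region!r}")
    sub["lamina"] = [
        _lamina_key(l, b) for l, b in zip(sub["layer"], sub["blade"])
    ]
    laminae = list(dict.fromkeys(sub["lamina"]))
    groups = [("ER", "no"), ("DR", "no"), ("ER", "yes"), ("DR", "yes")]
    names = ["ER", "DR", "ER + wheel", "DR + wheel"]
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(laminae) + 2, 4))
    width = 0.8 / len(groups)
    x = np.arange(len(laminae))
    for gi, ((rearing, wheel), name) in enumerate(zip(groups, names)):
        g = sub[(sub["rearing"] == rearing) & (sub["wheel"] == wheel)]
        g = g.set_index("lamina").reindex(laminae)
        ax.bar(
            x + (gi - 1.5) * width,
            g["mean"],
            width,
            yerr=g["sem"],
            capsize=2,
            label=name,
        )
    ax.set_xticks(x)
    ax.set_xticklabels(laminae, rotation=45, ha="right")
    ax.set_ylabel("precipitates per measuring field")
    ax.set_title(region)
    ax.legend(fontsize=8)
    return ax
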