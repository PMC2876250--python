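"""Region-wise factorial ANOVA and the unequal-n Tukey HSD post hoc.

Each region is analysed separately with a fixed-effects factorial ANOVA on
the factors rearing condition, wheel running and layer (Type III sums of
squares under sum-to-zero contrasts, the appropriate decomposition for the
study's unbalanced 2 x 2 x layer design). Specific comparisons use the
Tukey-Kramer generalization of the HSD test to unequal group sizes, with
the error term taken from the region's full factorial model. The
Spjotvoll-Stoline variant (conservative: harmonic term replaced by the
smaller group's n) is available behind a flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AliasingError",
    "factorial_anova",
    "unequal_n_hsd",
    "studentized_range_p",
    "region_analysis",
]


class AliasingError(ValueError):
    """Empty design cells make one or more model terms inestimable."""


def _check_cells(data: pd.DataFrame, factors: list[str]) -> None:
    levels = [sorted(data[f].dropna().unique()) for f in factors]
    observed = set(data[factors].itertuples(index=False, name=None))
    empty = [cell for cell in itertools.product(*levels) if cell not in observed]
    if empty:
        raise AliasingError(
            f"empty design cells make the full factorial inestimable: {empty}"
        )


def factorial_anova(
    data: pd.DataFrame,
    response: str = "count",
    factors: list[str] | tuple[str, ...] = ("rearing", "wheel", "layer"),
) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA with all interactions.

    Unbalanced cells are handled by Type III sums of squares under
    sum-to-zero contrasts. Returns a table indexed by term (main effects,
    interactions joined by ``:``, and ``Residual``) with columns
    ``df``, ``sum_sq``, ``mean_sq``, ``F`` and ``p``.
    """
    factors = list(factors)
    if len(data) == 0:
        raise ValueError("no observations")
    for f in factors:
        if f not in data.columns:
            raise ValueError(f"factor column {f!r} missing")
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    if response not in data.columns:
        raise ValueError(f"response column {response!r} missing")
    _check_cells(data, factors)

    df = data[factors + [response]].copy()
    df.columns = [f"f{i}" for i in range(len(factors))] + ["y"]
    terms = [f"C(f{i}, Sum)" for i in range(len(factors))]
    fit = smf.ols("y ~ " + " * ".join(terms), data=df).fit()
    tab = anova_lm(fit, typ=3)

    def clean(name: str) -> str:
        parts = name.split(":")
        out = []
        for part in parts:
            idx = int(part[part.index("(f") + 2 : part.index(",")])
            out.append(factors[idx])
        return ":".join(out)

    tab = tab.drop(index="Intercept")
    tab.index = [clean(t) if t != "Residual" else "Residual" for t in tab.index]
    tab = tab.rename(columns={"PR(>F)": "p"})
    tab["df"] = tab["df"].astype(int)
    tab["mean_sq"] = tab["sum_sq"] / tab["df"]
    return tab[["df", "sum_sq", "mean_sq", "F", "p"]]


def studentized_range_p(q: float, k: int, df: float) -> float:
    """Upper-tail probability of the studentized range statistic.

    ``k`` is the number of group means spanned by the range and ``df`` the
    error degrees of freedom. Evaluated by scipy's numerical integration of
    the studentized-range distribution (absolute tolerance ~1e-6 over the
    ranges used here); monotone decreasing in ``q`` with p -> 1 as q -> 0.
    """
    if not np.isfinite(q) or q < 0:
        raise ValueError("q must be a finite value >= 0")
    if k < 2:
        raise ValueError("k must be >= 2")
    if df < 1:
        raise ValueError("df must be >= 1")
    if q == 0:
        return 1.0
    p = float(sps.studentized_range.sf(q, k, df))
    return min(max(p, 0.0), 1.0)


def unequal_n_hsd(
    means: dict | pd.Series,
    ns: dict | pd.Series,
    ms_error: float,
    df_error: float,
    method: str = "tukey-kramer",
) -> pd.DataFrame:
    """All pairwise HSD comparisons between cells of unequal size.

    For cells i, j with means m and sizes n, the Tukey-Kramer statistic is

        q = |m_i - m_j| / sqrt( (MS_error / 2) (1/n_i + 1/n_j) )

    referred to the studentized range distribution with (k, df_error),
    where k is the total number of cells. With equal n this is exactly the
    classical Tukey HSD. ``method="spjotvoll-stoline"`` substitutes
    ``1/min(n_i, n_j)`` for the average, giving a conservative variant.
    Returns one row per unordered pair with ``mean_diff`` (group2 - group1),
    ``q`` and ``p_adj``.
    """
    means = pd.Series(means, dtype=float)
    ns = pd.Series(ns)
    if not means.index.equals(ns.index):
        ns = ns.reindex(means.index)
    if ns.isna().any() or (ns < 1).any():
        raise ValueError("every cell needs n >= 1")
    if not (ms_error > 0):
        raise ValueError("ms_error must be > 0")
    if df_error <= 0:
        raise ValueError("df_error must be > 0")
    if method not in ("tukey-kramer", "spjotvoll-stoline"):
        raise ValueError(f"unknown method {method!r}")
    k = len(means)
    if k < 2:
        raise ValueError("need at least 2 cells to compare")
    rows = []
    for g1, g2 in itertools.combinations(means.index, 2):
        diff = means[g2] - means[g1]
        if method == "tukey-kramer":
            se = np.sqrt(ms_error / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
        else:
            se = np.sqrt(ms_error / min(ns[g1], ns[g2]))
        q = abs(diff) / se
        rows.append((g1, g2, diff, q, studentized_range_p(q, k, df_error)))
    return pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "q", "p_adj"])


@dataclass(frozen=True)
class RegionAnalysis:
    """ANOVA table plus cell-level post hoc for one region."""

    region: str
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    cell_means: pd.Series
    cell_ns: pd.Series


def _lamina(df: pd.DataFrame) -> pd.Series:
    """Layer factor including the DG blade (e.g. 'iML/spb', 'Sr')."""
    if "blade" not in df.columns:
        return df["layer"].copy()
    has_blade = df["blade"].notna() & (df["blade"] != "") & (df["blade"] != "-")
    lamina = df["layer"].copy()
    lamina[has_blade] = df.loc[has_blade, "layer"] + "/" + df.loc[has_blade, "blade"]
    return lamina


def region_analysis(
    animal_means: pd.DataFrame,
    region: str,
    method: str = "tukey-kramer",
) -> RegionAnalysis:
    """Full factorial ANOVA and all-pairs post hoc for one region.

    ``animal_means`` is the animal-level aggregate (one row per animal x
    layer). Cells for the post hoc are (lamina, rearing, wheel); the error
    term is MS_error / df_error of the region's factorial model.
    """
    df = animal_means[animal_means["region"] == region].copy()
    if len(df) == 0:
        raise ValueError(f"no data for region {region!r}")
    df["lamina"] = _lamina(df)
    anova = factorial_anova(
        df, response="mean_count", factors=["rearing", "wheel", "lamina"]
    )
    cells = df.groupby(["lamina", "rearing", "wheel"], sort=False)["mean_count"].agg(
        ["mean", "size"]
    )
    posthoc = unequal_n_hsd(
        cells["mean"],
        cells["size"],
        ms_error=float(anova.loc["Residual", "mean_sq"]),
        df_error=float(anova.loc["Residual", "df"]),
        method=method,
    )
    return RegionAnalysis(
        region=region,
        anova=anova,
        posthoc=posthoc,
        cell_means=cells["mean"],
        cell_ns=cells["size"],
    )
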