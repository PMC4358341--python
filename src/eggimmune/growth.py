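"""Bacterial growth inside infected eggs from CFU plate counts.

Plate colony counts are inverted to per-egg colony-forming units through
the plating arithmetic (dilution, plated fraction, eggs per pool), the
specific exponential growth rate ``k`` is estimated from the mean CFU at
two time points via ``N(t) = N0 * exp(k t)``, and genotypes are compared
with a Pearson chi-square test on the 2x2 table of pooled per-egg CFU
totals at the two time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_PLATE_COLUMNS = (
    "genotype", "treatment", "time_h", "colonies", "dilution_factor",
    "plated_fraction", "eggs_per_pool",
)


def cfu_per_egg(
    colonies: float, dilution_factor: float = 1.0,
    plated_fraction: float = 0.25, eggs_per_pool: int = 10,
) -> float:
    """Per-egg CFU from one plate: colonies * dilution / fraction / eggs."""
    if eggs_per_pool <= 0:
        raise ValueError("eggs_per_pool must be positive")
    if not 0 < plated_fraction <= 1:
        raise ValueError("plated_fraction must lie in (0, 1]")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if colonies < 0:
        raise ValueError("colonies must be non-negative")
    return colonies * dilution_factor / plated_fraction / eggs_per_pool


def add_cfu_per_egg(plates: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`cfu_per_egg` over a plate-count table."""
    missing = set(REQUIRED_PLATE_COLUMNS) - set(plates.columns)
    if missing:
        raise ValueError(f"plate table lacks columns: {sorted(missing)}")
    out = plates.copy()
    out["cfu_per_egg"] = (
        out["colonies"] * out["dilution_factor"]
        / out["plated_fraction"] / out["eggs_per_pool"]
    )
    return out


def summarize_cfu(plates: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of per-egg CFU per (genotype, treatment, time)."""
    df = add_cfu_per_egg(plates)
    g = df.groupby(["genotype", "treatment", "time_h"])["cfu_per_egg"]
    out = g.agg(mean_cfu_per_egg="mean", sd="std", n_plates="count")
    out["se"] = out["sd"] / np.sqrt(out["n_plates"])
    return out.drop(columns="sd").reset_index()


@dataclass(frozen=True)
class GrowthEstimate:
    """Exponential growth summary between two time points."""

    n0_per_egg: float
    nt_per_egg: float
    t: float
    k: float


def estimate_growth_rate(n0: float, nt: float, t: float) -> float:
    """Specific growth rate k = ln(nt/n0)/t per hour."""
    if n0 <= 0 or nt <= 0 or t <= 0:
        raise ValueError("n0, nt and t must all be positive")
    return float(np.log(nt / n0) / t)


def growth_estimates(
    plates: pd.DataFrame, t0: float = 0.0, t1: float = 6.0,
    min_n0: float = 1.0,
) -> pd.DataFrame:
    """Per-genotype growth-rate table from a plate-count table.

    Groups with mean t0 CFU below ``min_n0`` per egg (e.g. sterile injury,
    which introduces essentially no bacteria) get means only, no rate.
    """
    summ = summarize_cfu(plates).set_index(["genotype", "treatment", "time_h"])
    rows = []
    for (genotype, treatment) in sorted(
        {(g, tr) for g, tr, _ in summ.index}
    ):
        try:
            m0 = summ.loc[(genotype, treatment, t0)]
            m1 = summ.loc[(genotype, treatment, t1)]
        except KeyError:
            continue
        n0, n1 = m0["mean_cfu_per_egg"], m1["mean_cfu_per_egg"]
        k = (estimate_growth_rate(n0, n1, t1 - t0)
             if n0 >= min_n0 and n1 > 0 else np.nan)
        rows.append({
            "genotype": genotype, "treatment": treatment,
            "n0_per_egg": n0, "se_n0": m0["se"],
            "nt_per_egg": n1, "se_nt": m1["se"], "t": t1 - t0, "k": k,
        })
    return pd.DataFrame(rows)


def compare_growth(
    group_a: pd.DataFrame, group_b: pd.DataFrame,
    t0: float = 0.0, t1: float = 6.0,
) -> dict:
    """Pearson chi-square comparison of bacterial expansion in two groups.

    Builds a 2x2 table of pooled per-egg CFU totals (rounded to integers)
    at ``t0`` and ``t1`` for the two groups and computes the uncorrected
    Pearson statistic sum((O-E)^2/E) with one degree of freedom. Per-egg
    CFU, not raw colonies, enters the table because the plating protocol
    dilutes the two groups differently at t1. A warning string is attached
    when any expected cell falls below 1.
    """
    def _totals(df: pd.DataFrame) -> list[float]:
        d = add_cfu_per_egg(df)
        out = []
        for t in (t0, t1):
            sel = d[d["time_h"] == t]
            if sel.empty:
                raise ValueError(f"no records at t={t}")
            out.append(float(sel["cfu_per_egg"].sum()))
        return out

    table = np.round(np.array([_totals(group_a), _totals(group_b)])).astype(int)
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    if (table == table[0]).all():
        stat, p = 0.0, 1.0
        expected = table.astype(float)
    else:
        stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    warning = ("expected cell below 1; chi-square approximation unreliable"
               if (expected < 1).any() else "")
    return {"statistic": float(stat), "p_value": float(p),
            "table": table, "warning": warning}
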