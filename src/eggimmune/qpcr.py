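"""Livak (2^-ddCt) relative quantification for qPCR Ct tables.

Technical replicates are averaged on the Ct scale, each biological
replicate yields dCt = Ct_target - Ct_reference, and expression of a group
relative to a calibrator group (naive eggs by default) is
2^-(mean dCt_group - mean dCt_calibrator). Amplification efficiency is
assumed to be 2.0 per cycle (pure Livak). The standard error is taken over
per-biological-replicate fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_CT_COLUMNS = (
    "gene_id", "sample_group", "biological_rep", "technical_rep", "ct",
)

CT_WINDOW = (0.0, 50.0)


class CtTableError(ValueError):
    """Raised for malformed Ct tables or missing reference measurements."""


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check columns and flag Ct values outside the plausible cycle window."""
    missing = set(REQUIRED_CT_COLUMNS) - set(table.columns)
    if missing:
        raise CtTableError(f"Ct table lacks columns: {sorted(missing)}")
    out = table.copy()
    out["ct_flagged"] = ~out["ct"].between(*CT_WINDOW)
    return out


def _delta_ct(
    table: pd.DataFrame, target: str, reference: str, group: str
) -> pd.Series:
    """Per-biological-replicate dCt for one gene in one group."""
    sub = table[table["sample_group"] == group]
    tgt = (sub[sub["gene_id"] == target]
           .groupby("biological_rep")["ct"].mean())
    ref = (sub[sub["gene_id"] == reference]
           .groupby("biological_rep")["ct"].mean())
    if tgt.empty:
        raise CtTableError(f"no Ct values for {target!r} in group {group!r}")
    missing = sorted(set(tgt.index) - set(ref.index))
    if missing:
        raise CtTableError(
            f"reference {reference!r} missing in group {group!r}, "
            f"biological replicate(s) {missing}"
        )
    return tgt - ref.loc[tgt.index]


@dataclass(frozen=True)
class RelativeExpression:
    """Fold change of one gene in one group relative to the calibrator."""

    gene_id: str
    group: str
    fold_change: float
    se: float
    n_biological: int


def livak_fold_change(
    table: pd.DataFrame, target: str, group: str,
    reference: str = "RPL13a", calibrator_group: str = "naive",
) -> RelativeExpression:
    """2^-ddCt fold change of ``target`` in ``group`` versus the calibrator.

    The point estimate uses mean dCt per group (so the calibrator group is
    exactly 1); the SE is over per-biological-replicate fold changes.
    """
    table = validate_ct_table(table)
    dct_g = _delta_ct(table, target, reference, group)
    dct_c = _delta_ct(table, target, reference, calibrator_group)
    ddct = dct_g.mean() - dct_c.mean()
    fold = float(2.0 ** (-ddct))
    per_rep = 2.0 ** (-(dct_g - dct_c.mean()))
    se = float(per_rep.std(ddof=1) / np.sqrt(len(per_rep))) if len(per_rep) > 1 else np.nan
    return RelativeExpression(
        gene_id=target, group=group, fold_change=fold, se=se,
        n_biological=len(dct_g),
    )


def livak_table(
    table: pd.DataFrame, reference: str = "RPL13a",
    calibrator_group: str = "naive",
) -> pd.DataFrame:
    """Fold-change table for every (target gene, non-calibrator group)."""
    table = validate_ct_table(table)
    genes = [g for g in table["gene_id"].unique() if g != reference]
    groups = [g for g in table["sample_group"].unique()]
    rows = []
    for gene in genes:
        for group in groups:
            r = livak_fold_change(
                table, gene, group, reference=reference,
                calibrator_group=calibrator_group,
            )
            rows.append({
                "gene_id": r.gene_id, "group": r.group,
                "fold_change": r.fold_change, "se": r.se,
                "n_biological": r.n_biological,
            })
    return pd.DataFrame(rows)
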