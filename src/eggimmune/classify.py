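"""Serosa-dependence classification of infection-responsive genes.

Combines per-genotype differential-expression results into the headline
set partitions of the egg-immunity analysis: the three-way Venn
decomposition of septic-injury DE genes across wild-type, control-RNAi and
zen1-RNAi (serosa-less) eggs, a per-gene serosa-dependence label, and
cross-tabulations of annotated immune genes by genotype, injury type,
direction and functional class.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

LABELS = (
    "serosa_dependent",
    "serosa_independent",
    "wound_response",
    "constitutive_serosal",
    "unresponsive",
)

IMMUNE_CLASSES = (
    "microbial_recognition",
    "extracellular_transduction",
    "intracellular_pathways",
    "execution_stress",
)


def venn_partition(sets: dict[str, set[str]]) -> dict[tuple[str, ...], set[str]]:
    """Disjoint Venn cells of three labeled gene sets.

    Returns a dict keyed by the sorted tuple of set labels the cell's genes
    belong to (7 cells); every gene in any input set lands in exactly one
    cell.
    """
    labels = list(sets)
    if len(labels) != 3 or len(set(labels)) != 3:
        raise ValueError("exactly three distinct labeled sets required")
    cells: dict[tuple[str, ...], set[str]] = {}
    for r in (1, 2, 3):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(
                set(), *(sets[c] for c in labels if c not in combo)
            )
            cells[tuple(sorted(combo))] = inside - outside
    return cells


def venn_counts(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Cell-count table of :func:`venn_partition` plus the union size."""
    cells = venn_partition(sets)
    rows = [{"cell": "+".join(k), "n_genes": len(v)} for k, v in cells.items()]
    rows.append({"cell": "union", "n_genes": len(set.union(*sets.values()))})
    return pd.DataFrame(rows)


def classify_serosa_dependence(
    septic_de: dict[str, set[str]],
    sterile_de: dict[str, set[str]],
    constitutive_de: set[str],
    universe: list[str],
    serosa_genotypes: tuple[str, str] = ("wildtype", "control_rnai"),
    serosaless_genotype: str = "zen1_rnai",
) -> pd.DataFrame:
    """Label every gene by its serosa dependence.

    Inputs are the five DE gene sets: septic-vs-naive per genotype,
    sterile-vs-naive for the serosa-less genotype (plus any others,
    ignored for labelling), and the naive serosa-bearing vs naive
    serosa-less contrast (``constitutive_de``).

    Label priority per gene:

    1. ``wound_response`` — DE after sterile injury in serosa-less eggs;
       such genes respond to wounding, not to infection.
    2. ``serosa_independent`` — septic DE in serosa-less eggs (and not
       wound-explained).
    3. ``serosa_dependent`` — septic DE in a serosa-bearing genotype only.
    4. ``constitutive_serosal`` — DE between naive eggs with and without a
       serosa, with no injury response.
    5. ``unresponsive`` — everything else.
    """
    required = set(serosa_genotypes) | {serosaless_genotype}
    if set(septic_de) != required:
        raise ValueError(f"septic_de must cover genotypes {sorted(required)}")
    if serosaless_genotype not in sterile_de:
        raise ValueError("sterile_de must include the serosa-less genotype")
    serosa_union = set.union(*(septic_de[g] for g in serosa_genotypes))
    zen_septic = septic_de[serosaless_genotype]
    zen_sterile = sterile_de[serosaless_genotype]

    labels = []
    for gid in universe:
        if gid in zen_sterile:
            label = "wound_response"
        elif gid in zen_septic:
            label = "serosa_independent"
        elif gid in serosa_union:
            label = "serosa_dependent"
        elif gid in constitutive_de:
            label = "constitutive_serosal"
        else:
            label = "unresponsive"
        labels.append(label)
    return pd.DataFrame({"gene_id": universe, "label": labels}).set_index("gene_id")


def tabulate_immune_genes(
    de_tables: dict[tuple[str, str], pd.DataFrame],
    immune_annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Immune-gene counts by genotype, injury type, direction and class.

    ``de_tables`` maps (genotype, injury) -> a selected DE table with a
    ``direction`` column ('induced'/'repressed'); ``immune_annotation`` is
    a two-column frame (``gene_id``, ``immune_class``). Genes with an
    unknown class are bucketed as 'unclassified'.
    """
    ann = immune_annotation.set_index("gene_id")["immune_class"]
    bad = sorted(set(ann.unique()) - set(IMMUNE_CLASSES))
    rows = []
    for (genotype, injury), table in de_tables.items():
        sig = (table.loc[table["significant"].astype(bool)]
               if "significant" in table.columns else table)
        for gid, direction in sig["direction"].items():
            if gid not in ann.index:
                continue
            cls = ann[gid]
            if cls not in IMMUNE_CLASSES:
                cls = "unclassified"
            rows.append({
                "genotype": genotype, "injury": injury,
                "direction": direction, "immune_class": cls,
            })
    if not rows:
        idx = pd.MultiIndex.from_product(
            [[], []], names=["immune_class", "direction"]
        )
        return pd.DataFrame(index=idx)
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["genotype", "injury", "direction", "immune_class"])
        .size().rename("n_genes").reset_index()
    )
    if bad:
        out.attrs["warning"] = f"unknown immune classes bucketed: {bad}"
    return out


def immune_table_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Per (genotype, injury, direction) totals of the immune-gene table."""
    if table.empty:
        return table
    return (
        table.groupby(["genotype", "injury", "direction"])["n_genes"]
        .sum().reset_index()
    )
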