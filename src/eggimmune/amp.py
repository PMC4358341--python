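"""Physicochemical screening for candidate antimicrobial peptides (AMPs).

AMPs are short, typically cationic and hydrophobic effector peptides, often
glycine- or proline-rich. The screen combines sequence properties (length,
molecular weight, net charge, hydrophobic ratio, glycine/proline content)
with infection-induced fold change from the differential-expression step:
a candidate is a peptide shorter than 200 residues, not net-negative (or
rescued by high glycine content), induced at least twofold upon septic
injury in either serosa-bearing genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight

#: residues counted as hydrophobic (common AMP-database convention)
HYDROPHOBIC_SET = frozenset("AVILMFWC")
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    """Raised for sequences containing non-canonical residues."""


@dataclass(frozen=True)
class PeptideProperties:
    """Physicochemical profile of one peptide.

    ``molecular_weight`` is in kDa (average masses, one water included);
    ``net_charge`` counts (K + R) - (D + E) at neutral pH with histidine
    and termini ignored; ratios are percentages of the residue count, the
    hydrophobic ratio rounded to integer percent.
    """

    length: int
    molecular_weight: float
    hydrophobic_ratio: int
    net_charge: int
    glycine_content: float
    proline_content: float


def compute_properties(
    sequence: str, hydrophobic_set: frozenset[str] = HYDROPHOBIC_SET
) -> PeptideProperties:
    """Compute the physicochemical profile of a peptide sequence."""
    seq = sequence.strip().upper()
    if not seq:
        raise SequenceError("empty sequence")
    for i, ch in enumerate(seq):
        if ch not in VALID_RESIDUES:
            raise SequenceError(f"invalid residue {ch!r} at position {i + 1}")
    n = len(seq)
    mw_da = molecular_weight(seq, seq_type="protein")  # average masses + water
    hydro = sum(seq.count(c) for c in hydrophobic_set)
    charge = (seq.count("K") + seq.count("R")) - (seq.count("D") + seq.count("E"))
    return PeptideProperties(
        length=n,
        molecular_weight=mw_da / 1000.0,
        hydrophobic_ratio=int(round(100.0 * hydro / n)),
        net_charge=charge,
        glycine_content=100.0 * seq.count("G") / n,
        proline_content=100.0 * seq.count("P") / n,
    )


def properties_table(records: list[tuple[str, str]]) -> pd.DataFrame:
    """Property table (one row per peptide) from (gene_id, sequence) pairs."""
    rows = []
    for gid, seq in records:
        p = compute_properties(seq)
        rows.append({
            "gene_id": gid, "length_aa": p.length, "mw_kda": p.molecular_weight,
            "hydrophobic_pct": p.hydrophobic_ratio, "net_charge": p.net_charge,
            "glycine_pct": p.glycine_content, "proline_pct": p.proline_content,
        })
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass(frozen=True)
class AmpThresholds:
    """Candidate filter cut-offs.

    ``max_length`` is a strict bound (length < 200); ``min_fold`` the
    induction required in at least one serosa-bearing genotype;
    ``min_charge`` the lowest acceptable net charge on the standard route;
    net-negative peptides pass only when glycine content reaches
    ``glycine_exception_pct``.
    """

    max_length: int = 200
    min_fold: float = 2.0
    min_charge: int = 0
    glycine_exception_pct: float = 25.0


def _fold_ok(value, min_fold: float) -> bool:
    """Missing ('no hit') folds never satisfy the rule; Inf always does."""
    if value is None:
        return False
    v = float(value)
    if np.isnan(v):
        return False
    return v >= min_fold or np.isinf(v)


def screen_candidates(
    properties: pd.DataFrame,
    fold_wildtype: pd.Series | dict,
    fold_control: pd.Series | dict,
    known_amps: set[str] | None = None,
    thresholds: AmpThresholds = AmpThresholds(),
) -> pd.DataFrame:
    """Score every peptide against the candidate-AMP filter.

    ``properties`` is indexed by gene_id with columns ``length_aa``,
    ``net_charge`` and ``glycine_pct`` (as from :func:`properties_table`).
    Fold changes are septic-vs-naive values per genotype; ``NaN`` means the
    gene was not detected in that genotype ('no hit') and passes in neither
    direction, while ``inf`` (expression from a zero baseline) passes.

    Known AMPs are carried through as reference rows (``is_known``) but do
    not count as new candidates. Rows are sorted by the maximum fold change
    across the two genotypes, descending.
    """
    known_amps = known_amps or set()
    fw = pd.Series(fold_wildtype, dtype=float).reindex(properties.index)
    fc = pd.Series(fold_control, dtype=float).reindex(properties.index)

    out = properties.copy()
    out["fold_wildtype"] = fw
    out["fold_control"] = fc
    out["is_known"] = out.index.isin(known_amps)

    length_ok = out["length_aa"] < thresholds.max_length
    fold_ok = [
        _fold_ok(a, thresholds.min_fold) or _fold_ok(b, thresholds.min_fold)
        for a, b in zip(fw, fc)
    ]
    charge_ok = out["net_charge"] >= thresholds.min_charge
    gly_ok = out["glycine_pct"] >= thresholds.glycine_exception_pct

    passed = length_ok & pd.Series(fold_ok, index=out.index) & (charge_ok | gly_ok)
    route = np.where(
        passed & ~charge_ok, "glycine_exception", np.where(passed, "standard", "")
    )
    out["passed"] = passed
    out["pass_route"] = route

    fmax = np.fmax(fw.fillna(-np.inf), fc.fillna(-np.inf))
    out = out.loc[fmax.sort_values(ascending=False, kind="stable").index]
    return out


def n_new_candidates(screened: pd.DataFrame) -> int:
    """Number of peptides passing the filter that are not known AMPs."""
    return int((screened["passed"] & ~screened["is_known"]).sum())


def load_reference_table() -> pd.DataFrame:
    """Published property compilation for Tribolium castaneum AMPs.

    Known AMPs (cecropins, attacins, coleoptericins, defensins) plus the
    candidate peptides reported alongside them, with septic-injury fold
    changes in wild-type and control-RNAi eggs. 'Inf' marks induction from
    an undetectable baseline, 'no hit' a gene not detected in that
    genotype.
    """
    with resources.files("eggimmune.data").joinpath(
        "tribolium_amp_reference.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"gene_id": str})
    for col in ("fold_wildtype", "fold_control"):
        df[col] = df[col].map(
            lambda v: np.nan if str(v).strip() == "no hit" else float(v)
        )
    df["known"] = df["known"] == "yes"
    return df.set_index("gene_id")
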