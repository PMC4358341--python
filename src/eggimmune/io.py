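"""Readers and writers for the pipeline's plain-text formats.

Counts travel as TSV (gene_id + one column per sample), sample sheets and
plate counts as CSV, peptides as 60-column-wrapped FASTA via Biopython,
annotations as two-column TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .de import CountMatrix


def write_counts(cm: CountMatrix, counts_path, samples_path) -> None:
    df = cm.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(counts_path, sep="\t")
    design = cm.design.copy()
    design.index.name = "sample_id"
    design.to_csv(samples_path)


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    design = pd.read_csv(samples_path, index_col="sample_id")
    return CountMatrix(counts=counts, design=design)


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(seq), id=gid, description="") for gid, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "category_id"}
    if not need <= set(df.columns):
        # two-column headerless form
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["gene_id", "category_id"])
    return df


def read_ground_truth(path) -> pd.Series:
    """Planted gene-class labels; the class literal 'null' must survive."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id",
                     keep_default_na=False)
    return df["gene_class"]


def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip().split("\t")[0] for line in fh if line.strip()}


def read_plates(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_ct(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
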