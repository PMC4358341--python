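"""Synthetic-data generation for the egg immune-competence pipeline.

Emulates a 3-genotype x 3-treatment x 3-replicate bulk RNA-seq design
(wild-type, control RNAi and zen1 RNAi eggs; naive, sterile injury and
septic injury) with negative-binomially distributed gene counts, plus the
side datasets the pipeline consumes: peptide FASTA files spanning AMP-like
and non-AMP property profiles, CFU plate-count tables from an exponential
within-egg growth model, qPCR Ct tables and GO-style category annotation.

Every generator draws from a substream of one global seed
(:class:`numpy.random.SeedSequence` spawning), so adding an output type
never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("wildtype", "control_rnai", "zen1_rnai")
TREATMENTS = ("naive", "sterile", "septic")

GENE_CLASSES = (
    "serosa_dependent_inducible",
    "wound_responsive",
    "constitutive_serosal",
    "null",
)

# genotypes that retain a serosa (zen1 RNAi deletes it)
SEROSA_GENOTYPES = ("wildtype", "control_rnai")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# substream indices: one per output type, fixed forever
_STREAMS = {"counts": 0, "peptides": 1, "cfu": 2, "ct": 3, "annotation": 4}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic count-matrix generator.

    Defaults are the study conditions the generators emulate: 2000 genes in
    a 3x3x3 design, 10% serosa-dependent inducible genes, 5% genes that
    respond to any wounding, 5% genes constitutively expressed only when a
    serosa is present, and 80% null genes. Induced effects are drawn
    uniformly in log2 from ``induction_log2fc_range``; the wide default
    reflects the hundreds-fold AMP inductions typical of infected insect
    eggs. ``nb_dispersion`` is the NB overdispersion alpha in
    ``var = mu + alpha * mu**2``.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    genotypes: tuple[str, ...] = GENOTYPES
    treatments: tuple[str, ...] = TREATMENTS
    gene_class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "serosa_dependent_inducible": 0.10,
            "wound_responsive": 0.05,
            "constitutive_serosal": 0.05,
            "null": 0.80,
        }
    )
    induction_log2fc_range: tuple[float, float] = (3.0, 8.0)
    nb_dispersion: float = 0.05
    mean_expression_log10_range: tuple[float, float] = (0.5, 3.0)
    sterile_induces_serosa_genes: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise ConfigurationError("n_genes and n_replicates must be positive")
        if len(self.genotypes) != 3 or len(self.treatments) != 3:
            raise ConfigurationError("design requires 3 genotypes and 3 treatments")
        if set(self.gene_class_fractions) - set(GENE_CLASSES):
            raise ConfigurationError(
                f"unknown gene classes: {set(self.gene_class_fractions) - set(GENE_CLASSES)}"
            )
        total = sum(self.gene_class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"gene_class_fractions sum to {total}, not 1")
        if any(f < 0 for f in self.gene_class_fractions.values()):
            raise ConfigurationError("gene_class_fractions must be non-negative")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        lo, hi = self.induction_log2fc_range
        if hi < lo:
            raise ConfigurationError("induction_log2fc_range must be ordered")


@dataclass
class GroundTruth:
    """Planted truth for one simulation: class labels and true means."""

    gene_class: pd.Series  # gene_id -> class label
    true_means: pd.DataFrame  # genes x samples, NB mean of every cell
    amp_gene_ids: tuple[str, ...] = ()

    def genes_of_class(self, label: str) -> list[str]:
        return list(self.gene_class.index[self.gene_class == label])


def design_table(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet for the full factorial design, one row per sample.

    Sample ids follow ``genotype.treatment.repN``.
    """
    rows = []
    for g in config.genotypes:
        for t in config.treatments:
            for r in range(1, config.n_replicates + 1):
                rows.append({"sample_id": f"{g}.{t}.rep{r}", "genotype": g,
                             "treatment": t, "replicate": r})
    return pd.DataFrame(rows).set_index("sample_id")


def _assign_classes(config: SimulationConfig) -> np.ndarray:
    """Deterministic class vector: contiguous blocks by class order."""
    counts = {}
    remaining = config.n_genes
    for cls in GENE_CLASSES[:-1]:
        n = int(round(config.gene_class_fractions.get(cls, 0.0) * config.n_genes))
        n = min(n, remaining)
        counts[cls] = n
        remaining -= n
    counts["null"] = remaining
    labels = []
    for cls in GENE_CLASSES:
        labels.extend([cls] * counts[cls])
    return np.array(labels)


def simulate_counts(config: SimulationConfig) -> tuple["CountMatrix", GroundTruth]:
    """Draw an NB count matrix with planted serosa-biology structure.

    Gene classes and their condition-mean structure:

    * ``serosa_dependent_inducible`` — baseline everywhere except septic
      (optionally also sterile) treatment in serosa-bearing genotypes,
      where the mean is multiplied by ``2**log2fc``.
    * ``wound_responsive`` — induced by both sterile and septic injury in
      every genotype.
    * ``constitutive_serosal`` — elevated in serosa-bearing genotypes under
      every treatment relative to zen1 RNAi eggs.
    * ``null`` — one mean everywhere.

    Returns the count matrix plus the planted :class:`GroundTruth`.
    """
    from .de import CountMatrix  # local import to avoid a cycle

    config.validate()
    rng = _rng(config.seed, "counts")
    design = design_table(config)
    gene_ids = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    classes = _assign_classes(config)

    lo10, hi10 = config.mean_expression_log10_range
    base = 10.0 ** rng.uniform(lo10, hi10, size=config.n_genes)
    l2lo, l2hi = config.induction_log2fc_range
    effect = 2.0 ** rng.uniform(l2lo, l2hi, size=config.n_genes)

    means = pd.DataFrame(
        np.tile(base[:, None], (1, len(design))), index=gene_ids,
        columns=design.index,
    )
    induce_treats = {"septic"}
    if config.sterile_induces_serosa_genes:
        induce_treats.add("sterile")
    for j, sample in enumerate(design.index):
        g = design.loc[sample, "genotype"]
        t = design.loc[sample, "treatment"]
        fac = np.ones(config.n_genes)
        sel = (classes == "serosa_dependent_inducible") & (g in SEROSA_GENOTYPES) & (
            t in induce_treats
        )
        fac = np.where(sel, effect, fac)
        sel = (classes == "wound_responsive") & (t in ("sterile", "septic"))
        fac = np.where(sel, effect, fac)
        sel = (classes == "constitutive_serosal") & (g in SEROSA_GENOTYPES)
        fac = np.where(sel, effect, fac)
        means.iloc[:, j] = base * fac

    mu = means.to_numpy()
    alpha = config.nb_dispersion
    if alpha == 0:
        counts = rng.poisson(mu)
    else:
        # NB as gamma-Poisson: shape 1/alpha, scale alpha*mu
        lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
        counts = rng.poisson(lam)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=design.index),
        design=design,
    )
    truth = GroundTruth(
        gene_class=pd.Series(classes, index=gene_ids, name="gene_class"),
        true_means=means,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# peptides

_HYDROPHOBIC = "AVILMFWC"
_CATIONIC = "KR"
_ANIONIC = "DE"


def _random_peptide(rng: np.random.Generator, length: int, weights: np.ndarray) -> str:
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=weights)
    return "".join(AMINO_ACIDS[i] for i in idx)


def simulate_peptides(
    n: int, planted_amp_fraction: float, seed: int,
    gene_ids: list[str] | None = None,
) -> tuple[list[tuple[str, str]], pd.Series]:
    """Generate peptide sequences spanning AMP-like and decoy profiles.

    Planted AMP-like sequences satisfy the physicochemical screen by
    construction: length < 200, net charge >= +1 and hydrophobic ratio
    >= 30%. Decoys violate at least one criterion (drawn to be too long,
    net-negative, or hydrophilic). Returns ``(records, labels)`` where
    records are ``(gene_id, sequence)`` pairs and labels is a boolean
    Series marking the planted AMPs.
    """
    if n <= 0:
        raise ConfigurationError("n must be positive")
    if not 0.0 <= planted_amp_fraction <= 1.0:
        raise ConfigurationError("planted_amp_fraction must lie in [0, 1]")
    rng = _rng(seed, "peptides")
    n_amp = int(round(planted_amp_fraction * n))
    if gene_ids is None:
        gene_ids = [f"P{i:05d}" for i in range(n)]
    if len(gene_ids) != n:
        raise ConfigurationError("gene_ids length must equal n")

    aa = np.array(list(AMINO_ACIDS))
    uniform = np.full(len(aa), 1.0 / len(aa))
    # AMP-ish residue bias: hydrophobic + cationic enriched, anionic rare
    amp_w = np.where(np.isin(aa, list(_HYDROPHOBIC)), 3.0, 1.0)
    amp_w = np.where(np.isin(aa, list(_CATIONIC)), 4.0, amp_w)
    amp_w = np.where(np.isin(aa, list(_ANIONIC)), 0.2, amp_w)
    amp_w = amp_w / amp_w.sum()

    records, labels = [], []
    for i in range(n):
        gid = gene_ids[i]
        if i < n_amp:
            while True:
                length = int(rng.integers(30, 190))
                seq = _random_peptide(rng, length, amp_w)
                charge = sum(seq.count(c) for c in _CATIONIC) - sum(
                    seq.count(c) for c in _ANIONIC
                )
                hydro = 100.0 * sum(seq.count(c) for c in _HYDROPHOBIC) / length
                if charge >= 1 and hydro >= 30.0:
                    break
            labels.append(True)
        else:
            mode = rng.integers(3)
            if mode == 0:  # too long
                length = int(rng.integers(210, 400))
                seq = _random_peptide(rng, length, amp_w)
            else:
                while True:
                    length = int(rng.integers(30, 190))
                    seq = _random_peptide(rng, length, uniform)
                    charge = sum(seq.count(c) for c in _CATIONIC) - sum(
                        seq.count(c) for c in _ANIONIC
                    )
                    if mode == 1 and charge <= -1:
                        break
                    if mode == 2:
                        hydro = 100.0 * sum(seq.count(c) for c in _HYDROPHOBIC) / length
                        gly = 100.0 * seq.count("G") / length
                        if hydro < 30.0 and charge <= -1 and gly < 25.0:
                            break
            labels.append(False)
        records.append((gid, seq))
    return records, pd.Series(labels, index=gene_ids, name="is_amp")


# ---------------------------------------------------------------------------
# CFU plate counts

#: the plating protocol: 10 eggs pooled per plate, a quarter of the
#: homogenate plated; t=6 suspensions diluted (50x serosa-bearing,
#: 500x serosa-less in the emulated protocol)
EGGS_PER_POOL = 10
PLATED_FRACTION = 0.25


def simulate_cfu(
    k_per_genotype: dict[str, float],
    n0_mean: float,
    plates: int,
    seed: int,
    times: tuple[float, ...] = (0.0, 6.0),
    dilution_at_t: dict[float, dict[str, float]] | None = None,
    treatment: str = "septic",
) -> pd.DataFrame:
    """Simulate plate colony counts under exponential within-egg growth.

    Each egg starts with ``Poisson(n0_mean)`` bacteria which grow to
    ``N0 * exp(k t)`` by sampling time; 10 eggs are pooled per plate and
    colonies arise by binomial thinning with probability
    ``plated_fraction / dilution_factor``.
    """
    if n0_mean < 0:
        raise ConfigurationError("n0_mean must be non-negative")
    if plates < 1:
        raise ConfigurationError("plates must be >= 1")
    if any(k < 0 for k in k_per_genotype.values()):
        raise ConfigurationError("growth rates must be >= 0")
    rng = _rng(seed, "cfu")
    if dilution_at_t is None:
        dilution_at_t = {
            0.0: {g: 1.0 for g in k_per_genotype},
            6.0: {g: (500.0 if g == "zen1_rnai" else 50.0) for g in k_per_genotype},
        }
    rows = []
    for genotype, k in k_per_genotype.items():
        for t in times:
            dilution = dilution_at_t.get(t, {}).get(genotype, 1.0)
            for _ in range(plates):
                n0 = rng.poisson(n0_mean, size=EGGS_PER_POOL)
                nt = rng.poisson(n0 * np.exp(k * t))
                total = int(nt.sum())
                p_obs = PLATED_FRACTION / dilution
                colonies = int(rng.binomial(total, p_obs)) if total > 0 else 0
                rows.append({
                    "genotype": genotype, "treatment": treatment, "time_h": t,
                    "colonies": colonies, "dilution_factor": dilution,
                    "plated_fraction": PLATED_FRACTION,
                    "eggs_per_pool": EGGS_PER_POOL,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR Ct tables

def simulate_ct(
    fold_changes: dict[str, dict[str, float]],
    seed: int,
    reference_gene: str = "RPL13a",
    n_biological: int = 2,
    n_technical: int = 2,
    ct_naive: float = 26.0,
    ct_reference: float = 16.0,
    noise_sd: float = 0.15,
) -> pd.DataFrame:
    """Generate a Ct table realising given per-group fold changes.

    ``fold_changes`` maps target gene -> {group: fold vs naive}. The naive
    group is implicit at fold 1. Target Cts shift by ``-log2(fold)``;
    the reference gene keeps one Ct everywhere up to technical noise.
    """
    rng = _rng(seed, "ct")
    rows = []
    groups = ["naive"] + sorted(
        {g for folds in fold_changes.values() for g in folds} - {"naive"}
    )
    for b in range(1, n_biological + 1):
        bio_shift = rng.normal(0, noise_sd)
        for group in groups:
            for gene, folds in fold_changes.items():
                fold = 1.0 if group == "naive" else folds.get(group, 1.0)
                true_ct = ct_naive - np.log2(fold) + bio_shift
                for tech in range(1, n_technical + 1):
                    rows.append({
                        "gene_id": gene, "sample_group": group,
                        "biological_rep": b, "technical_rep": tech,
                        "ct": true_ct + rng.normal(0, noise_sd),
                    })
            for tech in range(1, n_technical + 1):
                rows.append({
                    "gene_id": reference_gene, "sample_group": group,
                    "biological_rep": b, "technical_rep": tech,
                    "ct": ct_reference + bio_shift + rng.normal(0, noise_sd),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GO-style annotation

def simulate_annotation(
    truth: GroundTruth,
    seed: int,
    n_categories: int = 30,
    mean_categories_per_gene: float = 2.0,
    defense_category: str = "GO:0006952",
    defense_hit_rate: float = 0.8,
) -> pd.DataFrame:
    """Two-column gene -> category annotation with a planted defense term.

    Serosa-dependent inducible genes receive ``defense_category``
    ("defense response") with probability ``defense_hit_rate``; background
    genes receive it at the base rate, so enrichment of that category among
    recovered DE genes is the planted expectation.
    """
    rng = _rng(seed, "annotation")
    cats = [defense_category] + [f"GO:{7000000 + i}" for i in range(1, n_categories)]
    rows = []
    genes = list(truth.gene_class.index)
    p_any = min(1.0, mean_categories_per_gene / n_categories)
    for gid in genes:
        mask = rng.random(n_categories) < p_any
        for ci in np.nonzero(mask)[0]:
            rows.append({"gene_id": gid, "category_id": cats[ci]})
        if truth.gene_class[gid] == "serosa_dependent_inducible" and not mask[0]:
            if rng.random() < defense_hit_rate:
                rows.append({"gene_id": gid, "category_id": defense_category})
    return pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)


def simulate_immune_annotation(truth: GroundTruth, seed: int) -> pd.DataFrame:
    """Assign immune functional classes to the planted responsive genes.

    Emulates a curated immune-gene list: every non-null gene is tagged with
    one of the four canonical immune functional classes.
    """
    from .classify import IMMUNE_CLASSES

    rng = _rng(seed, "annotation")
    rows = []
    for gid, cls in truth.gene_class.items():
        if cls == "null":
            continue
        rows.append({
            "gene_id": gid,
            "immune_class": IMMUNE_CLASSES[int(rng.integers(len(IMMUNE_CLASSES)))],
        })
    return pd.DataFrame(rows)
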