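"""End-to-end orchestration: simulate -> DE -> enrich -> AMP screen -> classify.

``run_all`` generates one synthetic study (counts, peptides, plate counts,
Ct table, annotations), runs every analysis stage and writes all result
tables to an output directory. Table schemas are fixed in
``OUTPUT_SCHEMAS`` so downstream consumers can validate headers.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from . import amp, classify, de, enrichment, growth, io, qpcr, simulate

log = logging.getLogger("eggimmune")

#: first columns every output table must expose (index column included)
OUTPUT_SCHEMAS = {
    "counts.tsv": ["gene_id"],
    "samples.csv": ["sample_id", "genotype", "treatment", "replicate"],
    "ground_truth.tsv": ["gene_id", "gene_class"],
    "go_annotation.tsv": ["gene_id", "category_id"],
    "immune_annotation.tsv": ["gene_id", "immune_class"],
    "plates.csv": list(growth.REQUIRED_PLATE_COLUMNS),
    "ct.csv": list(qpcr.REQUIRED_CT_COLUMNS),
    "de_wildtype_septic.tsv": [
        "gene_id", "base_mean_a", "base_mean_b", "fold_change",
        "log2_fold_change", "pval", "padj", "significant", "direction",
    ],
    "enrichment.tsv": [
        "category_id", "n_universe", "n_category", "n_de",
        "n_de_in_category", "weight_ratio", "p_over", "significant", "p_adj",
    ],
    "amp_screen.tsv": [
        "gene_id", "length_aa", "mw_kda", "hydrophobic_pct", "net_charge",
        "glycine_pct", "proline_pct", "fold_wildtype", "fold_control",
        "is_known", "passed", "pass_route",
    ],
    "labels.tsv": ["gene_id", "label"],
    "venn_counts.tsv": ["cell", "n_genes"],
    "immune_table.tsv": ["genotype", "injury", "direction", "immune_class",
                          "n_genes"],
    "constitutive_table.tsv": [
        "gene_id", "base_mean_a", "base_mean_b", "fold_change",
        "log2_fold_change", "pval", "padj", "significant", "direction",
    ],
    "growth_estimates.tsv": [
        "genotype", "treatment", "n0_per_egg", "se_n0", "nt_per_egg",
        "se_nt", "t", "k",
    ],
    "growth_test.tsv": ["statistic", "p_value", "warning"],
    "qpcr_folds.tsv": ["gene_id", "group", "fold_change", "se",
                        "n_biological"],
}

DE_CONTRASTS = [
    # (file stem, genotype, treatment A, treatment B)
    ("de_wildtype_sterile", "wildtype", "naive", "sterile"),
    ("de_wildtype_septic", "wildtype", "naive", "septic"),
    ("de_control_rnai_sterile", "control_rnai", "naive", "sterile"),
    ("de_control_rnai_septic", "control_rnai", "naive", "septic"),
    ("de_zen1_rnai_sterile", "zen1_rnai", "naive", "sterile"),
    ("de_zen1_rnai_septic", "zen1_rnai", "naive", "septic"),
]


def load_config(path) -> simulate.SimulationConfig:
    """Simulation config from a YAML file (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(simulate.SimulationConfig.__dataclass_fields__)
    bad = set(raw) - known
    if bad:
        raise simulate.ConfigurationError(f"unknown config keys: {sorted(bad)}")
    for key in ("genotypes", "treatments", "induction_log2fc_range",
                "mean_expression_log10_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return simulate.SimulationConfig(**raw)


def simulate_all(config: simulate.SimulationConfig, outdir) -> dict:
    """Generate every pipeline input and write it under ``outdir``."""
    out = io.ensure_dir(outdir)
    cm, truth = simulate.simulate_counts(config)
    io.write_counts(cm, out / "counts.tsv", out / "samples.csv")

    gt = truth.gene_class.to_frame()
    gt.index.name = "gene_id"
    io.write_tsv(gt, out / "ground_truth.tsv")

    inducible = truth.genes_of_class("serosa_dependent_inducible")
    n_decoys = max(10, len(inducible) // 2)
    decoy_ids = [f"D{i:05d}" for i in range(n_decoys)]
    n_pep = len(inducible) + n_decoys
    frac = len(inducible) / n_pep if n_pep else 0.0
    records, amp_labels = simulate.simulate_peptides(
        n_pep, frac, config.seed, gene_ids=inducible + decoy_ids
    )
    truth.amp_gene_ids = tuple(amp_labels.index[amp_labels])
    io.write_fasta(records, out / "peptides.fasta")

    ann = simulate.simulate_annotation(truth, config.seed)
    ann.to_csv(out / "go_annotation.tsv", sep="\t", index=False)
    imm = simulate.simulate_immune_annotation(truth, config.seed)
    imm.to_csv(out / "immune_annotation.tsv", sep="\t", index=False)

    plates = simulate.simulate_cfu(
        {"wildtype": 0.44, "zen1_rnai": 0.83}, n0_mean=50.0, plates=10,
        seed=config.seed,
    )
    plates.to_csv(out / "plates.csv", index=False)

    ct = simulate.simulate_ct(
        {g: {"septic": 150.0, "sterile": 3.0} for g in inducible[:3]},
        seed=config.seed,
    )
    ct.to_csv(out / "ct.csv", index=False)
    return {"counts": cm, "truth": truth, "records": records,
            "annotation": ann, "immune": imm, "plates": plates, "ct": ct}


def run_all(config: simulate.SimulationConfig, outdir) -> dict[str, Path]:
    """Run the full pipeline on one synthetic study; returns output paths."""
    out = io.ensure_dir(outdir)
    log.info("simulating inputs (%d genes, seed %d)", config.n_genes, config.seed)
    data = simulate_all(config, out)
    cm: de.CountMatrix = data["counts"]

    log.info("estimating size factors and dispersions")
    factors = de.estimate_size_factors(cm)
    disp = de.estimate_dispersions(cm, factors)

    log.info("testing %d contrasts", len(DE_CONTRASTS) + 1)
    de_tables: dict[str, pd.DataFrame] = {}
    for stem, genotype, ta, tb in DE_CONTRASTS:
        res = de.de_contrast(cm, factors, disp, genotype=genotype,
                             treatment_a=ta, treatment_b=tb)
        res.index.name = "gene_id"
        io.write_tsv(res, out / f"{stem}.tsv")
        de_tables[stem] = res
    constitutive = de.de_contrast(
        cm, factors, disp,
        samples_a=cm.samples_for("zen1_rnai", "naive"),
        samples_b=cm.samples_for("wildtype", "naive"),
    )
    constitutive.index.name = "gene_id"
    io.write_tsv(constitutive, out / "constitutive_table.tsv")

    log.info("enrichment on wild-type septic induced genes")
    wt = de_tables["de_wildtype_septic"]
    induced = set(wt.index[wt["significant"] & (wt["direction"] == "induced")])
    universe = set(cm.gene_ids)
    enr = enrichment.enrich(induced, universe, data["annotation"])
    io.write_tsv(enr, out / "enrichment.tsv", index=False)

    log.info("AMP candidate screen")
    props = amp.properties_table(data["records"])
    ctl = de_tables["de_control_rnai_septic"]
    screened = amp.screen_candidates(
        props,
        wt["fold_change"].reindex(props.index),
        ctl["fold_change"].reindex(props.index),
    )
    screened.index.name = "gene_id"
    io.write_tsv(screened, out / "amp_screen.tsv")

    log.info("serosa-dependence classification")
    septic_sets = {
        g: set(t.index[t["significant"]])
        for g, t in (("wildtype", de_tables["de_wildtype_septic"]),
                     ("control_rnai", de_tables["de_control_rnai_septic"]),
                     ("zen1_rnai", de_tables["de_zen1_rnai_septic"]))
    }
    sterile_sets = {
        g: set(t.index[t["significant"]])
        for g, t in (("wildtype", de_tables["de_wildtype_sterile"]),
                     ("control_rnai", de_tables["de_control_rnai_sterile"]),
                     ("zen1_rnai", de_tables["de_zen1_rnai_sterile"]))
    }
    const_set = set(constitutive.index[constitutive["significant"]])
    labels = classify.classify_serosa_dependence(
        septic_sets, sterile_sets, const_set, list(cm.gene_ids)
    )
    io.write_tsv(labels, out / "labels.tsv")
    io.write_tsv(classify.venn_counts(septic_sets), out / "venn_counts.tsv",
                 index=False)
    imm_tables = {
        ("wildtype", "sterile"): de_tables["de_wildtype_sterile"],
        ("wildtype", "septic"): de_tables["de_wildtype_septic"],
        ("control_rnai", "sterile"): de_tables["de_control_rnai_sterile"],
        ("control_rnai", "septic"): de_tables["de_control_rnai_septic"],
        ("zen1_rnai", "sterile"): de_tables["de_zen1_rnai_sterile"],
        ("zen1_rnai", "septic"): de_tables["de_zen1_rnai_septic"],
    }
    imm_tab = classify.tabulate_immune_genes(imm_tables, data["immune"])
    io.write_tsv(imm_tab, out / "immune_table.tsv", index=False)

    log.info("growth-rate estimation and genotype comparison")
    plates = data["plates"]
    io.write_tsv(growth.growth_estimates(plates), out / "growth_estimates.tsv",
                 index=False)
    cmp = growth.compare_growth(
        plates[plates["genotype"] == "wildtype"],
        plates[plates["genotype"] == "zen1_rnai"],
    )
    io.write_tsv(
        pd.DataFrame([{k: cmp[k] for k in ("statistic", "p_value", "warning")}]),
        out / "growth_test.tsv", index=False,
    )

    log.info("Livak qPCR quantification")
    folds = qpcr.livak_table(data["ct"])
    io.write_tsv(folds, out / "qpcr_folds.tsv", index=False)

    return {name: out / name for name in OUTPUT_SCHEMAS}


def validate_outputs(outdir) -> list[str]:
    """Check that every expected output exists with its schema header."""
    out = Path(outdir)
    problems = []
    for name, cols in OUTPUT_SCHEMAS.items():
        path = out / name
        if not path.exists():
            problems.append(f"missing output {name}")
            continue
        sep = "," if name.endswith(".csv") else "\t"
        header = pd.read_csv(path, sep=sep, nrows=0).columns.tolist()
        missing = [c for c in cols if c not in header]
        if missing:
            problems.append(f"{name}: missing columns {missing}")
    return problems
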