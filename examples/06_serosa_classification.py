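"""Serosa-dependence partition of infection-responsive genes.

Runs the full synthetic study end to end and decomposes the septic-injury
DE sets of the three genotypes into Venn cells, then labels each gene:
genes responsive only in serosa-bearing eggs are serosa-dependent, genes
responding to sterile injury in serosa-less eggs are wound genes, and
genes elevated in naive serosa-bearing eggs are constitutively serosal.
"""

from eggimmune import (
    SimulationConfig,
    de_contrast,
    estimate_dispersions,
    estimate_size_factors,
    simulate_counts,
    venn_counts,
)
from eggimmune.classify import classify_serosa_dependence

cm, truth = simulate_counts(SimulationConfig(n_genes=600, seed=6))
sf = estimate_size_factors(cm)
disp = estimate_dispersions(cm, sf)

genos = ("wildtype", "control_rnai", "zen1_rnai")


def de_set(genotype, a, b):
    res = de_contrast(cm, sf, disp, genotype=genotype,
                      treatment_a=a, treatment_b=b)
    return set(res.index[res["significant"]])


septic = {g: de_set(g, "naive", "septic") for g in genos}
sterile = {g: de_set(g, "naive", "sterile") for g in genos}
const = de_contrast(cm, sf, disp,
                    samples_a=cm.samples_for("zen1_rnai", "naive"),
                    samples_b=cm.samples_for("wildtype", "naive"))

print("Venn cells of the septic-injury DE sets:")
print(venn_counts(septic).to_string(index=False))

labels = classify_serosa_dependence(
    septic, sterile, set(const.index[const["significant"]]),
    list(cm.gene_ids))
print("\nper-gene serosa-dependence labels:")
print(labels["label"].value_counts().to_string())
print("\nthe serosa_dependent count tracks the planted 10% inducible"
      " fraction; wound genes respond in every genotype")
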