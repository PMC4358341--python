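# eggimmune

Analysis toolkit for insect-egg immune competence studies, built around the
*Tribolium castaneum* egg model: most insect eggs are wrapped in the serosa,
an extraembryonic epithelium that can be deleted experimentally by parental
*Tc-zen1* RNAi, and the question is whether that epithelium mounts the egg's
immune response. The package implements the complete computational chain
such a study needs — bacterial growth rates from colony counts,
negative-binomial differential expression of a 3-genotype × 3-treatment ×
3-replicate RNA-seq design, category enrichment, a physicochemical screen
for candidate antimicrobial peptides (AMPs), Livak qPCR quantification and
the serosa-dependence partition of responsive genes — together with a
synthetic-data generator that plants every signal the chain is supposed to
find, so the whole pipeline is testable without any external download.

It is aimed at researchers analysing factorial bulk RNA-seq infection
experiments (in insects or elsewhere) who want a compact, fully tested and
scriptable implementation of these classic methods.

## Methods at the core

* **CFU growth rates** — plate colonies are inverted to per-egg
  colony-forming units through the plating arithmetic
  (`colonies · dilution / plated_fraction / eggs_per_pool`), and the
  specific growth rate comes from exponential growth
  N(t) = N₀·e^{kt}, i.e. k = ln(N_t/N₀)/t. Genotypes are compared with a
  Pearson chi-square on the 2×2 table of per-egg CFU totals.
* **Differential expression** — the classic count-based NB scheme:
  median-of-ratios size factors s_j; per-gene dispersion α in
  var = μ + α·μ² by pooled method of moments with a fitted trend
  α(q) = a₀ + a₁/q and a conservative max rule; a conditioned exact-style
  test on per-condition count sums; Benjamini–Hochberg FDR; and the
  selection filter |fold change| ≥ 2 with FDR < 0.01 (zero-baseline
  induction reported as `Inf`).
* **Enrichment** — one-sided over-representation of gene categories among
  DE genes under the Wallenius noncentral hypergeometric (biased urn)
  distribution, computed by numerical integration of its density; with
  unit odds it reduces to the one-sided Fisher test.
* **AMP screen** — peptide length, average-mass molecular weight, net
  charge (#K + #R − #D − #E), hydrophobic ratio over {A,V,I,L,M,F,W,C},
  glycine/proline content; candidates are < 200 residues, not
  net-negative (or glycine-rich as an exception) and ≥ 2-fold induced
  upon infection in at least one serosa-bearing genotype.
* **qPCR** — Livak relative quantification, fold = 2^(−ΔΔCt) with a
  reference gene and the naive group as calibrator.
* **Classification** — Venn decomposition of the per-genotype septic DE
  sets and per-gene labels: serosa-dependent, serosa-independent, wound
  response, constitutive serosal, unresponsive.

## Worked example

```sh
python examples/01_growth_rates.py
```

```
wild-type eggs:  k = 0.44 per hour
serosa-less eggs: k = 0.83 per hour
ratio: bacteria grow 1.9x faster without a serosa

recovered from 10 simulated plates per time point:
 genotype  n0_per_egg  nt_per_egg    k
 wildtype       49.28       728.0 0.45
zen1_rnai       50.24      7160.0 0.83

Pearson chi-square = 1818, p = 0
```

The first two lines use the published mean per-egg CFU counts (53 → 747
and 49 → 7260 over six hours): bacteria double their specific growth rate
when the serosa is absent. The lower block shows the same rates recovered
from a fully simulated plating experiment (Poisson inocula, exponential
growth, binomial plating), and the chi-square confirms the genotypes
differ far beyond sampling noise.

The remaining scripts in `examples/` walk through each capability one at
a time: differential expression on the synthetic study, Wallenius
enrichment, the AMP screen on the published *Tribolium* reference
compilation (20 new candidates, one rescued by the glycine exception),
Livak quantification, and the serosa-dependence partition.

There is also a thin CLI mirroring the library:

```sh
eggimmune run-all --outdir out/          # simulate + full analysis
eggimmune de --counts counts.tsv --samples samples.csv \
    --contrast wildtype:naive:septic --out de.tsv
```

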