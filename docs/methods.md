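# Methods

This note documents the statistical models behind eggimmune, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices a maintainer should know about.

## Study design

All generators and analyses assume the factorial egg-infection design:
three genotypes (wild-type; control RNAi, which controls for the RNAi
procedure itself; zen1 RNAi, whose eggs lack the serosa), three
treatments (naive; sterile injury, a clean needle prick isolating the
wound response; septic injury, a bacteria-coated prick adding infection),
and three biological replicates — 27 samples. The contrasts of interest
are treatment-vs-naive within each genotype plus naive wild-type vs naive
serosa-less eggs.

## Infection dynamics

Per-egg CFU inverts the plating protocol exactly:
`colonies × dilution / plated_fraction / eggs_per_pool` (protocol
defaults: 10 eggs pooled, a quarter of the homogenate plated, t = 6
suspensions diluted 50× for serosa-bearing and 500× for serosa-less
eggs). The specific growth rate is k = ln(N_t/N₀)/t per hour, valid while
growth is still exponential; the estimator is scale-invariant and
composes over adjacent intervals. Groups whose t = 0 mean is below one
CFU per egg (sterile injury) get means only — a rate from a near-zero
inoculum would be noise.

The genotype comparison is a Pearson chi-square (uncorrected
Σ(O−E)²/E, df = 1) on the 2×2 table of pooled per-egg CFU totals at the
two time points. Per-egg values rather than raw plate colonies enter the
table because the protocol dilutes the genotypes differently at t = 6;
raw colonies would cancel the growth signal entirely. Per-egg totals are
rounded to integers, and a warning is attached when any expected cell
falls below 1. A per-plate rate test would be a reasonable alternative;
the pooled 2×2 is the simplest table consistent with count data.

The CFU simulator draws, per plate, ten Poisson inocula around `n0_mean`,
grows each egg deterministically to N₀·e^{kt}, re-Poissons the within-egg
count, and thins the pooled total binomially with probability
`plated_fraction / dilution`. Over 200 replicates at protocol scale
(10 plates × 10 eggs, n₀ ≈ 53) the round-trip rate estimate is biased by
well under 5%.

## Differential expression

The scheme is the classic count-NB chain for small-replicate designs:

* **Size factors.** s_j = median over genes of count_gj / geometric
  mean_g, restricted to genes with positive counts in every sample
  (positive geometric mean). Factors are defined up to a common scale.
* **Dispersion.** Normalized counts q_gj = c_gj/s_j; per gene, the pooled
  within-condition variance w (df = n − #conditions) and the shot-noise
  term z = q̄·mean(1/s_j) give the method-of-moments estimate
  α_g = max(0, (w − z)/q̄²) — genes whose variance does not exceed the
  mean get exactly 0. A parametric trend α(q) = a₀ + a₁/q is least-squares
  fitted to the positive gene-wise estimates and the working dispersion is
  max(gene-wise, trend). The max rule is deliberately conservative: with
  three replicates, gene-wise estimates are noisy downward and
  underestimated dispersion inflates false positives.
* **Test.** For a two-group contrast the per-group count sums K_A, K_B
  are conditioned on their total; each split's probability is the product
  of moment-matched NB pmfs of the sums (mean q̂·Σs_j, variance
  q̂·Σs_j + α·q̂²·Σs_j², with q̂ the pooled normalized mean), and the
  two-sided p-value sums all splits no more likely than the observed one.
  Splits are enumerated inside a ±12σ window of the conditional mode; the
  truncated mass is far below double precision and a full-support
  enumeration is kept as a test oracle. When both groups are all-zero the
  p-value is 1 and the fold change NaN; a zero baseline with expression
  after treatment reports fold = Inf (no pseudocounts — the Inf semantics
  are part of the reporting convention).
* **FDR and selection.** BH step-up per contrast (not across contrasts),
  then the filter: significant ⇔ padj < 0.01 and fold ≥ 2 or ≤ 0.5 or
  infinite, flagged induced/repressed.

Calibration: with the true dispersion supplied, the 5% level rejects
4–6% of null genes in the suite's simulations; with estimated (max-rule)
dispersions the test runs conservative (~2–3%), which is the intended
trade-off at n = 3.

## Enrichment

Over-representation of a category of m₁ genes among n DE genes drawn from
a universe of N is tested with the Wallenius noncentral hypergeometric
distribution — biased sampling without replacement where in-category
genes carry odds w. The pmf is computed by numerical integration; with
the substitution t = s^D (D = w(m₁−x) + (m₂−(n−x))) the integrand

    D·s^(D−1)·(1−s^w)^x·(1−s)^(n−x)

is evaluated in log space, peak-shifted, and integrated with adaptive
quadrature, so the pmf is stable from toy urns to genome-scale
parameters (support mass 1 ± 1e−6 throughout; agreement with
`scipy.stats.nchypergeom_wallenius` and a weighted-urn Monte-Carlo
sampler to ~1e−8 and 3 MC SEs respectively in the tests). With w = 1
the tail equals the one-sided Fisher test.

Weights are optional and default to uniform: no bias covariate (such as
transcript length) is intrinsic to this artifact, so the odds ratio is 1
unless the caller supplies per-gene weights, in which case
w = mean(in-category weights)/mean(out-of-category weights). Category
p-values are reported raw against the conventional p < 0.001 threshold;
a BH-adjusted column is provided but not used for the flag. Only
over-representation is flagged by default; the under-representation tail
is available. Enrichment is run on induced genes only (the direction the
defense response moves), configurable by the caller.

## AMP screen

Properties are computed on the full input protein sequence (no signal-
peptide cleavage — no maturation annotation is assumed): length in
residues; molecular weight as the sum of average residue masses plus one
water (18.02 Da), via Biopython, reported in kDa; net charge as
(#K + #R) − (#D + #E) with histidine and termini ignored (integer charges
at neutral pH); hydrophobic ratio over the set {A,V,I,L,M,F,W,C}
(a common AMP-database convention; the set is configurable), rounded to
integer percent; glycine and proline content in percent.

The candidate filter: length strictly < 200 residues; induction ≥ 2-fold
upon septic injury in wild-type or control eggs (Inf passes, a missing
'no hit' value does not); net charge ≥ 0, or — for net-negative
peptides — glycine content ≥ 25% (the glycine exception; the one
published exemplar sits at 39%). Known AMPs are carried through as
reference rows but excluded from the new-candidate count; output is
sorted by the larger of the two fold changes. The filter is monotone:
tightening any threshold can only remove candidates. On the published
*Tribolium* reference compilation (shipped as package data) the screen
yields exactly 20 new candidates, one via the glycine exception.

## qPCR

Pure Livak quantification with amplification efficiency 2.0: technical
replicates are averaged on the Ct scale (standard practice), each
biological replicate gives ΔCt = Ct_target − Ct_reference, and the fold
change of a group versus the calibrator is 2^(−ΔΔCt) with
ΔΔCt = mean ΔCt_group − mean ΔCt_calibrator. Using group means keeps the
calibrator at exactly 1. The SE is taken over per-biological-replicate
fold changes (2^(−(ΔCt_i − mean ΔCt_cal))), i.e. biological variation
only, with technical variance absorbed by the Ct averaging. Fold changes
are invariant to any global Ct shift, and swapping group and calibrator
inverts them exactly.

## Serosa-dependence classification

"Responsive upon infection" means DE in the septic-vs-naive contrast;
sterile-injury contrasts feed only the wound label. Labels are assigned
with this priority: (1) DE after sterile injury in serosa-less eggs →
wound_response (the gene responds to wounding, not infection, even if it
also moves after septic injury); (2) septic DE in serosa-less eggs →
serosa_independent; (3) septic DE only in serosa-bearing genotypes →
serosa_dependent; (4) DE between naive eggs with and without a serosa
(same 2-fold/FDR filter) → constitutive_serosal; (5) otherwise
unresponsive. The Venn decomposition of the three septic DE sets is
computed exactly (seven disjoint cells covering the union), and labels
are invariant to genotype input order.

## Synthetic-data generator

The generator is the package's test bed: it produces data with exactly
the structure the analyses assume.

* **Counts.** NB via gamma-Poisson with var = μ + α·μ², constant α per
  simulation (per-gene dispersion can be emulated by composing runs).
  Baseline means are log10-uniform in [0.5, 3] (≈3–1000 counts), spanning
  the dynamic range where both the exact test and the dispersion
  estimator are exercised. Defaults: 2000 genes; 10%
  serosa-dependent-inducible, 5% wound-responsive, 5%
  constitutive-serosal, 80% null; induced effects 2^U(3, 8) — generous on
  purpose, since the real transcriptional response features
  hundreds-fold AMP induction. Serosa-dependent genes are induced by
  septic injury only by default (a sterile-response flag exists, since
  real responders include injury-only genes); wound genes respond to both
  injuries in all genotypes; constitutive-serosal genes are elevated in
  serosa-bearing genotypes under every treatment.
* **Dispersion is an assumption, not an estimate**: replicate-level
  variability of the real study is not published, so α = 0.05 (a typical
  bulk-RNA-seq biological-replicate value) is documented here as a
  modelling choice.
* **Peptides** are drawn from the 20 canonical residues with AMP-biased
  or uniform composition; planted AMPs satisfy the screen by
  construction (length < 200, charge ≥ +1, hydrophobic ≥ 30%), decoys
  violate at least one criterion by construction.
* **Ct tables** realise requested fold changes by shifting target Cts by
  −log2(fold) with small Gaussian noise; **annotations** plant a defense
  category on the inducible genes so enrichment has a known answer.
* **Seeding.** One global seed; every output type draws from its own
  `SeedSequence` spawn, so adding an output never perturbs the others,
  and identical configs are byte-identical on disk.

What the generator does **not** emulate: library-size imbalance beyond
what sampling induces (size factors hover near 1), per-gene dispersion
trends, correlated genes, batch effects, GC/length biases, partially
annotated genomes, or qPCR efficiency ≠ 2. Passing tests therefore
demonstrate correctness of the methods on data satisfying their own
assumptions — not robustness to the full messiness of real RNA-seq.

## Problem sizes and numerical choices

The suite runs the calibration checks at 1000 genes, recovery runs at
600–1000 genes, urn Monte-Carlo oracles at 10⁵–10⁶ draws, and the
end-to-end pipeline at the 2000-gene default — sizes chosen so planted
signals are measured with comfortable Monte-Carlo margins while the whole
suite stays fast. Ties in the exact test are included in the rejection
sum with a 1e−10 relative tolerance; BH never returns values above 1;
dispersion trend fitting falls back to zero (gene-wise estimates only)
when fewer than 10 positive estimates exist or the fit fails. Degenerate
inputs (all-zero matrices, empty universes, single-replicate designs,
missing reference wells) raise typed errors rather than propagating NaNs.

## Known limitations

Two-group contrasts only (no multi-factor GLMs, shrinkage estimators or
batch covariates); no GO-graph propagation or annotation transfer; no
saturating growth models (the exponential fit is valid only away from
carrying capacity); no qPCR efficiency correction; the AMP screen is a
physicochemical heuristic, not an activity predictor.
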