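# Methods

`speqtl` implements a spatial eQTL mapping pipeline: disease-associated SNPs
are assigned to the genes they may regulate by requiring physical
co-localization in Hi-C data, and each spatially supported SNP–gene pair is
then tested for a genotype–expression association in every tissue. The
package also implements the supporting statistics such an analysis needs
(SNP-set Monte Carlo enrichment, Fisher exact cis:trans contrast, per-tissue
HLA contribution, gene-set enrichment, pairwise LD), and a synthetic-data
generator that produces every input with planted ground truth so the whole
pipeline is verifiable without external downloads.

## Spatial stage

Hi-C records contacts between restriction fragments, so a SNP's candidate
target genes are the genes whose bodies overlap any fragment recorded in
contact with the fragment carrying the SNP. Coordinates are 0-based
half-open throughout; a point position maps to the unique tiling fragment
containing it, and a gene maps to **all** fragments overlapping its body
(gene-body anchoring, not TSS-only — the fragment join gives no narrower
rule). Contacts from all cell lines are pooled (union), with per-cell-line
provenance kept in the output. A per-record contact-count threshold
`min_count` (default 1) is exposed because no principled threshold exists at
fragment resolution; filtering is monotone by construction.

A SNP sitting on a fragment that itself overlaps a gene is trivially
co-localized with that gene. Such pairs are emitted with
`same_fragment=True` and one implicit supporting contact, and can be
excluded with `include_same_fragment=False`; recorded self-contacts
(fragment paired with itself) are always honored. Positions outside every
fragment produce explicit unmapped records rather than silent drops.

## Association model

For each pair × tissue the model is ordinary least squares of expression on
additive allele dosage (0/1/2) with an intercept; the slope's two-sided
t-test with n−2 degrees of freedom gives the nominal p. No covariates or
latent factors are fitted — expression is treated as already residualized,
which is what the synthetic generator emits. Missing dosages are dropped
pairwise; a test is skipped with a reason code when fewer than `min_samples`
(default 70, matching the donor floor used by tissue-level eQTL panels)
complete pairs remain or when the SNP is monomorphic after the drop.

Multiple testing is controlled with Benjamini–Hochberg step-up q-values over
**all** executed SNP × gene × tissue tests jointly (one family per run;
switchable to per-tissue). The q-value of a test is
`min over {j : p_j >= p_i} of m·p_j/rank_j`, capped at 1. The implementation
is a short vectorized routine rather than a library call because the family
size `m` may exceed the number of observed p-values; it is cross-checked in
the tests against both a brute-force O(n²) step-up oracle and statsmodels'
`fdr_bh` when the families coincide.

Cis/trans classification anchors distance at the SNP-to-TSS offset
(configurable to nearest gene edge): same chromosome and |distance|
strictly below 1 Mb is cis; exactly 1 Mb, farther, or another chromosome is
trans, with inter-chromosomal distance reported as a marker rather than a
number. Because published eQTL counts are sometimes pair-level and
sometimes triple-level, the stage reports significant counts under both
countings (unique SNP–gene pairs, and SNP–gene–tissue triples).

## Monte Carlo SNP-set enrichment

The enrichment question is whether the catalog SNP set has more significant
SNP–gene connections than equally sized random SNP sets from a control
universe. `monte_carlo_enrichment` takes the pipeline as a function
argument, runs it once on the catalog and `n_sets` times (default 100) on
random control sets drawn without replacement using deterministic
sub-seeds, and reports two p-values:

- a **one-sample two-sided t-test** of the null counts against the observed
  count — the conventional summary for this design; and
- a **permutation p**, `(#{null ≥ observed} + 1)/(n_sets + 1)`.

The t-test compares a single draw against a standard error of the mean, so
under the null hypothesis that the catalog is exchangeable with the control
sets it is anti-conservative (the observed count carries full set-level
variance). Calibration properties are therefore asserted on the permutation
p, which is valid (sub-uniform) under exchangeability; the t-test is kept
because it is the field's reporting convention and is extremely powerful
when the catalog is genuinely connected. With a degenerate null (all
control counts identical, variance zero) the t-test is reported as p = 0
when the observed count differs and p = 1 otherwise.

## Fisher exact cis:trans contrast

`fisher_cis_trans` tests whether predicted-regulatory SNPs (regulatory
score strictly below 0.05, missing scores non-regulatory) have a different
cis:trans interaction ratio than the remainder. The two-sided p uses the
summed-probabilities rule — all tables with the observed margins whose
point probability does not exceed the observed table's — which is the
convention of scipy and R and is stated explicitly because two-sided Fisher
conventions differ. The test is verified against exhaustive hypergeometric
enumeration for every table with margins ≤ 12. Zero-margin tables are
uninformative and return p = 1 with a warning. The four counts are explicit
arguments: published reports do not always print the table itself, and
reconstructions from marginal counts are the caller's responsibility.

## Tissue contribution and gene-set enrichment

Per tissue, the HLA contribution is the percentage of that tissue's
significant eQTLs whose SNP is HLA-class. Tissues are grouped high / mid /
low by strict ±1 sample-SD (ddof=1) around the mean over contributing
tissues; tissues with no significant eQTLs do not contribute. The
percentages are scale-free: doubling every tissue's counts changes nothing.

Gene-set enrichment is the one-sided hypergeometric upper tail of the
query–set overlap against a user-supplied background universe size, with BH
correction across sets via the same shared `bh_fdr` routine. Annotation
sets are read from standard GMT files; no ontology-graph propagation is
performed.

## Linkage disequilibrium

`pairwise_r2` computes composite (genotypic) r² — the squared Pearson
correlation of dosage vectors — which requires no phasing and tracks
haplotype r² closely under Hardy–Weinberg equilibrium; for haplotypes with
D′ = 1 and allele frequencies p, q it converges to pq/((1−p)(1−q)), which
the tests verify at n = 10,000. Monomorphic pairs are reported as missing,
never as 0, because an undefined correlation must not masquerade as absence
of LD. Strength labels: robust r² > 0.8, weak r² ≤ 0.6, intermediate
between.

## Synthetic data generator

The generator emulates the study's input layers with known ground truth:

- **Genome**: user-declared chromosomes; restriction fragments with
  geometric lengths around `fragment_size_mean` (default 1 kb, the contact
  resolution the pipeline targets), truncated to tile each chromosome
  exactly — emulating a restriction digest without needing sequence. Genes
  get uniform positions, random strand, and length in a configured range;
  the TSS is the 5′ body end.
- **SNP catalog**: unique positions; trait p-values log-uniform below the
  GWAS-catalog inclusion threshold 9×10⁻⁶; locus class HLA iff inside the
  declared HLA-like interval (half-open); a regulatory score in [0,1].
  An optional control universe (for the Monte Carlo stage) is drawn
  disjointly with uniform trait p.
- **Genotypes**: Hardy–Weinberg dosages at per-SNP MAF drawn from a range
  (default 0.1–0.5); monomorphic columns are redrawn deterministically;
  optional missingness (default 0).
- **Contacts**: one guaranteed contact per planted effect between the SNP's
  fragment and the gene's TSS-side fragment, plus Poisson background at a
  configurable rate per fragment pair; pairs stored smaller id first.
- **Expression**: per tissue, Gaussian noise at `noise_sd` (default 1, so
  betas are in residual-SD units) plus `beta × dosage` for each planted
  effect targeting that gene and tissue.

By default planted pairs are chosen with *exclusive support*: the SNP's
fragment carries no other catalog SNP and overlaps no gene, and the gene's
anchor fragment overlaps no other gene and carries no SNP. Under zero
background this makes the planted set exactly recoverable — the property
the round-trip and recovery tests rely on. The packaged demonstration
study (`speqtl/data/demo.yaml`) uses three chromosomes totalling 1 Mb,
60 catalog + 120 control SNPs, 40 genes, four tissues of 120 samples, seven
planted effects (five cis, two trans) at beta 1.5 — strong enough that
recovery is complete at q < 0.05 while the run stays under a few seconds.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic LD block structure (SNPs are
independent unless constructed otherwise), expression covariance and batch
structure (no PEER/ancestry confounding, so the no-covariate model is
correctly specified by construction), distance-decaying Hi-C contact
frequencies, and genotype–contact dependence (allele-specific looping).

## Numerical and design choices

- One 64-bit run seed; every stage draws from an independent substream
  derived from (seed, stage id), so stage outputs are individually
  reproducible and insertion of a new stage does not shift others.
- 1-based SNP positions at the file boundary are converted to 0-based
  internally; BED files are native 0-based half-open.
- Hypergeometric tail p-values are floored at the smallest positive double
  before BH correction, which requires p ∈ (0, 1].
- Calibration suites use moderate problem sizes chosen to keep the full
  test run short while leaving Monte Carlo error well below the asserted
  margins: 1,000 tests × 200 replicates for FDR calibration, and 200
  meta-replicates × 99 control sets for the enrichment null, on a cached
  test table (nominal p-values are set-independent, so only the BH family
  is recomputed per SNP set — mathematically identical to rerunning the
  stages).

## Known limitations

- No covariate correction in the association model; on real expression
  data this would inflate associations and a residualization step would be
  required upstream.
- The permutation p has resolution 1/(n_sets+1) and is conservative under
  heavy ties in connection counts.
- Fragment assignment assumes fragments tile each chromosome; overlapping
  fragment annotations are not supported.
- The cis window applies to the SNP–TSS distance only; gene-body overlap of
  distal SNPs is not considered in classification.
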