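# speqtl — spatial eQTL mapping from Hi-C contacts

Most disease-associated SNPs found by GWAS are non-coding, and the gene
nearest to a SNP is often not the gene it regulates: regulatory contacts
routinely skip neighbors and can reach across megabases or between
chromosomes. `speqtl` implements the analysis that resolves this by
combining two orthogonal kinds of evidence:

1. **Spatial**: a SNP and a gene are candidate partners only if the
   restriction fragment carrying the SNP is observed in physical contact
   (Hi-C) with a fragment overlapping the gene body.
2. **Functional**: each spatially supported pair is tested in every tissue
   for an association between allele dosage g ∈ {0,1,2} and expression y,

   y = α + βg + ε,  with the slope's two-sided t-test (n−2 df) giving p,

   Benjamini–Hochberg FDR over all SNP × gene × tissue tests (q < 0.05),
   and classification as *cis* (same chromosome, |SNP−TSS| < 1 Mb) or
   *trans* (≥ 1 Mb or inter-chromosomal).

Supporting statistics: a Monte Carlo SNP-set null (is the catalog more
connected than equally sized random SNP sets?), a Fisher exact test for
cis:trans enrichment among predicted-regulatory SNPs, per-tissue HLA
contribution percentages with ±1 SD grouping, hypergeometric gene-set
enrichment (GMT input), and pairwise composite LD r². A synthetic-data
module generates every input — genome, fragments, genes, SNP catalog,
contacts, genotypes, multi-tissue expression — with planted eQTL effects,
so the entire pipeline is testable against known ground truth. See
`docs/methods.md` for the models and their assumptions.

Intended users: statistical-genetics and regulatory-genomics analysts who
want a transparent, fully testable reimplementation of the fragment-level
spatial eQTL approach for method development and simulation studies.

## Worked example

The packaged demonstration study plants seven eQTL effects (five cis, two
trans, β = 1.5 residual SD per allele) in a 1 Mb three-chromosome genome
with four tissues of 120 samples, and zero background contacts:

```bash
speqtl run --config src/speqtl/data/demo.yaml --seed 0 -o demo_out
```

prints (abridged from `demo_out/report.json`):

```json
{
  "n_tests": 28,
  "n_significant_triples": 28,
  "n_cis_pairs": 5,
  "n_trans_pairs": 2,
  "n_cis_triples": 20,
  "n_trans_triples": 8,
  "n_egenes": 7,
  "n_esnps": 7
}
```

Reading this: the spatial join produced exactly the 7 planted SNP–gene
pairs (no background contacts, so nothing else is co-localized), each was
tested in 4 tissues (28 tests), and every test was significant at q < 0.05
— the planted effects are recovered with 100% sensitivity and no false
positives. Counts are reported both as unique SNP–gene pairs (5 cis + 2
trans) and as SNP–gene–tissue triples (20 + 8). The run directory also
contains `spatial_pairs.tsv`, `eqtl_results.tsv`, `links.tsv` (circos-style
link table), `tissue_summary.tsv`, `ld_pairs.tsv`, the Monte Carlo null
draws, and the generated inputs with `truth.tsv`.

Each stage is also individually invocable (`speqtl simulate`,
`map-spatial`, `eqtl`, `enrich`, `ld`, `report`); see `--help`.

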