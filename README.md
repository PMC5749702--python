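# poolscan

A tested, reusable pipeline for pooled whole-genome-resequencing
case-control scans and their downstream association analyses:

- **scan** — filter pooled SNP frequency tables (depth / missingness),
  compute the per-SNP resistant-minus-susceptible allele-frequency
  difference within each sex stratum, and call candidate regions as
  gap-bounded clusters of high-difference SNPs.
- **assoc** — per-genotype chi-square association tables (observed vs
  expected counts from the stratum-wide phenotype ratio) with an uncapped
  Bonferroni adjustment.
- **haplotype** — two-locus unphased genotype classification onto the six
  combined genotype classes of a three-haplotype model, allele-counting
  haplotype frequency estimates, and an EM diagnostic over all four
  haplotypes for the excluded recombinant.
- **expression** — ddCt relative-expression fold changes per genotype group
  and tissue, with Welch unequal-variance t-tests against the reference
  group.
- **simulate** — a synthetic generator (birds with latent haplotype pairs,
  sex-dependent penetrance, 8-pool sequencing design with Poisson depth and
  binomial read sampling, qPCR Ct tables) so every stage runs and is
  verifiable with no external data.
- **io_formats** — strict readers/writers for the TSV dialects, pool-design
  YAML, BED region output, and GFF3 gene-overlap annotation.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria.  The two
supplementary-table tests there fail by design when the study's
supplementary per-SNP tables are not present under `data/supplementary/`
(they are separate downloads, not bundled).

## CLI

```sh
poolscan simulate --seed 1 --out-dir out/            # synthetic data bundle
poolscan scan --pools out/pools.tsv --design out/design.yaml \
    --sex male --min-depth 9 --cutoffs 0.20,0.40 --out-prefix out/scan
poolscan assoc --genotypes out/genotypes.tsv --locus intron6 \
    --line SIM --out out/assoc.tsv
poolscan haplo --genotypes out/genotypes.tsv --out out/haplo.tsv
poolscan expr --ct out/ct.tsv --out out/expr.tsv
poolscan run-all --seed 1 --out-dir out/             # all of the above
```

Outputs are TSV tables, BED region files and a machine-readable
`summary.json` carrying every effective parameter.

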