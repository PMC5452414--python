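# binmeth

Bin-based differential DNA methylation, 24-nt small-RNA and expression
analysis, with a planted-truth simulator so every stage can be scored
against known ground truth.

The pipeline starts from count-level inputs (per-cytosine methylation
reports, per-read or per-bin small-RNA tables, feature count matrices) and
provides:

- **DMR calling** (`binmeth.dmr`): 100-bp bins, per-context pooled counts
  (cytosines covered ≥ 4× in both samples), Fisher exact test, BH
  correction per context, level-difference thresholds (CG > 0.4,
  CHG > 0.2, CHH > 0.1, strict), and joining of significant bins ≤ 200 bp
  apart into regions.
- **DSR calling and differential expression** (`binmeth.srna`): size
  selection (18–30 nt), structural-RNA masking, unique mappers only,
  5′-end bin assignment, reads-per-ten-million (RPTM) normalisation,
  retention of bins with RPTM > 5 in either sample, and an exact
  conditional binomial rate test (BH, FDR 0.01 for regions; FDR 0.05 and
  fold ≥ 2 for genes/TEs).
- **Region analyses** (`binmeth.regions`): gene/TE/gene-TE/intergenic
  partition, bp-weighted region distribution, overlap and total-length
  accounting, percent accounting with half-up rounding, 1-kb flank
  association of differentially expressed features with DMRs, strand-aware
  promoter methylation, and chromatin-state (1–9) distribution/enrichment
  with a binomial-unit test plus a seeded permutation cross-check.
- **Simulation** (`binmeth.simulate`): deterministic genomes, annotations,
  paired wild-type/mutant methylomes (Poisson coverage, binomial calls,
  site-level Beta heterogeneity fixed in the truth), 24-nt sRNA libraries
  and expression counts with recorded planted effects (partial changes for
  the remodeler mutant, near-total CHH/siRNA loss for the siRNA-pathway
  mutants).
- **Exact statistics** (`binmeth.stats`): vectorised two-sided Fisher
  exact and conditional binomial tests (point-probability rule) and BH
  step-up adjustment.

## Command line

```sh
binmeth simulate --outdir out/                 # synthetic data bundle
binmeth dmr --wt WT.cx --mut mut.cx --genome genome.fa \
        --bin 100 --min-cov 4 --gap 200 --q 0.05 --out out/pkl
binmeth dsr --wt-bins srna_WT.tsv --mut-bins srna_mut.tsv --out out/pkl
binmeth deg --counts expression.tsv --out out/degs.tsv
binmeth annotate --regions dmrs.bed --features features.gff3 --genome genome.fa --out out/dist.tsv
binmeth enrich --regions dmrs.bed --states states.bed --genome genome.fa --out out/enr.tsv
binmeth run-all --seed 1 --outdir out/run     # full synthetic pipeline
binmeth report --rundir out/run
```

`run-all` accepts a YAML config (`--config run.yaml`) whose keys mirror
`binmeth.pipeline.RunConfig`; every flag overrides its config default and
all randomness flows from the single root seed. Each run writes TSV/BED
outputs plus `manifest.json` (parameters, seed, sha256 checksums) and is
byte-identical when rerun with the same seed.

## File formats

Genome FASTA; 7-column per-cytosine reports (chrom, 1-based position,
strand, methylated count, unmethylated count, context, trinucleotide);
GFF3 or BED6(+kind) features; BED4 chromatin states (name = state 1–9);
BED6 regions (name = `direction|context`, score = −10·log₁₀ q capped at
1000); sRNA per-read BED6 (name = `length:hits`) or per-bin TSV with a
`# total_mapped=` header. Internal coordinates are 0-based half-open
everywhere; conversions happen only at file boundaries.
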