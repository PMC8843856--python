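# polyte

Polymorphic transposable-element (TE) population analysis, exercisable
end-to-end on synthetic data:

- **popgen** — windowed diversity statistics from scratch: π, Watterson's θ,
  Tajima's D, Hudson/Weir–Cockerham Fst, and the reduction-of-diversity
  statistic ROD = 1 − π_target/π_ref.
- **scan** — three-stage adaptive TE-insertion detection: joint top-5%
  empirical outliers of Fst and log π-ratio over polymorphic TE regions,
  a ROD screen in 500-bp windows over 10-kb flanks, and a Tajima's-D
  confirmation over 20-kb flanks.
- **sirna** — 24-nt siRNA locus construction (≥10-read clusters, 150-bp
  merging) and siRNA+/− TE labeling.
- **landscape** — TE genic-region classification (CDS > 5′UTR > 3′UTR >
  intron > 2-kb promoter > 2-kb downstream > intergenic), 100-bp flank-bin
  profiles around start/stop codons, and covered-bp density per 100-kb
  window.
- **expression** — nearest-TE distances, binned mean FPKM (500-bp bins to
  5 kb), siRNA±-stratified contrasts, and timepoint contrasts.
- **frequency** — complete-case TE insertion frequencies, shared/specific
  classification, the low-frequency (f ≤ 0.1) purifying-selection bias test
  (one-sided Fisher's exact, BH-corrected), frequency spectra, superfamily
  composition, and the distance–sharing Pearson correlation.
- **simulate** — generates every input the pipeline consumes (coalescent
  haplotype panels with an optional TE-linked sweep, TE genotype matrices
  with planted category bias, gene/TE/siRNA annotations, FPKM tables with
  planted effects) with known ground truth.

Internal coordinates are 0-based half-open everywhere; VCF and GFF3 are
converted at the I/O boundary, BED passes through.

## CLI

`polyte` (or `python -m polyte.cli`) exposes one subcommand per stage:

```sh
# generate a synthetic fixture bundle with a planted sweep
polyte simulate --seed 7 --n-regions 50 --sweep-region-index 25 --out-dir fix/

# windowed statistics and the adaptive scan
polyte stats --vcf fix/snps.vcf --populations fix/populations.tsv --out-dir out/
polyte scan  --vcf fix/snps.vcf --populations fix/populations.tsv \
             --te-bed fix/te_loci.bed --out-dir out/

# siRNA loci, TE landscape, expression, frequency analyses
polyte sirna      --reads-bed fix/sirna_reads.bed --te-bed fix/landscape_tes.bed --out-dir out/
polyte landscape  --te-bed fix/landscape_tes.bed --gff3 fix/genes.gff3 --out-dir out/
polyte expression --gff3 fix/genes.gff3 --te-bed fix/landscape_tes.bed \
                  --expression fix/expression.tsv --labels out/te_sirna_labels.tsv \
                  --contrast 0h 36h --out-dir out/
polyte frequency  --te-bed fix/te_loci.bed --te-matrix fix/te_matrix.tsv \
                  --populations fix/populations.tsv --out-dir out/
```

Every run logs its resolved parameter set to stderr; defaults live in
`ConfigProfile` and can be set in a flat `key = value` config file
(`--config`), with CLI flags taking precedence. Reruns with identical
inputs and `--seed` produce identical outputs.

## Fixture bundles

`polyte simulate` writes VCF/BED/GFF3/TSV artifacts plus `truth.json`
(planted parameters: adaptive TE ids, carrier frequencies, expression
effects) and `manifest.json` with SHA-256 checksums for reproducibility
verification (`polyte.simulate.verify_fixture_bundle`).
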