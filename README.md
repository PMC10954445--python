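# nrskit

Discovery, anchoring, merging, genotyping and population-genetic analysis
of **non-reference sequences (NRSs)** — insertion-type structural variants
present in individual genome assemblies but absent from the reference —
plus a fully seeded synthetic-panel simulator so the entire pipeline can be
exercised and validated at desk scale.

## What it does

1. **simulate** — build a random reference genome (chromosomes with
   centromeric satellite arrays, genes with TSSs), plant insertion events
   (tandem-repeat, mobile-element-like, unique novel) with
   population-stratified allele frequencies, trios, contaminant contigs,
   depth tracks, expression/phenotype tables and a tag-SNP panel; emit
   per-sample contig FASTAs and a truth set.
2. **extract** — align contigs to the reference (k-mer seed + chain +
   polish), emit unaligned segments ≥50 bp, and apply the depth (3×/⅓ of
   the sample mean), satellite (≥80% masked) and two-tier
   composition-based contamination filters.
3. **anchor** — place each segment via its 1 kb contig flanks (both flank
   alignments >500 bp, reference inner endpoints <20 bp apart → insertion
   point at the floor midpoint); filter unplaced sequences (reference
   hits, repeat content, cross-sample singletons); hotspot permutation
   scan and arm-end enrichment.
4. **merge** — cluster placed calls per chromosome (single linkage at
   250 bp + pairwise-bound splitting), pick representatives by
   sum-of-pairs alignment score (+2/−1/−0.5), deduplicate unplaced calls
   (all-vs-all ≥200 bp / ≥90% identity, 80% containment), and assign
   stable `GNRS_#####` ids.
5. **genotype** — presence/absence genotyping from breakpoint evidence
   (0/0, 0/1, 1/1, ./. at min support 2), Mendelian trio error rate,
   exact Hardy–Weinberg test, concordance against truth.
6. **analyse** — allele-frequency categories (singleton / polymorphic /
   major / shared), population sharing, growth curves, N50, genic
   annotation, Fisher enrichment; genotype PCA; Hudson-F_ST PBS selection
   scan with downsampling consensus, 1 Mb signal merging and
   platform-batch χ² exclusion; cis-eQTL (1 Mb TSS window, BH 5% FDR);
   GWAS (additive model, age/sex/BMI + PCs, Bonferroni threshold);
   LD between NRSs and phenotype-associated SNPs (100 kb, r² > 0.8).

## CLI

```bash
# full pipeline on a simulated panel described by a YAML config
nrskit run --config examples/demo.yaml --seed 42 --out out/

# or stage by stage
nrskit simulate --config examples/demo.yaml --out sim/
nrskit extract  --contigs sim/assemblies/AFR_001.fa --ref sim/reference \
                --depth sim/assemblies/AFR_001.depth.bed \
                --sample AFR_001 --out segments.tsv
nrskit anchor   --segments segments.tsv --contigs sim/assemblies/AFR_001.fa \
                --ref sim/reference --out calls
nrskit stats    --genotypes out/genotypes.vcf --panel out/panel.tsv --out stats/
nrskit scan-pbs --genotypes out/genotypes.vcf --panel out/panel.tsv \
                --focal EAS --sister AMR --outgroup AFR --out pbs.tsv
nrskit eqtl     --genotypes out/genotypes.vcf --expression expr.tsv \
                --genes out/reference/genes.tsv --out eqtl.tsv
nrskit gwas     --genotypes out/genotypes.vcf --phenotypes phen.tsv \
                --trait trait_q --out gwas.tsv
nrskit ld       --genotypes out/genotypes.vcf --snps snps.tsv \
                --snp-table snp_table.tsv --out ld.tsv
```

Pipeline outputs are plain text: catalogue VCF (ALT carries the full
insertion sequence; INFO: GNRS, SUPP, AF, CATEGORY), unplaced FASTA,
genotype VCF, panel/summary TSVs and a MANIFEST of completed stages.
Identical config + seed ⇒ identical outputs.

## Layout

```
src/nrskit/
  seqcore/       alignment, tandem/satellite/low-complexity annotation,
                 composition classifier, representative selection
  simulate.py    synthetic panels with planted truth
  extraction.py  unaligned-segment extraction + filters
  anchoring.py   flank anchoring, unplaced filters, hotspot/arm-end stats
  merging.py     clustering, representative selection, catalogue build
  genotyping.py  breakpoint-evidence genotyping, Mendelian, HWE
  popstats.py    AF categories, sharing, growth curves, N50, enrichment
  association.py PCA, F_ST/PBS scan, batch filter, eQTL, GWAS, LD
  pipeline.py    stage orchestration
  io.py, cli.py  formats and command line
  resources/     satellite monomer library, composition profiles
```
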