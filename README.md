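# dfprint

Differential DNase-seq footprinting from strand-specific 5′ cut imbalance.

Digital DNaseI footprinting locates transcription-factor binding sites as
short windows inside DNase hypersensitive sites (DHSs) that are protected
from cleavage, flanked by a characteristic strand-imbalanced pile-up of
cuts (positive-strand cuts directly upstream, negative-strand cuts directly
downstream). `dfprint` detects such footprints in a single dataset and, its
main purpose, scores **differential** footprint occupancy between two
DNase-seq datasets:

1. footprints are detected in the primary dataset;
2. at each locus the comparator dataset's per-base cut counts are pooled in
   and the footprint score of the pooled data is computed;
3. the comparator counts are shuffled (independently per strand, within the
   scored window) many times, pooled and re-scored, giving a bootstrap
   score distribution;
4. the percentile of the unshuffled pooled score within that distribution
   is the differential footprinting (DFP) score in [0, 100]. Low scores
   mean the comparator genuinely contributes footprint structure
   (non-differential); high scores mean it does not (differential). The
   roles of the two datasets are then reversed to obtain both directions.

Companion computations: library-normalised differential DHS (ΔDHS) scores
with a single-nearby-TSS promoter filter, hexamer cleavage-bias-corrected
average cleavage profiles (with optional VCF-based reference correction),
score-sorted strand-imbalance heatmap matrices, relative motif-frequency
matrices with Euclidean/complete-linkage clustering, a minimal PWM scanner,
a Mann–Whitney expression-shift test, and shared-DHS overlap summaries.
A fully seeded synthetic-data generator (planted footprints, SAM/FASTA
fixture emission) makes the whole pipeline testable offline.

## CLI

All commands are subcommands of `dfprint` (BAM or plain SAM accepted; SAM
is converted to an indexed BAM in a scratch directory automatically):

```bash
# per-base 5' cut counts over BED intervals (chrom, pos, fwd, rev)
dfprint cuts reads.bam dhs.bed

# single-dataset footprints (BED6, score = footprint score)
dfprint wellington reads.bam dhs.bed -o footprints.bed

# differential footprints between two datasets
dfprint bootstrap a.bam b.bam dhs_a.bed dhs_b.bed -n 1000 --seed 1 \
    --threshold 10 -o outdir/
# -> outdir/over_in_A.bed, outdir/over_in_B.bed, outdir/summary.tsv

# differential DHS scores (optionally filtered to single-TSS promoters)
dfprint ddhs a.bam b.bam dhs.bed --tss tss.bed -n 1000 -o ddhs.tsv

# average (optionally bias-corrected) cleavage profile around loci
dfprint profile reads.bam motifs.bed --flank 100 \
    -b genome.fa --bias sixmer_bias.txt --vcf sample.vcf -o profile.tsv

# score-sorted strand-imbalance matrix (TSV; render with any heatmap tool)
dfprint heatmap a.bam b.bam over_in_A.bed over_in_B.bed -o matrix.tsv

# relative motif-frequency matrix + clustering orders
dfprint motif-matrix dfp_beds/ motif_hit_beds/ -C 1.0 -o matrix.tsv \
    --order rows.txt cols.txt

# synthetic fixture (SAM reads, truth BED, toy genome FASTA)
dfprint simulate --spec spec.json -o fixture_dir/
```

The 6-mer bias table is a two-column text file (`6mer<TAB>weight`); supply
your own measured table (e.g. from naked-DNA DNase-seq).

## Library quick start

```python
from dfprint import (SimSpec, simulate_pair, differential_from_profiles,
                     ShuffleConfig)

sa = SimSpec(region_length=6000, depth=100, background=0.01, seed=1)
sb = SimSpec(region_length=6000, depth=100, background=0.01, seed=2)
pa, pb, truth = simulate_pair(sa, sb,
                              shared_footprints=[(1000, 25)],
                              a_only=[(3000, 25)], b_only=[(5000, 25)])
calls = differential_from_profiles([pa], [pb], cfg=ShuffleConfig(seed=3))
for d in calls.over_in_A:
    print(d.locus.interval, d.score)
```

## Conventions

- Coordinates are 0-based half-open (BED convention) everywhere.
- The 5′ cut of a −-strand read is its rightmost aligned base (no ±1
  offset).
- Duplicate reads are retained; unmapped/secondary/supplementary
  alignments are excluded.
- With `n` shuffles the DFP score is a multiple of `100/n`; ties count
  toward the differential side, and loci whose comparator has fewer than
  10 cuts in the scored window are flagged `low_coverage` (absence of
  reads is not evidence of absent binding).
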