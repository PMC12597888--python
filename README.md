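# fragkit

Fast extraction of cell-free DNA (cfDNA) fragmentation features from aligned
fragment data — for liquid-biopsy researchers who already have
coordinate-sorted BAM/CRAM files or FinaleDB-style tabix-indexed `frag.gz`
fragment files and need the standard fragmentomic measures without
reimplementing them.

## Features

| Feature | What it measures |
|---|---|
| fragment length histogram / per-interval stats | size distribution (167 bp nucleosomal mode, sub-nucleosomal ladder) |
| coverage | midpoint-counted fragment depth per interval |
| WPS (raw + adjusted) | window protection score: spanning minus endpoint-inside fragments per base; nucleosome footprints |
| DELFI | GC-corrected short (100–150 bp) / long (151–220 bp) count ratio per 100 kb bin |
| end motifs + MDS | 5′ k-mer frequencies and their normalized Shannon entropy |
| breakpoint motifs | k-mer context spanning the cleavage site |
| cleavage profile | per-position fraction of covering fragments that terminate there, around site lists |
| mds-classify | interval-MDS feature matrix → ANOVA-F selection → logistic regression, repeated stratified 10-fold CV AUC |
| synth | deterministic generators: reference FASTA, fragment files, two-cohort feature matrices |

Key definitions, with `w` the protection window (default 120 bp):

- **WPS(p)** = #{fragments spanning `[p − w/2, p + w/2)`} − #{fragments
  with an endpoint inside that window}. Adjusted WPS subtracts a 1 kb
  running median and applies Savitzky–Golay (21, order 2) smoothing.
- **MDS** = Σᵢ −fᵢ·log fᵢ / log 4ᵏ over the 4ᵏ end-motif frequencies fᵢ
  (1 = uniform, 0 = degenerate).
- **Cleavage proportion(p)** = termini exactly at p / fragments covering p,
  pooled across sites.

All features run genome-wide or over arbitrary BED intervals, stream
identically from BAM/CRAM and `frag.gz`, and accept `--workers N`
(byte-identical output for any worker count).

## Worked example

Generate a synthetic dataset and run the end-motif → MDS pipeline:

```bash
fragkit synth reference --seed 1 --length 60000 --out ref.fa
fragkit synth fragments --seed 2 --n 4000 --length 60000 --out frags.frag.gz
fragkit end-motifs frags.frag.gz ref.fa -k 4 --out motifs.tsv
fragkit mds motifs.tsv
```

prints

```
0.997252
```

an MDS close to 1: the synthetic reference is uniform ACGT, so the 256
4-mer end motifs are nearly equally frequent and the normalized entropy is
high (real cfDNA, with nuclease-preferred end motifs, sits lower). The same
table piped per interval:

```bash
printf 'chr1\t0\t30000\nchr1\t30000\t60000\n' > bins.bed
fragkit interval-end-motifs frags.frag.gz ref.fa bins.bed --out - | fragkit interval-mds -
```

```
contig	start	end	mds
chr1	0	30000	0.994269
chr1	30000	60000	0.994308
```

And a WPS track over a region (bedGraph or bigWig by extension):

```bash
printf 'chr1\t60000\n' > chrom.sizes
printf 'chr1\t20000\t30000\n' > region.bed
fragkit wps frags.frag.gz chrom.sizes --site-bed region.bed --out wps.bedgraph
```

Library use mirrors the CLI; for example:

```python
from fragkit import read_fragments, raw_wps, GenomicInterval
track = raw_wps("frags.frag.gz", GenomicInterval("chr1", 20_000, 30_000))
```

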