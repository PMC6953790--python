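# segstack

Analysis toolkit for segmented somatic copy-number data (SEG-style
tables of per-sample genomic intervals with log2 copy ratios).
It provides four analysis engines plus ground-truthed simulators:

* **Co-alteration queries** (`segstack.cairn_query`) — classify every
  sample of a cohort against one or two query regions (e.g. a gene
  pair) as `exclusive_a` / `exclusive_b` / `coincident` / `none`,
  find segments terminating inside a region (telo-centric events), and
  render deterministic stacked SVG views (blue losses, red gains, grey
  chromosome backbone).
* **Reduced-segment differential calling**
  (`segstack.reduced_segments`) — build the samples × union-breakpoint
  tile matrix, average controls into a baseline, call CNAs at a
  configurable |log2| deviation (default 0.2) with adjacent-tile
  merging and focal (<100 kb) / intermediate / large (>1 Mb) size
  classes, and count merged CNA events per chromosome in windowed
  tumor/normal profiles.
* **Drift statistics** (`segstack.drift_stats`) — Euclidean distance
  matrices over reduced-segment vectors, average-linkage hierarchical
  clustering (Newick export), unique-vs-shared CNA tabulation and the
  two-sided Fisher's exact comparison between groups.
* **Breakpoint features** (`segstack.breakpoints`) — classify CNA
  edges as telomeric / centromeric / intragenic / fragile / stable
  (2 Mb windows around chromosome ends and centromeres), collect
  overlapped gene sizes and expression, and compute an
  iso-chromosomal permutation null (each call relocated uniformly on
  its own chromosome, length preserved) with add-one empirical
  p-values.
* **Simulators** (`segstack.synthetic`) — cohorts with planted
  co-alteration compositions, serial-passage drift experiments with
  planted unique/shared events, windowed tumor/normal profiles with
  planted per-chromosome events, and breakpoint-biased call sets; all
  seed-deterministic with full ground truth.

Supported inputs: SEG / TCGA PanCanAtlas segment dialects (1-based
inclusive, gzip ok), HMMcopy-style merged-segment output, BED-like
gene/interval tracks, chromosome-length and expression tables.
Internal coordinates are 0-based half-open; `chr` prefixes are
normalized away.

## CLI

```sh
segstack simulate drift --config cfg.yaml --seed 5 --out-dir sim/
segstack query --segments tumors.seg --dialect tcga --genes genes.bed \
    --gene-a BECN1 --gene-b BRCA1 --direction loss --threshold 0.2 \
    --out-summary summary.tsv
segstack reduce --segments sim/segments.seg --controls c1,c2,c3,c4 \
    --threshold 0.2 --out-calls calls.tsv
segstack drift --segments sim/segments.seg --controls c1,c2,c3,c4 \
    --groups sim/groups.tsv --out-distances dist.tsv \
    --out-ratios ratios.tsv --out-dendrogram tree.nwk
segstack breaks --calls calls.tsv --chrom-lengths sim/chrom_lengths.tsv \
    --genes genes.bed --centromeres cen.bed --n-perm 1000 --seed 17 \
    --out breaks.tsv
segstack count-per-chrom --segments tumor.seg --dialect hmmcopy \
    --threshold 0.2 --out counts.tsv
segstack render --segments tumors.seg --genes genes.bed --gene-a A \
    --gene-b B --chrom-lengths lengths.tsv --out-svg stack.svg
```

Every command writes a `*.provenance.json` record (version, seed,
config echo) next to its first output. Exit codes: 0 success, 1 data
error (e.g. missing input file), 2 usage error.

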