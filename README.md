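# enhancerkit

Quantification and classification of signal-dependent enhancers from
genomic tag data (ChIP-seq / CUT&RUN / PRO-seq style), with a synthetic-data
generator so the entire analysis runs at desk scale with no downloads.

The pipeline:

1. **Tag directories** — deduplicate aligned-tag 5' positions with a clonal
   cap (2 tags per position for ChIP-style data, 3 for nascent
   transcription) and normalize every library to 10 million tags.
2. **Peak calling** — sliding-window Poisson test against the maximum of the
   genome-wide and local background rates; replicate concordance via a
   summit-distance filter (a documented stand-in for IDR, which is out of
   scope).
3. **Putative enhancers** — ±1,000 bp windows around TF/accessibility peak
   summits, at least 3 kb from any annotated TSS, scored by H3K27Ac tags.
4. **Classification** — the six enhancer-group definitions (MegaTrans,
   ERα-marked other-active, other-active, proinflammatory, androgen-induced,
   neuronal-induced) from windowed tag floors (≥16 H3K27Ac, ≥10 nascent/Pol II
   tags-per-10M) and pseudocounted fold-changes (≥1.5 induction; open
   "unchanged" band (0.67, 1.5)), plus TOP1cc-enrichment flags from feature
   peak summits near region centers.
5. **Differential** — fold-change + expression-floor calls for eRNA windows
   (±1,000 bp) and gene bodies (first 13 kb, 500 bp promoter-proximal region
   excluded, sense strand), with an optional exact conditional-binomial test
   and BH adjustment.
6. **Overlap statistics** — interval overlap counts (half-open, BED
   semantics), Venn partitions, enrichment versus seeded random genomic
   background, and per-region tag Pearson correlations.
7. **Synthetic data** — toy genome + annotation, planted enhancer classes
   with known intensities, per-gate decoys, and Poisson/Gaussian tag
   simulation with divergent eRNA geometry and ground truth for recovery
   testing. Planted treated-condition masses are solved analytically so that
   *normalized* fold-changes hit their targets despite depth normalization.

## CLI

```sh
# generate a self-contained synthetic fixture (tags, annotation, truth, manifest)
enhancerkit simulate --seed 1 --out fixture/

# run the full pipeline from a manifest (synthetic fixture or real tagAlign inputs)
enhancerkit run --manifest fixture/manifest.yaml --out results/run

# individual stages
enhancerkit tagdir --tags tags.bed --chrom-sizes genome.chrom.sizes --cap 2 --out mydir
enhancerkit callpeaks --tagdir mydir --pvalue-max 1e-5 --out peaks.bed
enhancerkit enhancers --anchors peaks.bed --k27ac-tagdir k27dir --tss tss.tsv --out enh.bed
enhancerkit diff --tagdir-a ctrl --tagdir-b treated --regions enh.bed --out diff.tsv
enhancerkit overlap --query a.bed --features era b.bed --chrom-sizes genome.chrom.sizes --out enr.tsv
enhancerkit profile --tagdir mydir --regions enh.bed --flank 3000 --out profile.tsv
```

Thresholds default to the published values (`--k27ac-min 16`,
`--tss-min-dist 3000`, `--fc-up 1.5`, `--cap 2`, `--norm-target 10000000`)
and can be overridden by flag or manifest YAML (flag wins).

### Input formats

- tags: BED6/tagAlign, 5' end = `start` for `+` tags, `end - 1` for `-` tags
- peaks/regions: BED3/BED6 (+ optional summit-offset column 7)
- chromosome sizes: two-column TSV (name, length)
- TSS annotation: five-column TSV (gene, chrom, tss, strand, gene_end)

All coordinates are 0-based half-open throughout.

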