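# utrscreen

Analysis toolkit for FACS-binned, sequencing-read-out 3′UTR reporter screens
(sort-seq / MPRA-style). It covers the full computational arm of such a
screen, plus a synthetic-screen generator with known ground truth so every
stage is testable without external data:

- **`utrscreen.simulate`** — ground-truth 8mer libraries, reporter-cell
  simulation, dsRed/GFP percentile gating into the screen's populations
  (five GFP bins, GFP-ALL, stringent dsRed middle-25 % background), and
  sequencing emission as count tables or full amplicon FASTQ.
- **`utrscreen.readproc`** — amplicon FASTQ → RPM-normalized 8mer count
  tables with the screen's filtering rules: exact barcode, Phred strictly
  > 20 over barcode and 8mer, exact `CATAC`/`ATA` flanks, first-failure
  attribution.
- **`utrscreen.scoring`** — per-bin enrichment against the GFP-ALL
  background, the bin-weighted expression score
  `S = Σ w·rpm / Σ rpm ∈ [−2, +2]` with weights (−2, −1, 0, +1, +2),
  activating (>+1) / repressive (<−1) calls, replicate concordance, and the
  robust-background-set filter.
- **`utrscreen.stability`** — log2(RNA/DNA) RPM ratios with ±0.5
  stabilizing/destabilizing cutoffs, first-order decay half-life fitting
  (OLS on log abundance, t½ = ln2/k), and score-vs-ratio correlation with
  discordant-set reporting.
- **`utrscreen.enrichment`** — motif-category enrichment
  `fold = (b/n)/(B/N)` with exact two-sided Fisher tests
  (minimum-likelihood convention; doubling optional), reverse-complement
  score correlation, and conserved-instance counting over 4-species
  alignments judged against composition-preserving shuffled controls.
- **`utrscreen.pipeline` / `utrscreen.cli`** — YAML-configured, seeded,
  byte-reproducible end-to-end runs with an audit report.

## CLI

```sh
# simulate a screen and analyze it end to end
utrscreen simulate --seed 1 --n-motifs 1000 --depth 200000 --outdir run/

# the same, emitting and re-parsing real FASTQ reads
utrscreen simulate --seed 1 --emit-reads --outdir run/

# individual stages
utrscreen count run/reads.fastq --barcodes run/barcodes.tsv --out counts.tsv
utrscreen score counts.tsv --out scores.tsv --threshold-sweep 0.5,1.0,1.5
utrscreen stability dna_counts.tsv rna_counts.tsv --out stability.tsv
utrscreen halflife decay.tsv
utrscreen enrich scores.tsv --category conserved conserved.txt --out enrich.tsv
utrscreen conserve gene1.fasta gene2.fasta --motif ACAGGGUA --out cons.tsv
utrscreen run --config config.yaml --outdir run/
utrscreen report run/
```

All tabular inputs/outputs are TSV; category lists are plain text (one
8mer per line, RNA alphabet); alignments are aligned multi-FASTA blocks.

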