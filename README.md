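# clonoscape

A desk-scale, fully tested reimplementation of a single-cell TCR clonotype
selection pipeline: from molecule-level sequencing tables to the dominant
antigen-specific clonotype, plus the LDH cytotoxicity statistics used to
validate it. All inputs are produced by a built-in synthetic-data generator
with planted ground truth, so every stage is testable offline.

## Pipeline stages

1. **synthetic** (`clonoscape.synthetic`) — generates molecule tables
   (cell label × UMI × feature × reads), AIRR rearrangement tables,
   per-sample targeted gene-expression matrices and LDH optical-density
   plates, all deterministic under a single seed, with a `GroundTruth`
   recording every planted fact (sample of origin, clonotype membership,
   the dominant clonotype, true binding affinities, UMI error parents).
2. **molecules** (`clonoscape.molecules`) — recursive substitution error
   correction of UMIs (RSEC; parent rule `reads(v) ≥ 2·reads(u) − 1`,
   applied to fixpoint), distribution-based error correction (DBEC;
   exhaustive minimum within-class-variance split of log2 read depths with
   a 1 log2-unit separation margin), second-derivative cell calling on the
   barcode-rank curve, and sample-tag demultiplexing with per-tag
   `mean + 3·SD` noise thresholds and multiplet exclusion.
3. **expression** (`clonoscape.expression`) — matrix merging, counts-per-
   million normalization, zero→one log2 transform, CD8+CD4−FOXP3− gating,
   mean-centered PCA with scree output, and seeded UMAP on the first 4
   principal components.
4. **clonotypes** (`clonoscape.clonotypes`) — AIRR TSV I/O, paired-chain
   clonotype construction (highest-duplicate-count productive chain per
   locus), abundance filtering, and dominant-clonotype selection by cell
   count first and mean predicted binding score second, restricted to
   predominantly effector (CD8+CD4−FOXP3−) clonotypes.
5. **affinity** (`clonoscape.affinity`) — the CSV dialect of the external
   TCR–peptide binding predictor (CDR3α/β, peptide, MHC class, V/J genes,
   T-cell type, cell index; scores in [0, 1]) and a deterministic
   surrogate scorer that stands in for the neural network.
6. **cytotoxicity** (`clonoscape.cytotoxicity`) — the LDH percent-
   cytotoxicity formula, per-donor group summaries, one-way ANOVA with
   Tukey HSD (Tukey–Kramer), and enrichment fold-change summaries. A
   bundled reference dataset of seven donors × three tumor cell lines ×
   two transduction conditions lives in `clonoscape.datasets`.
7. **pipeline** (`clonoscape.pipeline` / `clonoscape.cli`) — one-command
   orchestration with a YAML/JSON config, deterministic run reports, and
   per-stage timings.

## CLI

```bash
clonoscape demo --out runs/demo --seed 0        # full demo run (~5000 cells)
clonoscape run --config configs/demo.yaml --out runs/r1
clonoscape simulate --config configs/demo.yaml --seed 1 --out sim/
clonoscape correct --molecules sim/molecules.tsv --out corr/
clonoscape call-cells --molecules corr/corrected.tsv --out cells.json
clonoscape demux --molecules sim/molecules.tsv --cells cells.json --out demux.tsv
clonoscape clonotypes --airr sim/airr.tsv --min-cells 2 --out clonotypes.tsv
clonoscape cytotox-summary --out cytotox/
```

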