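# dualscreen

Toolkit for dual-sgRNA CRISPRi genetic-modifier screens: in-silico
dual-guide library construction, a synthetic FACS reporter-screen
generator with known ground truth, guide counting, per-screen gene
statistics, and anchored-vs-non-targeting screen comparison that
classifies genes as synthetic, same-pathway, or orthogonal interactors.

## What it does

A dual-guide library pairs a **fixed anchor guide** (knocking down a
chosen pathway gene in every cell) with a genome-wide **variable guide**.
Running a reporter screen once with a non-targeting (NT) anchor and once
with a gene anchor, then comparing per-gene results, reveals genetic
interactions:

* **synthetic** — phenotype enhanced in the anchored screen
  (parallel-pathway factor),
* **same_pathway** — phenotype drops out in the anchored screen,
* **orthogonal** — phenotype unchanged between screens.

The package covers each stage:

| module | purpose |
| --- | --- |
| `dualscreen.library_design` | annealing-oligo design for the anchor cassette, BamHI/NotI restriction attrition of the variable library, coverage arithmetic, library TSV/FASTA I/O |
| `dualscreen.screen_sim` | two-pathway redundancy flux model, per-cell reporter simulation, 30% tail FACS gates, multinomial sequencing depth, growth-screen mode, paired-dataset generator with truth tables |
| `dualscreen.counts_io` | exact-match guide counting from FASTQ, count-table TSV round-trips, table merging |
| `dualscreen.phenotype_stats` | 50-count filter, pseudocounted log2 enrichment, NT-median centering, replicate averaging, strongest-k gene phenotype, Mann-Whitney p (exact by enumeration for small samples), discriminant score, gene ranking, growth gamma |
| `dualscreen.interaction_compare` | rank deltas, three-way interaction classification, confusion matrix against simulated truth |

## CLI

```bash
# oligos for cloning a fixed guide into the anchor cassette
dualscreen design oligos --guide GGAGTACGCGTCCGGGCCAA

# restriction-attrite a parent library and attach the fixed guide
dualscreen design build --parent parent.tsv --fixed GACGACTAGTTAGGCGTGTA --out build/

# simulate a paired NT/anchored FACS screen with known ground truth
dualscreen simulate --config sim.yaml --seed 1 --out sim/

# count guides in reads (exact match after the 5' constant anchor)
dualscreen count --fastq reads.fastq --library sim/library.tsv \
    --anchor GTGTGTTTTGAGACTATAAGTATCCCTTGGAGAACCACCTTGTTG \
    --sample NT.1.high --out counts.tsv

# score each screen, then compare them
dualscreen analyze --counts sim/counts.tsv --library sim/library.tsv --screen NT --out nt/
dualscreen analyze --counts sim/counts.tsv --library sim/library.tsv --screen anchor --out anchor/
dualscreen compare --nt nt/gene_stats.tsv --anchor anchor/gene_stats.tsv \
    --anchor-gene G0001 --truth sim/truth.tsv --out cmp/
```

Count-table sample columns follow the grammar `library.replicate.bin`,
e.g. `NT.1.high`, `anchor.2.low`, `NT.1.day0` (growth mode).

Library TSVs have columns `element_id`, `gene`, `protospacer`,
`is_negative_control`; negative-control guides use the gene label
`negative_control`.

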