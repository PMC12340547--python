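# leaderless-scan

Detection and characterization of the bacterial promoter −10 element
(Pribnow-box-like hexamer, consensus TANNNT) that sits immediately upstream
of protein-coding genes in GC-rich genomes such as *Deinococcus
radiodurans*, where it marks **leaderless transcription**: the transcript
starts a handful of bases before the start codon, leaving no 5′-UTR and no
ribosome-binding site. The package is aimed at bacterial regulatory
genomicists who want to (a) find such an element de novo, (b) quantify how
many genes carry it and at what distance, (c) flag genes whose annotated
start codon is inconsistent with the element's position, and (d) confirm the
transcriptional signature in coverage data.

## What it computes

The pipeline chains five stages, each importable on its own:

1. **`genome_io`** — parse FASTA + GFF3/GenBank, extract coding-strand
   windows around each start codon (20 bp upstream for discovery; −300…+150
   for scanning).
2. **`motif_discovery`** — ZOOPS ("zero or one occurrence per sequence")
   expectation–maximization. Each window either contains one motif site
   (prior γ, uniform offset) or is pure background. The E-step computes the
   posterior site location per window; the M-step re-estimates the 4×w
   position probability matrix θ and γ. Restarts are seeded from the most
   over-represented w-mers; additional motifs are found after erasing the
   confidently assigned sites.
3. **`motif_scan`** — log-odds scoring, `score(word) = Σ_j log2
   θ'[word_j, j] / b[word_j]`, with **exact p-values** from the null score
   distribution computed by dynamic programming on a discretized score
   lattice (every one of the 4^w words is accounted for, to ≤1e−12). Sites
   with p ≤ 0.015 are reported, given strand only.
4. **`positional_stats` / `reannotation`** — spacer histograms (bases
   between the motif's 3′ end and the start codon), location classes
   (proximal-upstream / within-ORF / far-upstream / none), the
   motif-carrying fraction of the genome (chance-corrected, see
   `docs/methods.md`), and advisory start-codon corrections (nearest
   in-frame ATG/GTG/TTG downstream of a misplaced motif).
5. **`coverage_step`** — per-base transcript depth from an
   alignment-interval table (gapped/inverted alignments excluded), per-gene
   coding-strand profiles, and a ratio classifier for the "step increase
   right after the motif" signature of leaderless transcription:
   R = mean(60 bp after motif end) / (mean(20 bp up to motif end) + 0.5),
   step-increase if R ≥ 2.

A `synthetic` module generates genomes/annotations/coverage with planted
ground truth (GC 0.65, ~30 % of genes carrying a TACACT-consensus hexamer
6–7 bp upstream, Poisson coverage stepping from rate 1 to rate 10 at the
transcript start), so the whole chain is testable offline.

## Worked example

The numbered scripts under `analysis/` run the study on the default
synthetic genome (3000 genes, seed 0) and write tables to `results/`:

```sh
python analysis/01_simulate_genome.py
python analysis/02_discover_motifs.py
```

`02_discover_motifs.py` prints:

```
windows: 3000
consensus: TACACT  gamma: 0.258  logL: -80774.0
per-column information (bits): 2.33 2.42 0.08 0.26 0.07 2.33
top variants:
variant  count
 TACACT     63
 TACTCT     37
 TAAACT     34
```

The EM recovers the planted consensus TACACT; the information-content
profile shows the first, second and sixth positions as the near-invariant
ones (≈2.3–2.4 bits each), the hallmark of a −10 element. γ ≈ 0.26 is the
fitted prior that a window carries a site.

```sh
python analysis/03_scan_positional_stats.py
```

```
passing sites: 20671 across 3000 genes
spacer mode: 7 bp
corrected motif-carrying fraction: 0.288 (planted 0.312)
location classes: {'proximal-upstream': 835, 'far-upstream': 1397, 'within-ORF': 766, 'none': 2}
```

The spacer histogram peaks at 6–7 bp, and the chance-corrected fraction of
motif-carrying genes (0.288) recovers the planted prevalence. Location
classes are driven by each gene's single best site; with a permissive
p ≤ 0.015 threshold over a 450-bp window most genes have *some* passing
site somewhere, which is exactly why the fraction estimate subtracts the
analytically computed chance rate.

`04_reannotate.py` reports 60/60 planted intra-ORF cases corrected in frame
(and zero proposals once the corrections are applied), and
`05_coverage_trends.py` reports the step classifier at sensitivity 1.000 /
specificity 1.000 with the mean trend curve's sharpest rise 1 nt after the
motif's last base.

The same stages are available as a CLI for real genomes:

```sh
leaderless-scan extract --genome g.fna --gff g.gff3 --length 20 --out up20.fa
leaderless-scan discover --windows up20.fa -w 6 --nmotifs 2 --out motif.meme.txt
leaderless-scan scan --motif motif.meme.txt --windows up300_150.fa --thresh 0.015 --out sites.tsv
```

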