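# Methods

## The model

The object of study is a promoter −10 element that sits unusually close to
the start codon — so close that transcription initiating just downstream of
it yields a leaderless mRNA with no 5′-UTR. Three quantities characterize
it per genome: the motif itself (a width-6 position probability matrix, PPM),
its spacer distribution (bases strictly between the motif's last base and
the first base of the start codon; a site ending immediately before the ATG
has spacer 0), and the fraction of genes carrying a proximal site.

### ZOOPS mixture and EM

Each upstream window X (length L, offsets m = L − w + 1) is modeled as
either containing exactly one site at a uniformly chosen offset (prior γ)
or being pure 0-order background b:

P(X) = (1 − γ)·P_b(X) + (γ/m)·Σ_j P_b(X) · Π_k θ[x_{j+k}, k]/b[x_{j+k}]

The E-step computes the posterior over {offset 1…m, no site}; the M-step
re-estimates θ from posterior-weighted base counts plus a pseudocount of
0.01·b per column (prevents zero columns without washing out invariant
positions) and γ as the mean site posterior (γ₀ = 0.5). Iteration stops
when |ΔlogL| < 1e−6 or after 200 iterations. N bases contribute neither to
site odds nor to counts.

**Monotonicity safeguard.** Because the M-step maximizes the *penalized*
objective (the pseudocount acts as a Dirichlet prior), the raw
observed-data log likelihood is not strictly guaranteed to ascend; near a
boundary fixed point it can drift down by ~1e−6 per iteration while the
penalized objective still rises (observed in ~1 % of runs, with zero
later gain). An update that lowers the observed log likelihood is therefore
rejected and the EM terminates at the previous iterate; the reported
likelihood trace is non-decreasing by construction.

**Seeding and determinism.** Restarts start from the n_seeds (default 50)
w-mers most over-represented against the background (count divided by the
word's background probability; ties broken lexicographically), each
converted to a θ with 0.85 on the matching base and 0.05 elsewhere. The
highest-likelihood fit wins. The procedure has no RNG, so discovery is
fully deterministic for a given window set. Additional motifs are found
sequentially after masking (to N) the MAP site in every window with site
posterior > 0.5 — a simple, testable stand-in for the erasing heuristics of
classical motif discoverers. Model ranking is by training log likelihood;
E-value-style significance machinery is out of scope.

### Exact p-values and scanning

Scores are log2 odds of the pseudocount-smoothed PPM
(θ' = (θ + 0.001)/renorm) against a 0-order background, discretized to a
lattice with granularity 1e−3 bits. The null distribution of a random
background w-mer's score is built by convolving the per-column score
distributions on that lattice; the survival function is exact (it matches
brute-force enumeration of all 4^w words to ≤1e−12, which the test suite
verifies). A scanned word's p-value is the survival probability of its
discretized score; sites with p ≤ 0.015 are reported. Scanning is
single-strand (promoters are strand-specific); a reverse-complement mode
exists but is off by default. Words containing N are skipped — there is no
background model for N.

The scan background is estimated from the scanned corpus (the −300…+150
windows), not from the 20-bp discovery windows: the discovery windows are
motif-enriched, and a background contaminated by the signal miscalibrates
the null against the text actually scanned.

### Positional statistics and the fraction estimator

Per gene the minimum-p site is the *best site* (p ties broken toward the
most 3′ site, since the biological question concerns the proximal element).
Location classes, spacer histograms and variant tables are best-site based.
Class boundaries: spacer within [0, 20] → proximal-upstream (20 mirrors the
discovery window), site starting at/after the start codon → within-ORF,
spacer > 50 → far-upstream, anything else (e.g. straddling the start
codon) → proximal. Every gene receives exactly one class.

The headline *motif-carrying fraction* is **not** the best-site share. At
p ≤ 0.015 over a 445-offset window, background text alone yields ~6.7
passing sites per gene, and the genome-wide minimum p of those chance hits
is comparable to a typical true site's p; the best-site share therefore
under-counts carriers by ~40 % (the true site loses the ranking) while any
"≥1 site in the proximal band" count over-counts (chance hits land in the
band too). The estimator used is the chance-corrected detection rate:

    f̂ = (f_obs − f₀) / (1 − f₀)

where f_obs is the share of genes with at least one passing site whose
spacer lies in [0, 20], and f₀ is the probability of that event under the
null — computed *exactly* by a transfer-matrix dynamic program over the
score lattice (state = last w−1 bases of the null text), which accounts for
the correlation between overlapping w-mers that the naive 1 − (1 − u)^B
bound ignores. The null text composition is taken from the far-upstream
control slice (positions ≤ −100) of the same windows, a region with no
proximal promoter signal. On synthetic genomes with 30 % planted carriers,
f̂ recovers 0.27–0.30 at n = 3000; the residual downward bias (~0.015) is a
genuine detection floor — roughly 5 % of sites sampled from the planted PPM
mutate one of the three near-invariant positions and fall below the scan
threshold, and no threshold-based scan can count them.

### Start-codon reannotation

A best site inside the annotated ORF (or far upstream) suggests the
annotation missed the true, more downstream start of a leaderless gene. The
coding strand is scanned from one base past the motif's 3′ end up to 15
bases further (covering "immediately adjacent" through the modal 6–7-bp
spacer with margin) for ATG/GTG/TTG; the nearest candidate *in frame with
the annotated ORF* is proposed, otherwise the nearest candidate is reported
but flagged out-of-frame (frame shifts more plausibly indicate sequencing
error than a real alternative start, and flagged proposals are never
applied). Proposals shortening the ORF below 30 nt are suppressed.
Proposals are advisory output; applying the in-frame ones and re-running
produces no further proposals (idempotence, covered by tests).

### Coverage and the step classifier

Coverage is consumed as an alignment-interval table (or bedGraph);
intervals flagged as gapped or inverted are excluded and counted, mirroring
the quality filter applied to local-alignment results. Depth is unstranded.
Total retained interval length always equals total depth mass (exact
bookkeeping, tested). Per-gene profiles are coding-strand oriented over the
ORF ± 100 bp; a zoom accessor exposes the −20…+60 slice used in per-gene
bar charts.

The trend statistic compares the mean depth of the 20 bases ending at the
motif's last base with the 60 bases after it:
R = down/(up + ε), ε = 0.5 guarding division by zero. Classes:
low-coverage if the downstream mean is below 1.0, step-increase if R ≥ 2,
decrease if R ≤ 0.5, else flat. The thresholds (τ = 2, min_cov = 1.0) are
explicit, configurable choices of this package rather than community
standards, and raising τ can only shrink the step-increase count (tested). The aggregate
view normalizes each profile by its own mean (zero-mean profiles excluded)
and averages over motif-anchored coordinates.

## The synthetic data generator

`SyntheticSpec` defaults define the study conditions: 3000 alternating-
strand genes of 300–900 nt separated by 60–160 nt intergenic gaps on a
GC-0.65 contig; 30 % of genes receive a hexamer sampled from the planted
PPM (T/A/T at 0.97 in columns 1/2/6; C/A/C favored at 0.4 vs 0.2 in columns
3–5) ending 6 or 7 bases (equiprobable) before the start codon; start
codons sampled ATG/GTG/TTG at 0.8/0.15/0.05. Motif-carrying genes are
leaderless; half the remainder are leadered (transcript starting 80 bp
upstream), the rest unexpressed.

Coverage is drawn per base as independent Poisson counts from a genome-wide
rate track (rate 1 on flanks and unexpressed genes, 10 from the transcript
start through the ORF; overlapping transcription units add) and then
decomposed *exactly* into stacked intervals (open one interval per unit
rise, close one per unit fall), so the interval table reproduces the depth
base for base and the exclusion filter can be exercised with decoy
gapped/inverted intervals (5 % of the table by default). An earlier design
that synthesized fixed-length 100-bp fragments was discarded: fragment-
induced base-to-base correlation leaves a 20-base window with only ~2–3
effective observations, which is a property of read length, not of the
transcription signal the classifier is meant to detect.

What the generator does **not** emulate: operonic structure and
co-transcription, sequence composition heterogeneity (codon bias, repeats),
strand-specific coverage, library-size variation, positive correlation of
coverage noise, and partial/soft transcript starts. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not performance on real transcriptomes — on real data the step
classifier in particular inherits whatever correlation structure the read
mapper produces.

Benchmark geometries: the classifier benchmark spaces genes 220–320 nt
apart so that a leadered neighbor's transcript (starting 80 bp upstream of
its ORF) cannot reach into the profiled windows; with the dense default
spacing ~16 % of leaderless genes have a neighbor's transcript inside their
upstream window and the measurement becomes one of transcription-unit
overlap rather than of the classifier. The per-gene rate-recovery check
similarly uses 900–1000 nt gaps to isolate genes.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; reports are 1-based
  inclusive, with start-codon-relative positions written without a zero
  (+1 = first base of the start codon, −1 = the base before it).
- Genes whose window would cross a contig edge are dropped and counted, as
  are windows that are mostly N; non-ACGT IUPAC codes map to N on load.
  Pseudogenes are excluded; CDS features shorter than 3 nt are skipped with
  a warning.
- Upstream windows are extracted regardless of overlap with neighboring
  genes.
- The p-value lattice refuses to build beyond 1e8 cells and advises a
  coarser granularity; sequences shorter than the motif scan to an empty
  result rather than an error.
- Seed ranking ties break lexicographically; spacer-histogram mode ties
  break toward the smaller spacer; best-site p ties break toward the most
  3′ site.
- A genome counts as "motif-carrying" in cross-genome aggregation when its
  ORF-level fraction reaches 0.1 — comfortably above chance, comfortably
  below any real prevalence of interest.

## Known limitations

- The fraction estimator's ~0.015 downward bias (sites below the scan
  threshold) is irreducible at the fixed p ≤ 0.015 operating point.
- Discovery assumes a fixed motif width and at most one site per window;
  gapped or variable-width motifs and multi-site windows are out of scope.
- The 0-order background understates the null rate of low-complexity or
  periodic text; on such genomes the chance correction would need a
  higher-order transfer matrix (the DP generalizes, but only order 0 is
  implemented).
- Reannotation proposals are advisory: no protein-level or homology
  evidence is consulted.
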