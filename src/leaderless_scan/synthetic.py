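"""Synthetic genomes, annotations and coverage with planted ground truth.

The generator emulates the statistical structure of a high-GC
Deinococcus-Thermus-like genome in which a -10-like promoter hexamer
(consensus TACACT) sits a few bases upstream of roughly 30% of ORFs and
marks leaderless transcription:

* GC-rich background sequence (default GC 0.65) with alternating-strand
  single-exon genes separated by short intergenic gaps;
* a planted PWM-sampled hexamer ending ``spacer`` bases (default 6 or 7,
  equiprobable) before the start codon in a configurable fraction of genes;
* per-base Poisson coverage built from local-alignment-style intervals,
  with a sharp step from lambda_low to lambda_high at the motif's 3' end
  for leaderless genes, at a fixed upstream promoter position for leadered
  genes, and no step for unexpressed genes; a configurable fraction of
  intervals is flagged gapped/inverted to exercise the exclusion filter.

Every planted feature is recorded in a truth table so downstream stages can
be scored against known ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp
from .coverage_step import AlignmentInterval, CoverageTrack, depth_from_alignments, write_bedgraph, write_intervals_tsv
from .genome_io import Contig, GeneRecord, read_start_codon_raw


def default_planted_pwm() -> np.ndarray:
    """TACACT-consensus PWM: near-invariant T/A/T at columns 1, 2 and 6,
    weakly informative C/A/C preferences at columns 3-5."""
    pwm = np.zeros((4, 6))
    strong = 0.97
    weak_other = (1.0 - strong) / 3.0
    for j, base in ((0, "T"), (1, "A"), (5, "T")):
        pwm[:, j] = weak_other
        pwm["ACGT".index(base), j] = strong
    for j, base in ((2, "C"), (3, "A"), (4, "C")):
        pwm[:, j] = 0.2
        pwm["ACGT".index(base), j] = 0.4
    return pwm


@dataclass
class SyntheticSpec:
    """Parameters of the generated study conditions."""

    n_genes: int = 3000
    gene_length_range: tuple[int, int] = (300, 900)
    intergenic_length_range: tuple[int, int] = (60, 160)
    gc_content: float = 0.65
    planted_pwm: np.ndarray = field(default_factory=default_planted_pwm)
    planted_fraction: float = 0.30
    spacer_distribution: dict[int, float] = field(default_factory=lambda: {6: 0.5, 7: 0.5})
    lambda_low: float = 1.0
    lambda_high: float = 10.0
    leadered_promoter_offset: int = -80
    leadered_fraction: float = 0.5  # of non-motif genes; the rest are unexpressed
    read_length: int = 100
    gap_fraction: float = 0.05  # of emitted intervals flagged gapped/inverted
    coverage_flank: int = 400
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if any(s < 0 for s in self.spacer_distribution):
            raise ValueError("spacers must be non-negative")
        pwm = np.asarray(self.planted_pwm, dtype=float)
        if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("planted PWM columns must be stochastic")
        self.planted_pwm = pwm
        if self.intergenic_length_range[0] < max(self.spacer_distribution, default=0) + pwm.shape[1]:
            raise ValueError("intergenic gaps too short to hold a planted site")


_START_CODONS = ("ATG", "GTG", "TTG")
_START_PROBS = (0.8, 0.15, 0.05)
_STOP_CODONS = ("TAA", "TAG", "TGA")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=probs)


def _bases_to_str(codes: np.ndarray) -> str:
    return "".join("ACGT"[c] for c in codes)


def gen_genome(spec: SyntheticSpec) -> tuple[list[Contig], list[GeneRecord], pd.DataFrame]:
    """One synthetic contig with alternating-strand CDSs and planted motifs.

    Deterministic under ``spec.rng_seed``. The truth table records, per
    gene: strand, coordinates, motif presence, the sampled motif word and
    its forward-strand position, the spacer, the expression class, and the
    coding-strand-relative position of the coverage step.
    """
    rng = np.random.default_rng(spec.rng_seed)
    w = spec.planted_pwm.shape[1]
    spacers = sorted(spec.spacer_distribution)
    spacer_p = np.array([spec.spacer_distribution[s] for s in spacers], dtype=float)
    spacer_p = spacer_p / spacer_p.sum()

    pieces: list[str] = []
    pos = 0
    genes: list[GeneRecord] = []
    rows = []

    # leading gap long enough that gene 1 keeps its upstream windows
    lead = int(rng.integers(*spec.intergenic_length_range)) + 400
    pieces.append(_bases_to_str(_random_bases(rng, lead, spec.gc_content)))
    pos += lead

    for i in range(spec.n_genes):
        strand = "+" if i % 2 == 0 else "-"
        glen = int(rng.integers(spec.gene_length_range[0], spec.gene_length_range[1] + 1))
        glen -= glen % 3  # whole codons
        has_motif = bool(rng.random() < spec.planted_fraction)
        spacer = int(rng.choice(spacers, p=spacer_p)) if has_motif else -1
        word = ""
        if has_motif:
            word = "".join(
                "ACGT"[rng.choice(4, p=spec.planted_pwm[:, j])] for j in range(w)
            )

        start_codon = _START_CODONS[rng.choice(3, p=_START_PROBS)]
        stop_codon = _STOP_CODONS[rng.integers(3)]
        body = _bases_to_str(_random_bases(rng, glen - 6, spec.gc_content))
        coding = start_codon + body + stop_codon

        if strand == "+":
            # motif sits at the end of the gap just emitted
            if has_motif:
                gap = pieces[-1]
                insert_at = len(gap) - spacer - w
                pieces[-1] = gap[:insert_at] + word + gap[insert_at + w :]
                motif_fwd_start = pos - spacer - w
            else:
                motif_fwd_start = -1
            gstart, gend = pos, pos + glen
            pieces.append(coding)
            pos += glen
        else:
            gstart, gend = pos, pos + glen
            pieces.append(revcomp(coding))
            pos += glen
            motif_fwd_start = -1  # written into the next gap below

        gap_len = int(rng.integers(*spec.intergenic_length_range))
        gap = _bases_to_str(_random_bases(rng, gap_len, spec.gc_content))
        if strand == "-" and has_motif:
            # upstream of a minus gene lies to its right on the forward strand
            gap = gap[:spacer] + revcomp(word) + gap[spacer + w :]
            motif_fwd_start = pos + spacer
        pieces.append(gap)
        pos += gap_len

        if has_motif:
            expr = "leaderless"
            step_rel = -spacer  # first elevated base, coding-strand-relative
        elif rng.random() < spec.leadered_fraction:
            expr = "leadered"
            step_rel = spec.leadered_promoter_offset
        else:
            expr = "unexpressed"
            step_rel = None

        rows.append(
            {
                "gene_id": f"gene_{i:05d}",
                "strand": strand,
                "start": gstart,
                "end": gend,
                "has_motif": has_motif,
                "motif_word": word,
                "motif_fwd_start": motif_fwd_start,
                "spacer": spacer,
                "is_leaderless": has_motif,
                "expression_class": expr,
                "coverage_step_position": np.nan if step_rel is None else step_rel,
            }
        )

    # trailing gap so the last minus-strand gene keeps its upstream window
    tail = 400
    pieces.append(_bases_to_str(_random_bases(rng, tail, spec.gc_content)))

    seq = "".join(pieces)
    contig = Contig("synth_1", seq)
    for row in rows:
        genes.append(
            GeneRecord(
                row["gene_id"], "synth_1", row["strand"], row["start"], row["end"],
                read_start_codon_raw(row["strand"], row["start"], row["end"], seq),
            )
        )
    truth = pd.DataFrame(rows)
    return [contig], genes, truth


def _skyline_intervals(depth: np.ndarray) -> list[tuple[int, int]]:
    """Decompose a non-negative integer depth array into stacked intervals.

    Opens an interval at every unit rise and closes the most recent one at
    every unit fall, so the intervals exactly reproduce the depth when
    stacked (total length equals total depth mass).
    """
    out: list[tuple[int, int]] = []
    open_starts: list[int] = []
    d = np.concatenate([[0], depth, [0]])
    delta = np.diff(d)
    for x in np.flatnonzero(delta):
        step = int(delta[x])
        if step > 0:
            open_starts.extend([int(x)] * step)
        else:
            for _ in range(-step):
                out.append((open_starts.pop(), int(x)))
    return out


def gen_coverage(
    spec: SyntheticSpec,
    truth: pd.DataFrame,
    genes: list[GeneRecord],
    contigs: list[Contig],
    rng: np.random.Generator | None = None,
) -> tuple[list[AlignmentInterval], CoverageTrack]:
    """Alignment intervals (plus the resulting retained-depth track).

    Per-base depth is drawn as independent Poisson counts from a genome-wide
    rate track: each gene contributes lambda_low over its flanks and ORF,
    raised to lambda_high from the step position through the ORF's end for
    leaderless and leadered genes (overlapping transcription units add).
    The depth is then decomposed exactly into alignment-style intervals, so
    stacking the retained intervals reproduces the depth base for base.
    Flagged (gapped/inverted) decoy intervals are appended at
    ``gap_fraction`` of the emitted total.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed + 1)
    contig_len = len(contigs[0].seq)
    by_id = {g.gene_id: g for g in genes}
    rate = np.zeros(contig_len)
    for row in truth.itertuples(index=False):
        gene = by_id[row.gene_id]
        glen = gene.end - gene.start
        fl = spec.coverage_flank

        def fwd(rel_lo: int, rel_hi: int) -> tuple[int, int]:
            if gene.strand == "+":
                lo, hi = gene.start + rel_lo, gene.start + rel_hi
            else:
                lo, hi = gene.end - rel_hi, gene.end - rel_lo
            return max(lo, 0), min(hi, contig_len)

        segments: list[tuple[int, int, float]] = []  # rel_lo, rel_hi, lambda
        if row.expression_class == "unexpressed":
            segments.append((-fl, glen + fl, spec.lambda_low))
        else:
            step = int(row.coverage_step_position)
            segments.append((-fl, step, spec.lambda_low))
            segments.append((step, glen, spec.lambda_high))
            segments.append((glen, glen + fl, spec.lambda_low))
        for rel_lo, rel_hi, lam in segments:
            a, b = fwd(rel_lo, rel_hi)
            if b > a:
                rate[a:b] += lam

    depth = rng.poisson(rate)
    clean = [AlignmentInterval(contigs[0].name, s, e) for s, e in _skyline_intervals(depth)]
    n_flagged = int(round(spec.gap_fraction / (1.0 - spec.gap_fraction) * len(clean))) if spec.gap_fraction > 0 else 0
    flagged = []
    for _ in range(n_flagged):
        s = int(rng.integers(0, contig_len - spec.read_length))
        gap = bool(rng.random() < 0.5)
        flagged.append(
            AlignmentInterval(
                contigs[0].name, s, s + spec.read_length, has_gap=gap, is_inverted=not gap
            )
        )
    all_intervals = clean + flagged
    track, _counts = depth_from_alignments(all_intervals, contigs)
    return all_intervals, track


def end_to_end_fixture(spec: SyntheticSpec, outdir: str) -> dict[str, str]:
    """Write genome FASTA, GFF3, truth TSV, interval TSV and bedGraph to a directory."""
    os.makedirs(outdir, exist_ok=True)
    contigs, genes, truth = gen_genome(spec)
    intervals, track = gen_coverage(spec, truth, genes, contigs)

    paths = {
        "fasta": os.path.join(outdir, "genome.fna"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "intervals": os.path.join(outdir, "alignments.tsv"),
        "bedgraph": os.path.join(outdir, "coverage.bedgraph"),
    }
    with open(paths["fasta"], "w") as fh:
        for c in contigs:
            fh.write(f">{c.name}\n")
            for i in range(0, len(c.seq), 70):
                fh.write(c.seq[i : i + 70] + "\n")
    write_gff3(genes, paths["gff3"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    write_intervals_tsv(intervals, paths["intervals"])
    write_bedgraph(track, paths["bedgraph"])
    return paths


def gen_reannotation_cases(
    n_genes: int = 60, seed: int = 0, max_spacer: int = 15
) -> tuple[list[Contig], list[GeneRecord], list, dict]:
    """Genes with an intra-ORF promoter hexamer and a planted in-frame start.

    Each gene carries the motif at a known offset inside the annotated ORF,
    followed after ``d`` all-C filler bases by an in-frame ATG or GTG (the
    filler guarantees the planted codon is the nearest in-frame initiator).
    Returns contigs, genes, the per-gene motif sites, and a map
    gene_id -> (planted genomic start, planted codon) for scoring proposals.
    """
    from .motif_scan import MotifSite

    rng = np.random.default_rng(seed)
    pieces = ["C" * 50]
    pos = 50
    genes: list[GeneRecord] = []
    sites = []
    expected: dict[str, tuple[int, str]] = {}
    for i in range(n_genes):
        strand = "+" if i % 2 == 0 else "-"
        o = int(rng.choice([3, 7, 12, 18]))  # motif start inside the ORF
        frame_offset = (-(o + 6)) % 3
        d_options = [d for d in range(frame_offset, max_spacer + 1, 3)]
        d = int(rng.choice(d_options))
        rel = o + 6 + d
        codon = "ATG" if rng.random() < 0.5 else "GTG"
        tail_len = 90  # well above the 30-nt minimum for the corrected ORF
        tail = _bases_to_str(_random_bases(rng, tail_len - 3, 0.65)) + "TAA"
        coding = "ATG" + "C" * (o - 3) + "TACACT" + "C" * d + codon + tail
        glen = len(coding)
        gstart, gend = pos, pos + glen
        pieces.append(coding if strand == "+" else revcomp(coding))
        pos += glen
        pieces.append("C" * 50)
        pos += 50

        gene_id = f"reanno_{i:03d}"
        genes.append(
            GeneRecord(gene_id, "reanno_1", strand, gstart, gend, "ATG")
        )
        sites.append(
            MotifSite(gene_id, offset=o, word="TACACT", score=10.0,
                      p_value=1e-4, spacer=-(o + 6))
        )
        planted = gstart + rel if strand == "+" else gend - 1 - rel
        expected[gene_id] = (planted, codon)
    contigs = [Contig("reanno_1", "".join(pieces))]
    return contigs, genes, sites, expected


def shift_sites_to_new_starts(sites, old_genes, new_genes):
    """Re-express motif sites relative to updated start-codon positions."""
    from .motif_scan import MotifSite

    old_by_id = {g.gene_id: g for g in old_genes}
    new_by_id = {g.gene_id: g for g in new_genes}
    out = []
    for s in sites:
        old, new = old_by_id[s.gene_id], new_by_id[s.gene_id]
        if old.strand == "+":
            shift = new.start - old.start
        else:
            shift = old.end - new.end
        offset = s.offset - shift
        out.append(
            MotifSite(s.gene_id, offset, s.word, s.score, s.p_value,
                      spacer=-(offset + len(s.word)))
        )
    return out


def write_gff3(genes: list[GeneRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tsynth\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id};locus_tag={g.gene_id}\n"
            )
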