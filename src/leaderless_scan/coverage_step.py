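"""Per-nucleotide transcript coverage and the post-motif step signature.

Coverage is consumed as a table of alignment intervals (local alignments of
transcriptome reads against the genome); intervals flagged as gapped or
inverted are excluded, mirroring the filtering applied to local-alignment
results. Depth is unstranded. For each gene, a coding-strand-oriented depth
profile over the ORF plus flanks is cut out, and a simple ratio statistic
around the motif's 3' end classifies the gene's transcriptional trend:
leaderless transcription shows a step increase in depth immediately after
the promoter element.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import Contig, GeneRecord

log = logging.getLogger(__name__)

TREND_CLASSES = ("step-increase", "flat", "decrease", "low-coverage")
EPSILON = 0.5  # ratio-denominator guard


@dataclass(frozen=True)
class AlignmentInterval:
    contig: str
    start: int  # 0-based half-open, forward strand
    end: int
    has_gap: bool = False
    is_inverted: bool = False

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("interval start must precede end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Per-contig integer read depth, one array entry per base."""

    depth: dict[str, np.ndarray]

    def total_depth(self) -> int:
        return int(sum(arr.sum() for arr in self.depth.values()))


@dataclass
class GeneProfile:
    """Coding-strand depth over positions -flank .. gene_length+flank-1."""

    gene_id: str
    depth: np.ndarray
    flank: int

    def at(self, rel: int) -> float:
        return float(self.depth[rel + self.flank])

    def zoom(self, lo: int = -20, hi: int = 60) -> np.ndarray:
        """The -20..+60 slice shown in per-gene bar charts."""
        return self.depth[lo + self.flank : hi + self.flank]


@dataclass(frozen=True)
class TrendCall:
    gene_id: str
    upstream_mean: float
    downstream_mean: float
    ratio: float
    trend: str  # one of TREND_CLASSES


@dataclass
class FilterCounts:
    kept: int = 0
    gapped: int = 0
    inverted: int = 0

    @property
    def excluded(self) -> int:
        return self.gapped + self.inverted


def depth_from_alignments(
    intervals: Sequence[AlignmentInterval],
    contigs: Sequence[Contig],
) -> tuple[CoverageTrack, FilterCounts]:
    """Stack retained intervals into a per-base depth track.

    Gapped or inverted intervals contribute nothing and are counted; an
    interval outside its contig raises.
    """
    lengths = {c.name: len(c.seq) for c in contigs}
    diffs = {name: np.zeros(n + 1, dtype=np.int64) for name, n in lengths.items()}
    counts = FilterCounts()
    for iv in intervals:
        if iv.contig not in lengths:
            raise ValueError(f"interval on unknown contig {iv.contig!r}")
        if iv.start < 0 or iv.end > lengths[iv.contig]:
            raise ValueError(f"interval [{iv.start},{iv.end}) beyond contig {iv.contig!r}")
        if iv.has_gap:
            counts.gapped += 1
            continue
        if iv.is_inverted:
            counts.inverted += 1
            continue
        counts.kept += 1
        diffs[iv.contig][iv.start] += 1
        diffs[iv.contig][iv.end] -= 1
    track = CoverageTrack({name: np.cumsum(d[:-1]) for name, d in diffs.items()})
    if counts.excluded:
        log.info(
            "depth_from_alignments: kept %d intervals, excluded %d gapped + %d inverted",
            counts.kept, counts.gapped, counts.inverted,
        )
    return track, counts


def read_intervals_tsv(path: str) -> list[AlignmentInterval]:
    df = pd.read_csv(path, sep="\t")
    return [
        AlignmentInterval(
            str(r.contig), int(r.start), int(r.end), bool(r.gap_flag), bool(r.inverted_flag)
        )
        for r in df.itertuples(index=False)
    ]


def write_intervals_tsv(intervals: Sequence[AlignmentInterval], path: str) -> None:
    pd.DataFrame(
        [
            {
                "contig": iv.contig,
                "start": iv.start,
                "end": iv.end,
                "gap_flag": int(iv.has_gap),
                "inverted_flag": int(iv.is_inverted),
            }
            for iv in intervals
        ],
        columns=["contig", "start", "end", "gap_flag", "inverted_flag"],
    ).to_csv(path, sep="\t", index=False)


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """Run-length encoded depth; zero-depth runs are omitted as is conventional."""
    with open(path, "w") as fh:
        for name in sorted(track.depth):
            arr = track.depth[name]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = int(arr[s])
                if v != 0:
                    fh.write(f"{name}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path: str, contig_lengths: dict[str, int]) -> CoverageTrack:
    depth = {name: np.zeros(n, dtype=np.int64) for name, n in contig_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            try:
                name, s, e, v = line.split()[:4]
                depth[name][int(s) : int(e)] = int(float(v))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"malformed bedGraph line {lineno}: {line!r}") from exc
    return CoverageTrack(depth)


def region_selection(
    gene: GeneRecord, contigs: Sequence[Contig], up: int = 400, down: int = 400
) -> tuple[str, int, int] | None:
    """Forward-strand interval covering the ORF plus up/down coding-strand flanks.

    Returns None (with a log entry) for genes too close to a contig edge.
    """
    lengths = {c.name: len(c.seq) for c in contigs}
    if gene.strand == "+":
        lo, hi = gene.start - up, gene.end + down
    else:
        lo, hi = gene.start - down, gene.end + up
    if lo < 0 or hi > lengths[gene.contig]:
        log.warning("region for %s truncated by contig edge; dropped", gene.gene_id)
        return None
    return gene.contig, lo, hi


def gene_profile(
    track: CoverageTrack, gene: GeneRecord, flank: int = 100
) -> GeneProfile | None:
    """Coding-strand-oriented depth over the ORF with ``flank`` bases each side."""
    arr = track.depth[gene.contig]
    lo, hi = gene.start - flank, gene.end + flank
    if lo < 0 or hi > len(arr):
        log.warning("profile for %s runs off the contig; dropped", gene.gene_id)
        return None
    window = arr[lo:hi].astype(float)
    if gene.strand == "-":
        window = window[::-1]
    return GeneProfile(gene.gene_id, window, flank)


def step_statistic(
    profile: GeneProfile,
    motif_end_rel: int,
    up_window: int = 20,
    down_window: int = 60,
    tau: float = 2.0,
    min_cov: float = 1.0,
) -> TrendCall:
    """Classify the depth trend around a motif's 3' end.

    ``motif_end_rel`` is the coding-strand position of the motif's last base
    relative to the start codon (e.g. -7 for a spacer of 6). The upstream
    mean is taken over the ``up_window`` bases ending at that position and
    the downstream mean over the ``down_window`` bases after it; the ratio
    R = down/(up + eps) yields step-increase (R >= tau), decrease
    (R <= 1/tau), flat, or low-coverage (downstream mean below ``min_cov``).
    """
    idx = motif_end_rel + profile.flank
    lo = idx - up_window + 1
    hi = idx + 1 + down_window
    if lo < 0 or hi > len(profile.depth):
        raise ValueError(f"trend windows leave the profiled span for {profile.gene_id}")
    up_mean = float(profile.depth[lo : idx + 1].mean())
    down_mean = float(profile.depth[idx + 1 : hi].mean())
    ratio = down_mean / (up_mean + EPSILON)
    if down_mean < min_cov:
        trend = "low-coverage"
    elif ratio >= tau:
        trend = "step-increase"
    elif ratio <= 1.0 / tau:
        trend = "decrease"
    else:
        trend = "flat"
    return TrendCall(profile.gene_id, up_mean, down_mean, ratio, trend)


def aggregate_trends(
    calls: Sequence[TrendCall],
    profiles: Sequence[GeneProfile] | None = None,
    anchors: Sequence[int] | None = None,
    curve_window: tuple[int, int] = (-50, 100),
) -> tuple[dict[str, int], pd.DataFrame | None]:
    """Class counts plus the mean motif-anchored depth curve.

    Each profile is normalized by its own mean (zero-mean profiles are
    excluded) and aligned so position 0 is the motif's last base; the
    returned frame has columns position, mean_depth.
    """
    counts = dict(Counter(c.trend for c in calls))
    for cls in TREND_CLASSES:
        counts.setdefault(cls, 0)
    curve = None
    if profiles is not None and anchors is not None:
        lo, hi = curve_window
        stack = []
        for profile, anchor in zip(profiles, anchors):
            idx = anchor + profile.flank
            if idx + lo < 0 or idx + hi > len(profile.depth):
                continue
            seg = profile.depth[idx + lo : idx + hi]
            total = profile.depth.mean()
            if total <= 0:
                continue
            stack.append(seg / total)
        if stack:
            mean_curve = np.mean(stack, axis=0)
            curve = pd.DataFrame(
                {"position": np.arange(lo, hi), "mean_depth": mean_curve}
            )
    return counts, curve
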