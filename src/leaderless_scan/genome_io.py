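"""Genome / annotation parsing and upstream-window extraction.

The downstream motif stages all operate on short windows taken 5'->3' on the
coding strand of each annotated CDS: a 20-bp window immediately upstream of
the start codon for de novo discovery, and a wider window (300 bp upstream
through 150 bp into the ORF by default) for PWM scanning.

Coordinates are 0-based half-open on the forward strand internally;
human-readable reports convert to 1-based inclusive.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO

from ._seq import clean_sequence, revcomp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contig:
    """One replicon: name plus its forward-strand sequence over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self):
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.name!r} is empty")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated ORF (CDS feature), forward-strand half-open coordinates."""

    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    start: int
    end: int
    start_codon: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad coordinates for {self.gene_id}")
        if self.end - self.start < 3:
            raise ValueError(f"CDS shorter than 3 nt: {self.gene_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class UpstreamWindow:
    """A coding-strand window near a gene's start codon.

    ``offset_of_last_base`` is the position of the window's final base
    relative to the first base of the start codon (position 0); -1 means the
    window ends immediately 5' of the start codon.
    """

    gene_id: str
    seq: str
    offset_of_last_base: int

    @property
    def offset_of_first_base(self) -> int:
        return self.offset_of_last_base - len(self.seq) + 1


def _coding_slice(gene: GeneRecord, contig_seq: str, rel_start: int, rel_end: int) -> str | None:
    """Coding-strand bases at start-codon-relative positions [rel_start, rel_end).

    Returns None when the interval leaves the contig.
    """
    if gene.strand == "+":
        lo = gene.start + rel_start
        hi = gene.start + rel_end
        if lo < 0 or hi > len(contig_seq):
            return None
        return contig_seq[lo:hi]
    # minus strand: coding position p sits at forward coordinate end-1-p
    lo = gene.end - rel_end
    hi = gene.end - rel_start
    if lo < 0 or hi > len(contig_seq):
        return None
    return revcomp(contig_seq[lo:hi])


def read_start_codon(gene_like, contig_seq: str) -> str:
    """First codon of the coding-strand sequence of a gene."""
    if gene_like.strand == "+":
        return contig_seq[gene_like.start : gene_like.start + 3]
    return revcomp(contig_seq[gene_like.end - 3 : gene_like.end])


def _genes_from_gff3(path: str, contigs: dict[str, Contig]) -> list[GeneRecord]:
    import gffutils

    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - exercised via malformed input test
        raise ValueError(f"malformed GFF3 {path!r}: {exc}") from exc

    genes: list[GeneRecord] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if "pseudo" in feat.attributes or feat.attributes.get("pseudogene"):
            continue
        gid = (feat.attributes.get("ID") or feat.attributes.get("locus_tag") or [feat.id])[0]
        if feat.seqid not in contigs:
            raise ValueError(f"gene {gid!r} references unknown contig {feat.seqid!r}")
        start, end = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
        cseq = contigs[feat.seqid].seq
        if end > len(cseq) or start < 0:
            raise ValueError(f"gene {gid!r} outside contig bounds")
        if end - start < 3:
            log.warning("skipping CDS shorter than 3 nt: %s", gid)
            continue
        strand = feat.strand if feat.strand in "+-" else "+"
        rec = GeneRecord(gid, feat.seqid, strand, start, end,
                         read_start_codon_raw(strand, start, end, cseq))
        genes.append(rec)
    return genes


def read_start_codon_raw(strand: str, start: int, end: int, contig_seq: str) -> str:
    if strand == "+":
        return contig_seq[start : start + 3]
    return revcomp(contig_seq[end - 3 : end])


def _genes_from_genbank(path: str, contigs: dict[str, Contig]) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    for rec in SeqIO.parse(path, "genbank"):
        if rec.id not in contigs:
            raise ValueError(f"GenBank record {rec.id!r} has no matching contig")
        cseq = contigs[rec.id].seq
        for feat in rec.features:
            if feat.type != "CDS" or "pseudo" in feat.qualifiers:
                continue
            gid = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", ["?"]))[0]
            start = int(feat.location.start)
            end = int(feat.location.end)
            if end - start < 3:
                log.warning("skipping CDS shorter than 3 nt: %s", gid)
                continue
            strand = "+" if feat.location.strand != -1 else "-"
            genes.append(
                GeneRecord(gid, rec.id, strand, start, end,
                           read_start_codon_raw(strand, start, end, cseq))
            )
    return genes


def load_genome(fasta_path: str, annotation_path: str) -> tuple[list[Contig], list[GeneRecord]]:
    """Parse a genome FASTA plus a GFF3 (or GenBank) annotation.

    Returns one GeneRecord per CDS feature, coordinates normalized to 0-based
    half-open on the forward strand, with the start codon read from the
    coding strand. Non-ACGT symbols in the genome are mapped to N.
    """
    if not os.path.exists(fasta_path):
        raise FileNotFoundError(fasta_path)
    if not os.path.exists(annotation_path):
        raise FileNotFoundError(annotation_path)

    contigs: dict[str, Contig] = {}
    for rec in SeqIO.parse(fasta_path, "fasta"):
        contigs[rec.id] = Contig(rec.id, clean_sequence(str(rec.seq)))
    if not contigs:
        raise ValueError(f"no FASTA records in {fasta_path!r}")

    lower = annotation_path.lower()
    if lower.endswith((".gb", ".gbk", ".gbff", ".genbank")):
        genes = _genes_from_genbank(annotation_path, contigs)
    else:
        genes = _genes_from_gff3(annotation_path, contigs)
    return list(contigs.values()), genes


def extract_scan_window(
    genes: Sequence[GeneRecord],
    contigs: Sequence[Contig],
    up: int = 300,
    down: int = 150,
    max_n_fraction: float = 0.5,
) -> list[UpstreamWindow]:
    """Coding-strand windows spanning positions -up .. +down-1 around each start codon.

    Genes whose window would run off the contig are dropped (counted in the
    log); windows that are mostly N are likewise dropped.
    """
    if up < 0 or down < 0 or up + down < 1:
        raise ValueError("window must have positive length")
    by_name = {c.name: c for c in contigs}
    out: list[UpstreamWindow] = []
    n_edge = n_masked = 0
    for gene in genes:
        contig = by_name[gene.contig]
        seq = _coding_slice(gene, contig.seq, -up, down)
        if seq is None:
            n_edge += 1
            continue
        if seq.count("N") > max_n_fraction * len(seq):
            n_masked += 1
            continue
        out.append(UpstreamWindow(gene.gene_id, seq, offset_of_last_base=down - 1))
    if n_edge or n_masked:
        log.info(
            "extract_scan_window: %d emitted, %d dropped at contig edges, %d dropped as mostly-N",
            len(out), n_edge, n_masked,
        )
    return out


def extract_upstream(
    genes: Sequence[GeneRecord],
    contigs: Sequence[Contig],
    length: int = 20,
) -> list[UpstreamWindow]:
    """The `length` bases immediately 5' of each start codon on the coding strand."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return extract_scan_window(genes, contigs, up=length, down=0)


def write_windows_fasta(windows: Iterable[UpstreamWindow], path: str) -> None:
    """Write windows as a wrapped multi-FASTA; headers carry offset metadata."""
    seen: set[str] = set()
    with open(path, "w") as fh:
        for win in windows:
            if win.gene_id in seen:
                raise ValueError(f"duplicate gene_id {win.gene_id!r}")
            seen.add(win.gene_id)
            fh.write(f">{win.gene_id} offset_of_last_base={win.offset_of_last_base}\n")
            for i in range(0, len(win.seq), 60):
                fh.write(win.seq[i : i + 60] + "\n")


def read_windows_fasta(path: str) -> list[UpstreamWindow]:
    out: list[UpstreamWindow] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate gene_id {rec.id!r}")
        seen.add(rec.id)
        offset = -1
        for token in rec.description.split():
            if token.startswith("offset_of_last_base="):
                offset = int(token.split("=", 1)[1])
        out.append(UpstreamWindow(rec.id, clean_sequence(str(rec.seq)), offset))
    return out


def window_to_genomic(win: UpstreamWindow, gene: GeneRecord) -> tuple[int, int]:
    """Forward-strand half-open genomic interval a window was cut from."""
    first, last = win.offset_of_first_base, win.offset_of_last_base
    if gene.strand == "+":
        return gene.start + first, gene.start + last + 1
    return gene.end - last - 1, gene.end - first
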