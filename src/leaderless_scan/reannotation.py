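"""Start-codon reannotation proposals for leaderless genes.

When a gene's best -10-like site lies inside the annotated ORF or far
upstream of it, the annotated start codon is suspect: in leaderless
transcription the start codon sits just downstream of the promoter element.
This module scans the coding strand immediately 3' of such a site for a
bacterial initiator codon (ATG/GTG/TTG), preferring the nearest one that
keeps the annotated reading frame. Out-of-frame candidates are reported but
flagged, never applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_io import Contig, GeneRecord, _coding_slice
from .motif_scan import MotifSite, best_site_per_gene
from .positional_stats import classify_location

log = logging.getLogger(__name__)

START_CODONS = ("ATG", "GTG", "TTG")
MIN_ORF_NT = 30


@dataclass(frozen=True)
class StartProposal:
    gene_id: str
    original_start: int  # genomic coordinate of the annotated start codon's first base
    proposed_start: int  # genomic coordinate of the proposed codon's first base
    proposed_codon: str
    spacer_after_motif: int  # bases between motif 3' end and the proposed codon
    in_frame_with_annotation: bool
    trimmed_nterm_length: int  # codons removed from the N terminus (negative = extended)


def propose_start(
    gene: GeneRecord,
    best_site: MotifSite,
    contigs: Sequence[Contig] | dict[str, Contig],
    max_spacer: int = 15,
    codons: Iterable[str] = START_CODONS,
) -> StartProposal | None:
    """Propose a corrected start codon just downstream of a misplaced motif.

    Scans coding-strand positions from one base past the motif's 3' end up
    to ``max_spacer`` bases further for a start codon; the nearest in-frame
    candidate wins, otherwise the nearest candidate is returned with
    ``in_frame_with_annotation=False``. Returns None when no candidate
    exists or the resulting ORF would be shorter than 30 nt.
    """
    if isinstance(contigs, dict):
        by_name = contigs
    else:
        by_name = {c.name: c for c in contigs}
    contig = by_name[gene.contig]
    codons = tuple(codons)
    w = best_site.width
    motif_end_rel = best_site.offset + w - 1  # start-codon-relative, coding strand

    candidates: list[tuple[int, int, str]] = []  # (spacer, rel, codon)
    for d in range(max_spacer + 1):
        rel = motif_end_rel + 1 + d
        codon = _coding_slice(gene, contig.seq, rel, rel + 3)
        if codon is None:
            break
        if codon in codons:
            candidates.append((d, rel, codon))
    if not candidates:
        return None

    in_frame = [c for c in candidates if c[1] % 3 == 0]
    d, rel, codon = in_frame[0] if in_frame else candidates[0]

    new_length = gene.length - rel
    if new_length < MIN_ORF_NT:
        log.warning(
            "suppressing proposal for %s: corrected ORF would be %d nt", gene.gene_id, new_length
        )
        return None

    if gene.strand == "+":
        original = gene.start
        proposed = gene.start + rel
    else:
        original = gene.end - 1
        proposed = gene.end - 1 - rel

    return StartProposal(
        gene_id=gene.gene_id,
        original_start=original,
        proposed_start=proposed,
        proposed_codon=codon,
        spacer_after_motif=d,
        in_frame_with_annotation=rel % 3 == 0,
        trimmed_nterm_length=rel // 3,
    )


def propose_reannotations(
    genes: Sequence[GeneRecord],
    sites: Sequence[MotifSite],
    contigs: Sequence[Contig],
    proximal_max: int = 20,
    far_min: int = 50,
    max_spacer: int = 15,
) -> list[StartProposal]:
    """Proposals for every gene whose best site is within-ORF or far-upstream."""
    best = best_site_per_gene(list(sites))
    by_name = {c.name: c for c in contigs}
    proposals = []
    for gene in genes:
        site = best.get(gene.gene_id)
        if site is None:
            continue
        call = classify_location(site, gene, proximal_max, far_min)
        if call.location not in ("within-ORF", "far-upstream"):
            continue
        prop = propose_start(gene, site, by_name, max_spacer=max_spacer)
        if prop is not None:
            proposals.append(prop)
    return proposals


def apply_proposal(gene: GeneRecord, prop: StartProposal, contigs: Sequence[Contig]) -> GeneRecord:
    """A GeneRecord with the proposed (in-frame) start applied."""
    if not prop.in_frame_with_annotation:
        raise ValueError("refusing to apply an out-of-frame proposal")
    by_name = {c.name: c for c in contigs}
    seq = by_name[gene.contig].seq
    if gene.strand == "+":
        start, end = prop.proposed_start, gene.end
    else:
        start, end = gene.start, prop.proposed_start + 1
    from .genome_io import read_start_codon_raw

    return GeneRecord(
        gene.gene_id, gene.contig, gene.strand, start, end,
        read_start_codon_raw(gene.strand, start, end, seq),
    )


def proposals_to_table(proposals: Sequence[StartProposal]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": p.gene_id,
                "original_start": p.original_start + 1,  # 1-based for reports
                "proposed_start": p.proposed_start + 1,
                "proposed_codon": p.proposed_codon,
                "spacer_after_motif": p.spacer_after_motif,
                "in_frame_with_annotation": p.in_frame_with_annotation,
                "trimmed_nterm_length": p.trimmed_nterm_length,
            }
            for p in proposals
        ],
        columns=[
            "gene_id", "original_start", "proposed_start", "proposed_codon",
            "spacer_after_motif", "in_frame_with_annotation", "trimmed_nterm_length",
        ],
    )


def proposals_to_gff3(proposals: Sequence[StartProposal], genes: Sequence[GeneRecord], path: str) -> None:
    """GFF3 of proposed CDS features with provenance attributes."""
    by_id = {g.gene_id: g for g in genes}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in proposals:
            g = by_id[p.gene_id]
            if g.strand == "+":
                start, end = p.proposed_start, g.end
            else:
                start, end = g.start, p.proposed_start + 1
            attrs = (
                f"ID={p.gene_id}_reannotated;original_start={p.original_start + 1};"
                f"proposed_codon={p.proposed_codon};in_frame={str(p.in_frame_with_annotation).lower()}"
            )
            fh.write(
                f"{g.contig}\tleaderless-scan\tCDS\t{start + 1}\t{end}\t.\t{g.strand}\t0\t{attrs}\n"
            )
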