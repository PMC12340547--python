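"""Positional statistics over scanned motif sites.

Turns per-gene best sites into the headline numbers: the spacer-distance
histogram (how far upstream of the start codon the -10-like element sits),
location classes (proximal upstream / within the ORF / far upstream / none),
the motif-carrying fraction of a genome, and multi-genome aggregation.

Spacer convention: the number of bases strictly between the motif's last
base and the first base of the start codon, so a site ending immediately
before the ATG has spacer 0 and sites overlapping or inside the ORF have
negative spacers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .genome_io import GeneRecord
from .motif_scan import MotifSite, best_site_per_gene

LOCATION_CLASSES = ("proximal-upstream", "within-ORF", "far-upstream", "none")


@dataclass
class SpacerHistogram:
    counts: dict[int, int]
    mode: int | None
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counts.items()), columns=["spacer", "count"]
        )


@dataclass(frozen=True)
class LocationCall:
    gene_id: str
    location: str  # one of LOCATION_CLASSES


@dataclass
class GenomeSummary:
    genome_id: str
    n_genes: int
    n_motif_genes: int
    fraction: float
    top_variants: pd.DataFrame = field(repr=False, default=None)
    spacer_mode: int | None = None


def spacer_distribution(sites: list[MotifSite]) -> SpacerHistogram:
    """Histogram of best-site spacers; mode ties resolve to the smaller spacer."""
    best = best_site_per_gene(sites)
    counts = Counter(site.spacer for site in best.values())
    mode = None
    if counts:
        mode = min(counts, key=lambda s: (-counts[s], s))
    return SpacerHistogram(dict(counts), mode, sum(counts.values()))


def classify_location(
    site: MotifSite | None,
    gene: GeneRecord,
    proximal_max: int = 20,
    far_min: int = 50,
) -> LocationCall:
    """Assign a gene's best site to one location class.

    proximal-upstream: spacer within [0, proximal_max]; within-ORF: site
    starting at/after the start codon; far-upstream: spacer beyond far_min;
    anything else (including sites straddling the start codon) is treated as
    proximal.
    """
    gene_id = gene.gene_id if gene is not None else site.gene_id
    if site is None:
        return LocationCall(gene_id, "none")
    if 0 <= site.spacer <= proximal_max:
        return LocationCall(gene_id, "proximal-upstream")
    if site.offset >= 0:
        return LocationCall(gene_id, "within-ORF")
    if site.spacer > far_min:
        return LocationCall(gene_id, "far-upstream")
    return LocationCall(gene_id, "proximal-upstream")


def classify_all(
    genes: list[GeneRecord],
    sites: list[MotifSite],
    proximal_max: int = 20,
    far_min: int = 50,
) -> list[LocationCall]:
    best = best_site_per_gene(sites)
    return [
        classify_location(best.get(g.gene_id), g, proximal_max, far_min) for g in genes
    ]


def motif_fraction(
    genes: list[GeneRecord],
    sites: list[MotifSite],
    band: tuple[int, int] = (0, 20),
    genome_id: str = "genome",
) -> GenomeSummary:
    """Fraction of genes whose best site's spacer falls within ``band``.

    Uses the best-site-per-gene view; variant counts and the spacer mode of
    the counted sites are attached for reporting.
    """
    lo, hi = band
    best = best_site_per_gene(sites)
    gene_ids = {g.gene_id for g in genes}
    carriers = {
        gid: site
        for gid, site in best.items()
        if gid in gene_ids and lo <= site.spacer <= hi
    }
    variant_counts = Counter(site.word for site in carriers.values())
    top = pd.DataFrame(
        sorted(variant_counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["variant", "count"],
    )
    spacer_counts = Counter(site.spacer for site in carriers.values())
    mode = None
    if spacer_counts:
        mode = min(spacer_counts, key=lambda s: (-spacer_counts[s], s))
    n_genes = len(genes)
    return GenomeSummary(
        genome_id=genome_id,
        n_genes=n_genes,
        n_motif_genes=len(carriers),
        fraction=len(carriers) / n_genes if n_genes else 0.0,
        top_variants=top,
        spacer_mode=mode,
    )


def corrected_motif_fraction(
    genes: list[GeneRecord],
    sites: list[MotifSite],
    matrix,
    dist,
    band: tuple[int, int] = (0, 20),
    p_threshold: float = 0.015,
    genome_id: str = "genome",
    null_background=None,
) -> tuple[float, GenomeSummary]:
    """Background-corrected estimate of the proximal-motif-carrying fraction.

    The raw detection rate — the share of genes with at least one passing
    site whose spacer lies in ``band`` — is inflated by chance hits, since a
    permissive scan threshold over a wide window guarantees some passing
    w-mers in random sequence. The chance rate f0 is computed exactly from
    the scoring lattice (transfer-matrix null over the band's base span, see
    ``motif_scan.null_band_hit_probability``) and removed:

        fraction = (f_obs - f0) / (1 - f0)

    ``null_background`` sets the base composition of the null text; pass the
    composition of a motif-free control region (e.g. the far-upstream part
    of the scanned windows, see ``control_background``) so that f0 reflects
    the sequence the band actually sits in rather than the whole corpus.

    Returns the corrected fraction together with a GenomeSummary holding the
    raw in-band counts, variants and spacer mode.
    """
    from .motif_scan import null_band_hit_probability

    lo, hi = band
    n_offsets = hi - lo + 1
    carriers: dict[str, MotifSite] = {}
    gene_ids = {g.gene_id for g in genes}
    for site in sites:
        if site.gene_id in gene_ids and lo <= site.spacer <= hi:
            cur = carriers.get(site.gene_id)
            if cur is None or site.p_value < cur.p_value:
                carriers[site.gene_id] = site
    n_genes = len(genes)
    f_obs = len(carriers) / n_genes if n_genes else 0.0
    f0 = null_band_hit_probability(
        matrix, dist, n_offsets, p_threshold, background=null_background
    )
    corrected = max(0.0, (f_obs - f0) / (1.0 - f0)) if f0 < 1.0 else 0.0

    variant_counts = Counter(s.word for s in carriers.values())
    spacer_counts = Counter(s.spacer for s in carriers.values())
    summary = GenomeSummary(
        genome_id=genome_id,
        n_genes=n_genes,
        n_motif_genes=len(carriers),
        fraction=corrected,
        top_variants=pd.DataFrame(
            sorted(variant_counts.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["variant", "count"],
        ),
        spacer_mode=(
            min(spacer_counts, key=lambda s: (-spacer_counts[s], s)) if spacer_counts else None
        ),
    )
    return corrected, summary


def control_background(windows, max_offset: int = -100):
    """Base composition of the far-upstream control slice of scan windows.

    Only bases at start-codon-relative positions <= ``max_offset`` are
    counted; that region carries no proximal promoter signal, so its
    composition is a clean null-text model for the chance-hit correction.
    """
    from .motif_discovery import estimate_background

    slices = []
    for win in windows:
        first = win.offset_of_first_base
        k = max_offset - first + 1
        if k > 0:
            slices.append(win.seq[:k])
    if not slices:
        raise ValueError("no window extends far enough upstream for a control slice")
    return estimate_background(slices)


def aggregate_genomes(
    summaries: list[GenomeSummary],
    grouping: dict[str, str] | None = None,
    detection_min_fraction: float = 0.1,
) -> pd.DataFrame:
    """Per-group motif prevalence across genomes.

    A genome counts as carrying a detectable -10-like motif when its
    ORF-level fraction reaches ``detection_min_fraction``. Reports, per
    group, the proportion of such genomes and the mean ORF fraction among
    them.
    """
    if grouping is None:
        grouping = {s.genome_id: "all" for s in summaries}
    rows = []
    by_group: dict[str, list[GenomeSummary]] = {}
    for s in summaries:
        by_group.setdefault(grouping.get(s.genome_id, "all"), []).append(s)
    for group, members in sorted(by_group.items()):
        detected = [s for s in members if s.fraction >= detection_min_fraction]
        rows.append(
            {
                "group": group,
                "n_genomes": len(members),
                "species_proportion": len(detected) / len(members),
                "mean_orf_fraction": (
                    sum(s.fraction for s in detected) / len(detected) if detected else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
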