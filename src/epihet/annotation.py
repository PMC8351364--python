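"""Genomic context for epiallele loci.

Builds annotation tracks from gene models and CpG islands — promoters
(TSS ± 2 kb), TTS windows, exons, introns; CGI shores (2 kb flanks of
islands) and shelves (the next 2 kb) — and classifies each locus by the
genomic features at the *center* of its 4-CpG span.  Also provides the
interval summaries used for partially methylated domain (PMD) analysis:
base-overlap concordance between region sets, length/coverage summaries,
and TSS distance to the nearest containing-region boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .io import GeneModel, GenomicInterval, GenomicRegionSet
from .loci import EpialleleLocus


class GenicFeature(str, Enum):
    PROMOTER_TSS = "promoter_tss"
    TTS = "tts"
    EXON = "exon"
    INTRON = "intron"
    INTERGENIC = "intergenic"


class CpGContext(str, Enum):
    CGI = "cgi"
    SHORE = "shore"
    SHELF = "shelf"
    OPEN_SEA = "open_sea"


#: genic precedence when tracks overlap, highest first
GENIC_PRECEDENCE = (
    GenicFeature.PROMOTER_TSS,
    GenicFeature.TTS,
    GenicFeature.EXON,
    GenicFeature.INTRON,
)

CPG_PRECEDENCE = (CpGContext.CGI, CpGContext.SHORE, CpGContext.SHELF)


@dataclass(frozen=True)
class FeatureAnnotation:
    genic_feature: GenicFeature
    cpg_context: CpGContext
    region_flags: dict[str, bool] | None = None


@dataclass(frozen=True)
class ContextTracks:
    """Region sets used by :func:`annotate_locus_center` (0-based)."""

    promoters: GenomicRegionSet
    tts_windows: GenomicRegionSet
    exons: GenomicRegionSet
    introns: GenomicRegionSet
    cgis: GenomicRegionSet
    shores: GenomicRegionSet
    shelves: GenomicRegionSet
    promoter_cgis: GenomicRegionSet


def _flank(iv: GenomicInterval, width: int) -> list[GenomicInterval]:
    out = []
    if iv.start > 0:
        out.append(GenomicInterval(iv.chrom, max(0, iv.start - width), iv.start))
    out.append(GenomicInterval(iv.chrom, iv.end, iv.end + width))
    return out


def _point_window(chrom: str, pos: int, flank: int) -> GenomicInterval:
    return GenomicInterval(chrom, max(0, pos - flank), pos + flank)


def build_context_tracks(
    genes: Sequence[GeneModel],
    cgis: GenomicRegionSet,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> ContextTracks:
    """Derive annotation tracks from gene models and CpG islands.

    Promoters are TSS ± ``promoter_flank`` (clipped at the contig start);
    TTS windows are defined symmetrically.  Shores are the
    ``shore_width`` flanks of the merged CGIs minus the CGIs; shelves the
    next ``shelf_width``, minus shores and CGIs — so CGI, shore and shelf
    are pairwise disjoint by construction.  Promoter CGIs are promoters
    intersected with CGIs.
    """
    promoters = GenomicRegionSet(
        _point_window(g.chrom, g.tss, config.promoter_flank) for g in genes
    )
    tts_windows = GenomicRegionSet(
        _point_window(g.chrom, g.tts, config.promoter_flank) for g in genes
    )
    exons = GenomicRegionSet(
        GenomicInterval(g.chrom, s, e) for g in genes for s, e in g.exons
    )
    gene_spans = GenomicRegionSet(
        GenomicInterval(g.chrom, min(g.tss, g.tts), max(g.tss, g.tts) + 1)
        for g in genes
    )
    introns = gene_spans.subtract(exons)

    cgi_merged = cgis.merge()
    shore_halo = GenomicRegionSet(
        iv for cgi in cgi_merged for iv in _flank(cgi, config.shore_width)
    )
    shores = shore_halo.subtract(cgi_merged)
    shelf_ivs = []
    for cgi in cgi_merged:
        left_end = cgi.start - config.shore_width
        if left_end > 0:
            shelf_ivs.append(
                GenomicInterval(
                    cgi.chrom, max(0, left_end - config.shelf_width), left_end
                )
            )
        right_start = cgi.end + config.shore_width
        shelf_ivs.append(
            GenomicInterval(
                cgi.chrom, right_start, right_start + config.shelf_width
            )
        )
    shelf_halo = GenomicRegionSet(shelf_ivs)
    shelves = shelf_halo.subtract(cgi_merged).subtract(shores)

    return ContextTracks(
        promoters=promoters,
        tts_windows=tts_windows,
        exons=exons,
        introns=introns,
        cgis=cgi_merged,
        shores=shores,
        shelves=shelves,
        promoter_cgis=promoters.intersect(cgi_merged),
    )


def annotate_locus_center(
    locus: EpialleleLocus,
    tracks: ContextTracks,
    region_sets: dict[str, GenomicRegionSet] | None = None,
) -> FeatureAnnotation:
    """Classify the midpoint of the locus span on both annotation axes.

    The center is ``floor((first + last) / 2)`` in 1-based CpG coordinates,
    converted to 0-based for interval membership.  Precedence:
    promoter > TTS > exon > intron > intergenic, and
    CGI > shore > shelf > open sea.  ``region_sets`` adds boolean
    membership flags (e.g. ``{"pmd": <regions>}``).
    """
    center0 = locus.center - 1  # 1-based midpoint -> 0-based point
    chrom = locus.chrom

    genic = GenicFeature.INTERGENIC
    for feature, track in zip(
        GENIC_PRECEDENCE,
        (tracks.promoters, tracks.tts_windows, tracks.exons, tracks.introns),
    ):
        if track.contains(chrom, center0):
            genic = feature
            break

    cpg_context = CpGContext.OPEN_SEA
    for context, track in zip(
        CPG_PRECEDENCE, (tracks.cgis, tracks.shores, tracks.shelves)
    ):
        if track.contains(chrom, center0):
            cpg_context = context
            break

    flags = None
    if region_sets is not None:
        flags = {
            f"in_{name}": regions.contains(chrom, center0)
            for name, regions in region_sets.items()
        }
    return FeatureAnnotation(genic, cpg_context, flags)


def region_overlap_stats(
    set_a: GenomicRegionSet, set_b: GenomicRegionSet
) -> dict[str, float]:
    """Base-level concordance of two region sets.

    Returns the fraction of A's bases covered by B and the Jaccard index
    of the two base sets (both computed on merged intervals).
    """
    a_bases = set_a.total_bases()
    if a_bases == 0:
        raise ValueError("overlap fraction undefined for an empty first set")
    inter = set_a.merge().intersect(set_b.merge()).total_bases()
    union = set_a.union(set_b).total_bases()
    return {
        "base_overlap_fraction_of_a": inter / a_bases,
        "jaccard": inter / union if union else 0.0,
    }


def region_summary(
    regions: GenomicRegionSet, genome_size: int
) -> dict[str, float | None]:
    """Interval count, median length and merged genome coverage."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    lengths = [len(iv) for iv in regions]
    return {
        "n": len(lengths),
        "median_length": float(np.median(lengths)) if lengths else None,
        "genome_coverage": regions.total_bases() / genome_size,
    }


def tss_boundary_distance(
    genes: Iterable[GeneModel],
    regions: GenomicRegionSet,
    quantile: float = 0.75,
    method: str = "linear",
) -> tuple[dict[str, int], float | None]:
    """Distance of each in-region TSS to its region's nearest boundary.

    Genes whose TSS lies outside every region are skipped.  Returns the
    per-gene distances and the requested quantile of their distribution
    (``method`` follows :func:`numpy.quantile`; ``linear`` interpolation
    by default, ``nearest`` for a rank-based convention).
    """
    distances: dict[str, int] = {}
    for gene in genes:
        iv = regions.containing_interval(gene.chrom, gene.tss)
        if iv is None:
            continue
        distances[gene.gene_id] = min(gene.tss - iv.start, iv.end - gene.tss)
    if not distances:
        return distances, None
    q = float(
        np.quantile(np.array(list(distances.values()), dtype=float),
                    quantile, method=method)
    )
    return distances, q
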