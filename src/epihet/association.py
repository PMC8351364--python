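"""Expression–methylation association.

The central question: does promoter methylation keep its usual repressive
relationship with transcription when the promoter's methylation patterns
are disordered?  Genes are stratified by promoter PDR (below/above the
cohort mean), and within each stratum a 2x2 odds ratio relates expression
(FPM > 1 vs <= 1) to promoter methylation class (mean methylation > 0.75
vs < 0.25; intermediate promoters are excluded).  An OR well below 1 is
the canonical coupling — methylated promoters silent; a CI covering 1
marks decoupling.  Expression variability across samples is summarized by
the per-gene coefficient of variation, optionally split by region-set
membership (e.g. inside/outside partially methylated domains).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .config import AnalysisConfig, DEFAULT_CONFIG
from .io import ExpressionTable, GeneModel, GenomicRegionSet
from .metrics import LocusMetrics


class PdrStratum(str, Enum):
    LOW = "low"
    HIGH = "high"


class MethylationClass(str, Enum):
    METHYLATED = "methylated"
    UNMETHYLATED = "unmethylated"
    INTERMEDIATE = "intermediate"  # excluded from the odds-ratio table


@dataclass(frozen=True)
class GenePromoterState:
    """Promoter methylation/PDR and expression of one gene in one sample."""

    gene_id: str
    promoter_mean_methylation: float
    promoter_pdr: float
    fpm: float
    n_promoter_loci: int

    def methylation_class(
        self, config: AnalysisConfig = DEFAULT_CONFIG
    ) -> MethylationClass:
        if self.promoter_mean_methylation > config.promoter_meth_high:
            return MethylationClass.METHYLATED
        if self.promoter_mean_methylation < config.promoter_meth_low:
            return MethylationClass.UNMETHYLATED
        return MethylationClass.INTERMEDIATE

    def is_expressed(self, config: AnalysisConfig = DEFAULT_CONFIG) -> bool:
        return self.fpm > config.fpm_expressed_threshold


@dataclass(frozen=True)
class OddsRatioResult:
    """2x2 odds ratio with a Woolf (log-scale) 95% confidence interval.

    Table orientation: rows expressed / not expressed, columns methylated /
    unmethylated — ``a`` counts expressed & methylated genes, so OR > 1
    means methylated promoters are *enriched* among expressed genes (the
    decoupled, counter-canonical direction).
    """

    a: int
    b: int
    c: int
    d: int
    or_estimate: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool

    def covers_one(self) -> bool:
        return self.ci_low <= 1.0 <= self.ci_high


def odds_ratio(
    table: Sequence[Sequence[int]], confidence: float = 0.95
) -> OddsRatioResult:
    """OR = ad/bc with Haldane–Anscombe +0.5 correction on any zero cell
    and a Woolf confidence interval on the log scale."""
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("odds ratio undefined for an all-zero table")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    est = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(0.5 + confidence / 2)
    return OddsRatioResult(
        a=a, b=b, c=c, d=d,
        or_estimate=est,
        ci_low=est * math.exp(-z * se),
        ci_high=est * math.exp(z * se),
        continuity_corrected=corrected,
    )


def gene_promoter_states(
    genes: Sequence[GeneModel],
    loci_metrics: Sequence[LocusMetrics],
    locus_centers: Mapping[str, tuple[str, int]],
    expression: ExpressionTable,
    sample: str,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> list[GenePromoterState]:
    """Promoter-level methylation and PDR per gene, from promoter loci.

    A locus belongs to a gene's promoter when its center (1-based; given
    by ``locus_centers`` as ``locus_id -> (chrom, center)``) falls within
    TSS ± ``config.promoter_flank``.  Promoter methylation and PDR are
    unweighted means over those loci.  Genes without promoter loci, or
    absent from the expression table, are skipped.
    """
    states = []
    for gene in genes:
        lo = gene.tss - config.promoter_flank
        hi = gene.tss + config.promoter_flank
        promoter_metrics = [
            m
            for m in loci_metrics
            if m.locus_id in locus_centers
            and locus_centers[m.locus_id][0] == gene.chrom
            and lo <= locus_centers[m.locus_id][1] - 1 < hi
        ]
        if not promoter_metrics or gene.gene_id not in expression.data.index:
            continue
        states.append(
            GenePromoterState(
                gene_id=gene.gene_id,
                promoter_mean_methylation=float(
                    np.mean([m.mean_methylation for m in promoter_metrics])
                ),
                promoter_pdr=float(np.mean([m.pdr for m in promoter_metrics])),
                fpm=expression.fpm(gene.gene_id, sample),
                n_promoter_loci=len(promoter_metrics),
            )
        )
    return states


def stratify_by_pdr(
    states: Sequence[GenePromoterState],
) -> dict[PdrStratum, list[GenePromoterState]]:
    """Split genes at the cohort mean promoter PDR (high = strictly above)."""
    if not states:
        raise ValueError("no gene promoter states to stratify")
    mean_pdr = float(np.mean([s.promoter_pdr for s in states]))
    out = {PdrStratum.LOW: [], PdrStratum.HIGH: []}
    for s in states:
        stratum = PdrStratum.HIGH if s.promoter_pdr > mean_pdr else PdrStratum.LOW
        out[stratum].append(s)
    return out


def expression_methylation_table(
    states: Iterable[GenePromoterState],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """2x2 counts (rows expressed/not, columns methylated/unmethylated);
    genes with intermediate promoter methylation are excluded."""
    a = b = c = d = 0
    for s in states:
        mclass = s.methylation_class(config)
        if mclass is MethylationClass.INTERMEDIATE:
            continue
        expressed = s.is_expressed(config)
        methylated = mclass is MethylationClass.METHYLATED
        if expressed and methylated:
            a += 1
        elif expressed:
            b += 1
        elif methylated:
            c += 1
        else:
            d += 1
    return (a, b), (c, d)


def stratified_odds_ratios(
    states: Sequence[GenePromoterState],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict[PdrStratum, OddsRatioResult]:
    """The promoter-PDR-stratified expression/methylation odds ratios."""
    out = {}
    for stratum, members in stratify_by_pdr(states).items():
        table = expression_methylation_table(members, config)
        if sum(table[0]) + sum(table[1]) == 0:
            continue
        out[stratum] = odds_ratio(table)
    return out


def expression_cv(
    expression: ExpressionTable,
    gene_sets: Mapping[str, Iterable[str]],
    min_mean_fpm: float = 1.0,
) -> dict[str, dict[str, float]]:
    """Per-gene coefficient of variation (sample sd / mean across samples),
    grouped by gene set; genes with mean FPM <= ``min_mean_fpm`` excluded.

    Requires at least two samples.  Returns ``set -> {gene -> CV}``.
    """
    df = expression.data
    if df.shape[1] < 2:
        raise ValueError("CV requires at least two samples")
    means = df.mean(axis=1)
    sds = df.std(axis=1, ddof=1)
    qualifying = means > min_mean_fpm
    cv = (sds[qualifying] / means[qualifying]).to_dict()
    out: dict[str, dict[str, float]] = {}
    for name, members in gene_sets.items():
        out[name] = {g: cv[g] for g in members if g in cv}
    return out


def gene_set_by_region(
    genes: Iterable[GeneModel], regions: GenomicRegionSet
) -> tuple[set[str], set[str]]:
    """Split gene ids by whether their TSS lies inside the region set."""
    inside, outside = set(), set()
    for g in genes:
        (inside if regions.contains(g.chrom, g.tss) else outside).add(g.gene_id)
    return inside, outside
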