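"""Paired-sample epiallele shift analysis.

The entropy difference at a locus shared by two samples, ΔS = S2 - S1,
measures how much the epiallele composition reorganized between disease
states.  Loci with ΔS strictly below the threshold (default -70 on the
[-100, 0] entropy scale) are eloci; their burden is normalized as eloci
per million loci covered in both samples, EPM = 1e6 * E / C.  Against a
panel of control samples, a locus is a consensus elocus only when called
against every control.  Eloci are further split by methylation direction
(hyper/hypo at a 25% locus mean-methylation difference) and into four
pattern-change categories driven by whether either stage has a highly
predominant pattern.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .loci import EpialleleLocus, PatternCounts, counts_to_distribution
from .metrics import entropy, mean_methylation, _validate_distribution


class ChangeCategory(str, Enum):
    DISORDER_MAINTENANCE = "disorder_maintenance"
    SELECTION = "selection"
    DISORDER = "disorder"
    SWITCH = "switch"
    UNCLASSIFIED = "unclassified"


class Direction(str, Enum):
    HYPER = "hyper"
    HYPO = "hypo"
    NONE = "none"


@dataclass(frozen=True)
class PairedLocusComparison:
    """ΔS, elocus flag, methylation direction and pattern-change category
    for one locus between two samples (1 = earlier stage, 2 = later)."""

    locus: EpialleleLocus
    s1: float
    s2: float
    delta_s: float          # signed S2 - S1
    delta_s_effective: float  # the value compared against the threshold
    is_elocus: bool
    meth1: float
    meth2: float
    direction: Direction
    change_category: ChangeCategory

    @property
    def meth_diff(self) -> float:
        return self.meth2 - self.meth1


@dataclass(frozen=True)
class SampleComparison:
    """Elocus burden of a sample pair: E eloci among C shared loci."""

    n_eloci: int
    n_shared_loci: int

    @property
    def epm(self) -> float | None:
        """Eloci per million shared loci; None when no locus is shared."""
        if self.n_shared_loci == 0:
            return None
        return epm(self.n_eloci, self.n_shared_loci)


def epm(n_eloci: int, n_shared_loci: int) -> float:
    """EPM = 1e6 / C * E."""
    if n_shared_loci <= 0:
        raise ValueError("EPM undefined without shared loci")
    if not 0 <= n_eloci <= n_shared_loci:
        raise ValueError("elocus count must lie in [0, shared loci]")
    return 1e6 * n_eloci / n_shared_loci


def classify_change(
    dist1: np.ndarray,
    dist2: np.ndarray,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> ChangeCategory:
    """Assign one of the four pattern-change categories (or unclassified).

    disorder maintenance: no predominant pattern (all proportions strictly
    below ``minor_threshold``) at either stage; selection: disordered at
    stage 1, one pattern strictly above ``dominant_threshold`` at stage 2;
    disorder: the reverse; switch: a different dominant pattern at each
    stage.  Everything else, e.g. the same dominant pattern twice or
    intermediate compositions, is unclassified.
    """
    p1 = _validate_distribution(dist1)
    p2 = _validate_distribution(dist2)
    disordered1 = bool(p1.max() < config.minor_threshold)
    disordered2 = bool(p2.max() < config.minor_threshold)
    dominant1 = bool(p1.max() > config.dominant_threshold)
    dominant2 = bool(p2.max() > config.dominant_threshold)
    if disordered1 and disordered2:
        return ChangeCategory.DISORDER_MAINTENANCE
    if disordered1 and dominant2:
        return ChangeCategory.SELECTION
    if dominant1 and disordered2:
        return ChangeCategory.DISORDER
    if dominant1 and dominant2 and int(p1.argmax()) != int(p2.argmax()):
        return ChangeCategory.SWITCH
    return ChangeCategory.UNCLASSIFIED


def _direction(meth_diff: float, config: AnalysisConfig) -> Direction:
    if meth_diff >= config.meth_diff_threshold:
        return Direction.HYPER
    if meth_diff <= -config.meth_diff_threshold:
        return Direction.HYPO
    return Direction.NONE


def compare_locus(
    counts1: PatternCounts,
    counts2: PatternCounts,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> PairedLocusComparison:
    if counts1.locus != counts2.locus:
        raise ValueError("paired comparison requires the same locus")
    d1 = counts_to_distribution(counts1)
    d2 = counts_to_distribution(counts2)
    s1 = entropy(d1, config.entropy_scale)
    s2 = entropy(d2, config.entropy_scale)
    delta = s2 - s1
    effective = -abs(delta) if config.elocus_on_absolute_delta_s else delta
    meth1 = mean_methylation(counts1)
    meth2 = mean_methylation(counts2)
    return PairedLocusComparison(
        locus=counts1.locus,
        s1=s1,
        s2=s2,
        delta_s=delta,
        delta_s_effective=effective,
        is_elocus=effective < config.elocus_delta_s_threshold,
        meth1=meth1,
        meth2=meth2,
        direction=_direction(meth2 - meth1, config),
        change_category=classify_change(d1, d2, config),
    )


def compare_samples(
    loci_s1: Sequence[PatternCounts],
    loci_s2: Sequence[PatternCounts],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[list[PairedLocusComparison], SampleComparison]:
    """Compare every locus covered (at depth) in both samples.

    Loci are matched by chromosome and the exact 4 CpG positions.  C is
    the number of shared loci, E the number of eloci among them.  With no
    shared loci, EPM is reported as missing (None), not zero.
    """
    index2 = {pc.locus: pc for pc in loci_s2}
    comparisons = [
        compare_locus(pc, index2[pc.locus], config)
        for pc in loci_s1
        if pc.locus in index2
    ]
    n_eloci = sum(c.is_elocus for c in comparisons)
    return comparisons, SampleComparison(n_eloci, len(comparisons))


def consensus_eloci(
    control_comparisons: Sequence[Sequence[PairedLocusComparison]],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> set[EpialleleLocus]:
    """Loci called elocus against *every* control sample.

    ``control_comparisons`` holds one comparison list per control (the
    tumor sample compared against each of the ``config.n_controls``
    controls, 3 normal plasma cell samples by default).
    """
    if len(control_comparisons) != config.n_controls:
        raise ValueError(
            f"expected {config.n_controls} control comparisons, "
            f"got {len(control_comparisons)}"
        )
    per_control = [
        {c.locus for c in comps if c.is_elocus} for comps in control_comparisons
    ]
    return set.intersection(*per_control) if per_control else set()


def category_fractions(
    eloci: Iterable[PairedLocusComparison],
) -> dict[ChangeCategory, float]:
    """Proportion of eloci in each pattern-change category (sums to 1)."""
    eloci = list(eloci)
    if not eloci:
        raise ValueError("category fractions undefined for zero eloci")
    counts = Counter(c.change_category for c in eloci)
    return {cat: counts.get(cat, 0) / len(eloci) for cat in ChangeCategory}
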