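"""Build 4-CpG epiallele loci from epireads.

A locus is a window of 4 consecutive CpGs in the observed CpG map of a
chromosome; a read contributes one epiallele to a locus iff it carries a
determinate (non-missing) call at all 4 positions.  The 16 possible
methylation patterns are indexed by treating the calls in genomic order as
bits, most significant first: UUUU -> 0, MUUU -> 8, MMMM -> 15.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .io import MISSING, EpiRead

N_PATTERNS = 16
LOCUS_SIZE = 4

#: number of methylated CpGs in each pattern index
PATTERN_POPCOUNT = np.array([bin(i).count("1") for i in range(N_PATTERNS)])


@dataclass(frozen=True)
class EpialleleLocus:
    """Four consecutive CpGs on one chromosome (1-based positions)."""

    chrom: str
    cpg_positions: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.cpg_positions)
        object.__setattr__(self, "cpg_positions", pos)
        if len(pos) != LOCUS_SIZE:
            raise ValueError(f"locus needs exactly {LOCUS_SIZE} CpGs")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("locus positions must be strictly ascending")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.cpg_positions[0]}-{self.cpg_positions[-1]}"

    @property
    def start(self) -> int:
        return self.cpg_positions[0]

    @property
    def end(self) -> int:
        return self.cpg_positions[-1]

    @property
    def center(self) -> int:
        """Midpoint of the span, floored (1-based coordinate)."""
        return (self.cpg_positions[0] + self.cpg_positions[-1]) // 2


@dataclass(frozen=True)
class PatternCounts:
    """Read counts over the 16 epiallele patterns at one locus."""

    locus: EpialleleLocus
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (N_PATTERNS,):
            raise ValueError(f"counts must have length {N_PATTERNS}")
        if (counts < 0).any():
            raise ValueError("pattern counts must be non-negative")

    @property
    def depth(self) -> int:
        return int(self.counts.sum())


def encode_pattern(calls: Sequence[int]) -> int:
    """Map 4 M/U calls (genomic order) to a pattern index in 0..15.

    The first genomic CpG is the most significant bit.  Missing calls are
    not encodable: the read must be excluded from the locus instead.
    """
    if len(calls) != LOCUS_SIZE:
        raise ValueError(f"need exactly {LOCUS_SIZE} calls")
    idx = 0
    for c in calls:
        if c == MISSING:
            raise ValueError("cannot encode a pattern containing a missing call")
        idx = (idx << 1) | int(c)
    return idx


def decode_pattern(index: int) -> tuple[int, int, int, int]:
    """Inverse of :func:`encode_pattern`."""
    if not 0 <= index < N_PATTERNS:
        raise ValueError("pattern index out of range")
    return tuple((index >> shift) & 1 for shift in (3, 2, 1, 0))


def enumerate_loci(
    reads: Iterable[EpiRead],
    config: AnalysisConfig = DEFAULT_CONFIG,
    cpg_map: dict[str, np.ndarray] | None = None,
) -> list[PatternCounts]:
    """Slide 4-CpG windows over the observed CpG map and count epialleles.

    The CpG map is derived from the data: all positions carrying at least
    ``config.min_cpg_coverage`` determinate calls, per chromosome.  An
    explicit ``cpg_map`` (chrom -> sorted 1-based positions) restricts the
    data-derived map to known CpGs instead of replacing the coverage rule.
    Candidate loci are every stride-1 window of 4 consecutive map CpGs;
    windows with fewer than ``config.min_locus_depth`` contributing reads
    are dropped.  Output is sorted by chromosome then position.
    """
    by_chrom: dict[str, list[EpiRead]] = defaultdict(list)
    for read in reads:
        by_chrom[read.chrom].append(read)

    out: list[PatternCounts] = []
    for chrom in sorted(by_chrom):
        out.extend(_enumerate_chrom(chrom, by_chrom[chrom], config, cpg_map))
    return out


def _enumerate_chrom(
    chrom: str,
    reads: list[EpiRead],
    config: AnalysisConfig,
    cpg_map: dict[str, np.ndarray] | None,
) -> list[PatternCounts]:
    # coverage pass: determinate calls per observed position
    all_pos = np.concatenate([r.cpg_positions[r.calls != MISSING] for r in reads]) \
        if reads else np.empty(0, dtype=np.int64)
    if all_pos.size == 0:
        return []
    positions, coverage = np.unique(all_pos, return_counts=True)
    keep = coverage >= config.min_cpg_coverage
    if cpg_map is not None:
        known = np.asarray(cpg_map.get(chrom, ()), dtype=np.int64)
        keep &= np.isin(positions, known)
    cmap = positions[keep]
    if cmap.size < LOCUS_SIZE:
        return []
    index_of = {int(p): i for i, p in enumerate(cmap)}

    window_counts: dict[int, np.ndarray] = {}
    for read in reads:
        det = read.calls != MISSING
        pos = read.cpg_positions[det]
        calls = read.calls[det]
        idx = np.fromiter(
            (index_of.get(int(p), -1) for p in pos), dtype=np.int64, count=pos.size
        )
        ok = idx >= 0
        idx, calls = idx[ok], calls[ok]
        if idx.size < LOCUS_SIZE:
            continue
        # maximal runs of consecutive map indices
        breaks = np.flatnonzero(np.diff(idx) != 1) + 1
        for lo, hi in zip(
            np.concatenate(([0], breaks)), np.concatenate((breaks, [idx.size]))
        ):
            run_len = hi - lo
            if run_len < LOCUS_SIZE:
                continue
            bits = calls[lo:hi].astype(np.int64)
            # pattern index of each 4-CpG window within the run
            patt = (
                (bits[:-3] << 3) | (bits[1:-2] << 2) | (bits[2:-1] << 1) | bits[3:]
            )
            start0 = int(idx[lo])
            for off, p in enumerate(patt):
                w = start0 + off
                arr = window_counts.get(w)
                if arr is None:
                    arr = np.zeros(N_PATTERNS, dtype=np.int64)
                    window_counts[w] = arr
                arr[p] += 1

    out = []
    for w in sorted(window_counts):
        counts = window_counts[w]
        if counts.sum() < config.min_locus_depth:
            continue
        locus = EpialleleLocus(chrom, tuple(int(p) for p in cmap[w : w + LOCUS_SIZE]))
        out.append(PatternCounts(locus, counts))
    return out


def counts_to_distribution(pattern_counts: PatternCounts) -> np.ndarray:
    """Epiallele proportions p_i = counts_i / depth."""
    depth = pattern_counts.depth
    if depth == 0:
        raise ValueError("cannot form a distribution from zero-depth counts")
    return pattern_counts.counts / depth
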