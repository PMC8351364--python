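"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's vectorized code paths: metrics are
recomputed read by read, and locus enumeration re-derives every candidate
window by scanning all reads per window.
"""

from __future__ import annotations

import numpy as np

from epihet.io import MISSING, EpiRead
from epihet.loci import PatternCounts


def expand_reads(counts: PatternCounts) -> list[int]:
    """Pattern index of every individual read at the locus."""
    out = []
    for pattern, n in enumerate(counts.counts):
        out.extend([pattern] * int(n))
    return out


def epi_per_read(counts: PatternCounts) -> float:
    reads = expand_reads(counts)
    n = len(reads)
    total = 0.0
    for pattern in set(reads):
        total += (reads.count(pattern) / n) ** 2
    return 1.0 - total


def pdr_per_read(counts: PatternCounts) -> float:
    reads = expand_reads(counts)
    discordant = sum(1 for p in reads if p not in (0, 15))
    return discordant / len(reads)


def mean_meth_per_read(counts: PatternCounts) -> float:
    reads = expand_reads(counts)
    return float(np.mean([bin(p).count("1") / 4 for p in reads]))


def entropy_per_read(counts: PatternCounts, scale: float = 25.0) -> float:
    reads = expand_reads(counts)
    n = len(reads)
    s = 0.0
    for pattern in set(reads):
        p = reads.count(pattern) / n
        s += p * np.log2(p)
    return scale * s


def enumerate_loci_bruteforce(
    reads: list[EpiRead], min_depth: int, min_cpg_coverage: int
) -> dict[tuple[str, tuple[int, ...]], np.ndarray]:
    """All 4-consecutive-CpG windows with their pattern counts.

    Scans every read for every candidate window; quadratic and slow on
    purpose.
    """
    out: dict[tuple[str, tuple[int, ...]], np.ndarray] = {}
    chroms = sorted({r.chrom for r in reads})
    for chrom in chroms:
        chrom_reads = [r for r in reads if r.chrom == chrom]
        coverage: dict[int, int] = {}
        for r in chrom_reads:
            for pos, call in zip(r.cpg_positions, r.calls):
                if call != MISSING:
                    coverage[int(pos)] = coverage.get(int(pos), 0) + 1
        cpg_map = sorted(p for p, c in coverage.items() if c >= min_cpg_coverage)
        for i in range(len(cpg_map) - 3):
            window = tuple(cpg_map[i : i + 4])
            counts = np.zeros(16, dtype=np.int64)
            for r in chrom_reads:
                calls = {}
                for pos, call in zip(r.cpg_positions, r.calls):
                    calls[int(pos)] = int(call)
                if all(calls.get(p, MISSING) != MISSING for p in window):
                    idx = 0
                    for p in window:
                        idx = (idx << 1) | calls[p]
                    counts[idx] += 1
            if counts.sum() >= min_depth:
                out[(chrom, window)] = counts
    return out


def max_epi_exact(m: float) -> float:
    """Exact maximum epipolymorphism at mean methylation m.

    Patterns are grouped into the 5 weight classes by methylated-CpG
    count (sizes 1,4,6,4,1); within a class equal split minimizes the sum
    of squares, reducing the problem to minimizing sum(w_k^2 / c_k) over
    class masses with sum(w) = 1 and sum(k w_k)/4 = m.  Solved by
    enumerating every support set: on each support the two equality
    constraints give a linear system for the Lagrange multipliers, hence
    a closed-form candidate; the best feasible candidate is optimal.
    """
    import itertools

    sizes = np.array([1, 4, 6, 4, 1], dtype=float)
    best = None
    for r in range(1, 6):
        for support in itertools.combinations(range(5), r):
            c = sizes[list(support)]
            k = np.array(support, dtype=float)
            # w_j = c_j (lam + mu k_j) / 2 on the support
            A = np.array(
                [[c.sum(), np.dot(k, c)], [np.dot(k, c), np.dot(k * k, c)]]
            )
            b = np.array([2.0, 8.0 * m])
            try:
                lam, mu = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                continue
            w = c * (lam + mu * k) / 2.0
            if (w < -1e-12).any():
                continue
            w = np.clip(w, 0, None)
            if abs(w.sum() - 1) > 1e-9 or abs(np.dot(k, w) / 4 - m) > 1e-9:
                continue
            obj = 1.0 - float(np.sum(w**2 / c))
            if best is None or obj > best:
                best = obj
    if best is None:
        raise ValueError(f"no feasible class-mass vector at m={m}")
    return best
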