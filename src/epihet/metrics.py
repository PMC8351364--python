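"""Per-locus heterogeneity metrics.

Epipolymorphism is the Gini–Simpson diversity of the 16 epiallele
proportions, ``Epi = 1 - sum(p_i^2)``, ranging from 0 (single pattern) to
0.9375 (uniform over all 16 patterns).  PDR is the proportion of reads that
are neither fully methylated nor fully unmethylated over the locus's 4
CpGs.  Combinatorial entropy ``S = scale * sum(p_i * log2 p_i)`` is
non-positive; with the default scale of 25 it spans [-100, 0] for a 4-CpG
locus, and its between-sample difference drives elocus calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .config import AnalysisConfig, DEFAULT_CONFIG
from .loci import (
    LOCUS_SIZE,
    N_PATTERNS,
    PATTERN_POPCOUNT,
    PatternCounts,
    counts_to_distribution,
)

EPI_MAX = 1.0 - 1.0 / N_PATTERNS  # 0.9375

#: pattern indices whose reads are concordant (fully U or fully M)
CONCORDANT_PATTERNS = (0, N_PATTERNS - 1)

_NORMALIZATION_TOL = 1e-9

#: multiplicity of patterns by methylated-CpG count (binomial coefficients)
_CLASS_SIZES = np.array([1, 4, 6, 4, 1], dtype=float)


def _validate_distribution(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (N_PATTERNS,):
        raise ValueError(f"distribution must have length {N_PATTERNS}")
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > _NORMALIZATION_TOL:
        raise ValueError("proportions must sum to 1")
    return p


def epipolymorphism(dist: np.ndarray) -> float:
    """``1 - sum(p_i^2)`` over the 16 epiallele proportions."""
    p = _validate_distribution(dist)
    return float(1.0 - np.dot(p, p))


def pdr(counts: PatternCounts) -> float:
    """Proportion of discordant reads (not all-M and not all-U)."""
    depth = counts.depth
    if depth == 0:
        raise ValueError("PDR undefined at zero depth")
    concordant = int(counts.counts[CONCORDANT_PATTERNS[0]]) + int(
        counts.counts[CONCORDANT_PATTERNS[1]]
    )
    return (depth - concordant) / depth


def entropy(dist: np.ndarray, entropy_scale: float = 25.0) -> float:
    """Combinatorial entropy ``scale * sum(p_i log2 p_i)`` (<= 0)."""
    p = _validate_distribution(dist)
    nz = p[p > 0]
    return float(entropy_scale * np.sum(nz * np.log2(nz)))


def mean_methylation(counts: PatternCounts) -> float:
    """Mean methylation over reads and CpGs: sum p_i * popcount(i) / 4."""
    depth = counts.depth
    if depth == 0:
        raise ValueError("mean methylation undefined at zero depth")
    return float(np.dot(counts.counts, PATTERN_POPCOUNT) / (depth * LOCUS_SIZE))


def epipolymorphism_envelope(m: float) -> tuple[float, float]:
    """Envelope of epipolymorphism at a given mean methylation ``m``.

    Returns ``(max_epi, bimodal_epi)``.  ``bimodal_epi = 2m(1-m)`` is the
    diversity achievable with mass only on the fully unmethylated and fully
    methylated patterns.  ``max_epi`` maximizes ``1 - sum(p^2)`` subject to
    mean methylation ``m``: patterns are grouped into the 5 weight classes
    by methylated-CpG count (sizes 1,4,6,4,1); within a class an equal
    split minimizes the sum of squares, so the problem reduces to a
    quadratic program over the class masses.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError("mean methylation must lie in [0, 1]")
    bimodal = 2.0 * m * (1.0 - m)
    if m in (0.0, 1.0):
        return 0.0, 0.0  # only one feasible pattern

    # minimize sum_k w_k^2 / c_k  s.t.  sum w = 1, sum k*w_k/4 = m, w >= 0
    k = np.arange(LOCUS_SIZE + 1, dtype=float)

    def objective(w: np.ndarray) -> float:
        return float(np.sum(w**2 / _CLASS_SIZES))

    def jac(w: np.ndarray) -> np.ndarray:
        return 2.0 * w / _CLASS_SIZES

    w0 = np.full(LOCUS_SIZE + 1, 1.0 / (LOCUS_SIZE + 1))
    # feasible start: shift mass between ends to hit the mean constraint
    w0 = (1 - 0.5) * w0 + 0.5 * np.array([1 - m, 0, 0, 0, m])
    res = optimize.minimize(
        objective,
        w0,
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * (LOCUS_SIZE + 1),
        constraints=[
            {"type": "eq", "fun": lambda w: w.sum() - 1.0},
            {"type": "eq", "fun": lambda w: float(np.dot(k, w)) / LOCUS_SIZE - m},
        ],
        options={"ftol": 1e-12, "maxiter": 200},
    )
    if not res.success:  # pragma: no cover - SLSQP converges on this QP
        raise RuntimeError(f"envelope optimization failed: {res.message}")
    max_epi = 1.0 - float(objective(res.x))
    return min(max_epi, EPI_MAX), bimodal


@dataclass(frozen=True)
class LocusMetrics:
    """Heterogeneity metrics of one locus in one sample."""

    locus_id: str
    depth: int
    epipolymorphism: float
    pdr: float
    entropy: float
    mean_methylation: float


def locus_metrics(
    counts: PatternCounts, config: AnalysisConfig = DEFAULT_CONFIG
) -> LocusMetrics:
    dist = counts_to_distribution(counts)
    return LocusMetrics(
        locus_id=counts.locus.locus_id,
        depth=counts.depth,
        epipolymorphism=epipolymorphism(dist),
        pdr=pdr(counts),
        entropy=entropy(dist, config.entropy_scale),
        mean_methylation=mean_methylation(counts),
    )


def sample_summary(
    metrics: list[LocusMetrics], config: AnalysisConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """Unweighted per-sample summary over loci.

    Returns mean epipolymorphism, mean PDR, the number of loci and the
    fraction of loci whose PDR exceeds ``config.discordant_locus_fraction``
    (predominantly discordant loci).
    """
    if not metrics:
        raise ValueError("sample summary undefined for zero loci")
    epis = np.array([m.epipolymorphism for m in metrics])
    pdrs = np.array([m.pdr for m in metrics])
    return {
        "n_loci": len(metrics),
        "mean_epipolymorphism": float(epis.mean()),
        "mean_pdr": float(pdrs.mean()),
        "fraction_loci_pdr_above_threshold": float(
            (pdrs > config.discordant_locus_fraction).mean()
        ),
    }
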