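"""Synthetic epiallele cohorts.

Generates a miniature paired-sample bisulfite cohort — three normal
plasma-cell (NPC) controls plus a diagnosis/relapse tumor pair — with
known ground truth at every locus, so the whole pipeline can be exercised
and validated without patient data.

Each locus carries a true 16-pattern epiallele distribution per sample;
reads are drawn multinomially at Poisson depth (clamped at the 60-read
locus floor so coverage dropout never masks metric behavior).  NPC
replicates share a baseline distribution with small Dirichlet jitter.
Planted events rewrite the diagnosis (or relapse) distribution according
to their category:

* ``hyper_shift`` / ``hypo_shift`` — a concordant unmethylated (resp.
  methylated) baseline collapses into near-uniform disorder, producing a
  strong entropy loss with a >= 25% methylation change in the stated
  direction;
* ``disorder`` — a single dominant pattern dissolves into disorder;
* ``selection`` — a disordered baseline collapses onto one dominant
  pattern (an entropy *gain*, invisible to the signed elocus rule);
* ``switch`` — the dominant pattern is replaced by a different one;
* ``disorder_maintenance`` — two independent disordered compositions;
* ``null`` — jittered copy of the baseline.

Gene promoters get their own loci whose composition controls the
methylation–expression coupling: low-PDR promoters (concordant dominant
patterns) are *coupled* — log-expression decreases with promoter
methylation — while high-PDR promoters (disordered patterns) are
*decoupled* — expression is independent of methylation and noisier.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    EpiRead,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    GenomicRegionSet,
    write_bed,
    write_epireads,
    write_expression,
    write_gene_models,
)
from .loci import N_PATTERNS, PATTERN_POPCOUNT, EpialleleLocus, decode_pattern
from .metrics import entropy

import pandas as pd

EVENT_CATEGORIES = (
    "null",
    "hyper_shift",
    "hypo_shift",
    "disorder",
    "selection",
    "switch",
    "disorder_maintenance",
)

_DEFAULT_PLANTED = (
    (0.02, "hyper_shift"),
    (0.02, "hypo_shift"),
    (0.02, "disorder"),
    (0.02, "selection"),
    (0.01, "switch"),
    (0.01, "disorder_maintenance"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort generator parameters.

    ``archetype_weights`` mixes the background locus compositions
    (bimodal concordant, single dominant pattern, Dirichlet-disordered)
    that emulate a mostly bimodal normal methylome with a disordered
    fraction.  ``planted_events`` assigns fractions of background loci to
    the shift categories (applied between the NPC baseline and
    diagnosis); ``relapse_events`` does the same between diagnosis and
    relapse.  Depth is Poisson with mean ``depth_mean`` clamped at
    ``min_locus_depth``.
    """

    seed: int = 0
    n_chromosomes: int = 2
    n_loci: int = 200
    depth_mean: float = 80.0
    min_locus_depth: int = 60
    archetype_weights: tuple[float, float, float] = (0.45, 0.35, 0.20)
    dirichlet_alpha: float = 2.0
    n_npc: int = 3
    planted_events: tuple[tuple[float, str], ...] = _DEFAULT_PLANTED
    relapse_events: tuple[tuple[float, str], ...] = ()
    npc_jitter_concentration: float = 400.0
    null_jitter_concentration: float = 400.0
    cpg_dropout_rate: float = 0.0
    pmd_genome_fraction: float = 0.65
    pmd_length_mean: float = 15000.0
    locus_spacing: int = 1000
    n_genes: int = 100
    fraction_hyper_promoters: float = 0.5
    fraction_decoupled: float = 0.5
    expression_log2_base: float = 3.0
    expression_log2_slope: float = 5.0
    expression_noise_sd_coupled: float = 0.5
    expression_noise_sd_decoupled: float = 1.5
    expression_decoupled_log2_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.n_loci < 0 or self.n_genes < 0:
            raise ValueError("n_loci and n_genes must be non-negative")
        if self.depth_mean < self.min_locus_depth:
            raise ValueError("depth_mean must be >= min_locus_depth clamp")
        if sum(self.archetype_weights) <= 0 or min(self.archetype_weights) < 0:
            raise ValueError("archetype weights must be non-negative, not all 0")
        for frac, cat in list(self.planted_events) + list(self.relapse_events):
            if cat not in EVENT_CATEGORIES:
                raise ValueError(f"unknown event category {cat!r}")
            if not 0 <= frac <= 1:
                raise ValueError("event fractions must lie in [0, 1]")
        for events in (self.planted_events, self.relapse_events):
            if sum(f for f, _ in events) > 1 + 1e-12:
                raise ValueError("planted event fractions must sum to <= 1")
        if not 0 <= self.pmd_genome_fraction <= 1:
            raise ValueError("pmd_genome_fraction must lie in [0, 1]")
        if not 0 <= self.cpg_dropout_rate < 1:
            raise ValueError("cpg_dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class LocusTruth:
    """Ground truth for one simulated locus."""

    locus: EpialleleLocus
    role: str  # 'shift' or 'gene_promoter'
    category: str  # planted NPC->diagnosis event, or 'null'
    relapse_category: str
    npc_dist: np.ndarray  # shared NPC baseline (before per-replicate jitter)
    diagnosis_dist: np.ndarray
    relapse_dist: np.ndarray
    in_pmd: bool

    def delta_s_true(self, entropy_scale: float = 25.0) -> float:
        """Entropy difference diagnosis - baseline at infinite depth."""
        return entropy(self.diagnosis_dist, entropy_scale) - entropy(
            self.npc_dist, entropy_scale
        )

    def pdr_true(self, stage: str = "diagnosis") -> float:
        dist = {
            "npc": self.npc_dist,
            "diagnosis": self.diagnosis_dist,
            "relapse": self.relapse_dist,
        }[stage]
        return float(1.0 - dist[0] - dist[N_PATTERNS - 1])


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    locus_id: str
    coupling: str  # 'coupled' or 'decoupled'
    methylation_state: str  # 'hypo' or 'hyper'
    promoter_pdr_true: float


@dataclass
class SyntheticCohort:
    """In-memory cohort: per-sample pattern counts plus ground truth.

    Reads are materialized lazily per sample (:meth:`reads`) to keep large
    multi-sample cohorts cheap when only some samples are analyzed.
    """

    config: SimulationConfig
    samples: list[str]
    locus_truths: list[LocusTruth]
    gene_truths: list[GeneTruth]
    counts: dict[str, np.ndarray]  # sample -> (n_total_loci, 16) int array
    genes: list[GeneModel]
    expression: ExpressionTable
    pmds: GenomicRegionSet
    cgis: GenomicRegionSet
    chromosome_sizes: dict[str, int]

    @property
    def loci(self) -> list[EpialleleLocus]:
        return [t.locus for t in self.locus_truths]

    def reads(self, sample: str, rng: np.random.Generator | None = None) -> list[EpiRead]:
        """Materialize epireads for one sample from its pattern counts.

        ``rng`` is only consulted when ``cpg_dropout_rate > 0``; by default
        a generator derived from the cohort seed and sample name is used so
        repeated calls are reproducible.
        """
        cfg = self.config
        if rng is None:
            salt = sum(ord(c) for c in sample)
            rng = np.random.default_rng((cfg.seed, 7919, salt))
        out: list[EpiRead] = []
        for li, truth in enumerate(self.locus_truths):
            locus = truth.locus
            pos = np.asarray(locus.cpg_positions, dtype=np.int64)
            counts = self.counts[sample][li]
            ridx = 0
            for pattern in np.repeat(np.arange(N_PATTERNS), counts):
                calls = np.array(decode_pattern(int(pattern)), dtype=np.int8)
                if cfg.cpg_dropout_rate > 0:
                    drop = rng.random(4) < cfg.cpg_dropout_rate
                    calls = np.where(drop, np.int8(-1), calls)
                out.append(
                    EpiRead(
                        locus.chrom,
                        f"{sample}:{locus.locus_id}:{ridx}",
                        pos,
                        calls,
                    )
                )
                ridx += 1
        return out

    def counts_for(self, sample: str) -> list:
        """Pattern counts of one sample as :class:`~epihet.loci.PatternCounts`."""
        from .loci import PatternCounts

        return [
            PatternCounts(t.locus, self.counts[sample][i])
            for i, t in enumerate(self.locus_truths)
        ]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the cohort in the pipeline's on-disk dialects."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sample in self.samples:
            p = out_dir / f"{sample}.epiread"
            write_epireads(self.reads(sample), p)
            paths[sample] = p
        paths["pmd"] = out_dir / "pmd.bed"
        write_bed(self.pmds, paths["pmd"])
        paths["cgi"] = out_dir / "cgi.bed"
        write_bed(self.cgis, paths["cgi"])
        paths["genes"] = out_dir / "genes.tsv"
        write_gene_models(self.genes, paths["genes"])
        paths["expression"] = out_dir / "expression.tsv"
        write_expression(self.expression, paths["expression"])
        paths["truth"] = out_dir / "truth_loci.tsv"
        self._write_truth(paths["truth"])
        paths["truth_genes"] = out_dir / "truth_genes.tsv"
        self._write_gene_truth(paths["truth_genes"])
        return paths

    def _write_truth(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "#locus_id\trole\tcategory\trelapse_category\tin_pmd\t"
                "delta_s_true\tnpc_dist\tdiagnosis_dist\trelapse_dist\n"
            )
            for t in self.locus_truths:
                fh.write(
                    f"{t.locus.locus_id}\t{t.role}\t{t.category}\t"
                    f"{t.relapse_category}\t{int(t.in_pmd)}\t"
                    f"{t.delta_s_true():.6f}\t"
                    + "\t".join(
                        ",".join(f"{p:.6f}" for p in d)
                        for d in (t.npc_dist, t.diagnosis_dist, t.relapse_dist)
                    )
                    + "\n"
                )

    def _write_gene_truth(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("#gene_id\tlocus_id\tcoupling\tmethylation_state\tpromoter_pdr_true\n")
            for g in self.gene_truths:
                fh.write(
                    f"{g.gene_id}\t{g.locus_id}\t{g.coupling}\t"
                    f"{g.methylation_state}\t{g.promoter_pdr_true:.6f}\n"
                )


# ---------------------------------------------------------------------------
# distribution archetypes and event realizations
# ---------------------------------------------------------------------------

def _bimodal_concordant(rng: np.random.Generator) -> np.ndarray:
    """Mass mostly on the fully-U and fully-M patterns (concordant mix)."""
    w = rng.beta(0.3, 0.3)
    leak = 0.02
    p = np.full(N_PATTERNS, leak / (N_PATTERNS - 2))
    p[0] = (1 - leak) * (1 - w)
    p[N_PATTERNS - 1] = (1 - leak) * w
    return p


def _dominant(
    rng: np.random.Generator,
    pattern: int | None = None,
    lo: float = 0.80,
    hi: float = 0.95,
) -> np.ndarray:
    if pattern is None:
        pattern = int(rng.integers(N_PATTERNS))
    top = rng.uniform(lo, hi)
    rest = rng.dirichlet(np.ones(N_PATTERNS - 1)) * (1 - top)
    p = np.empty(N_PATTERNS)
    p[:pattern] = rest[:pattern]
    p[pattern] = top
    p[pattern + 1 :] = rest[pattern:]
    return p


def _disordered(
    rng: np.random.Generator, alpha: float, max_p: float = 0.25
) -> np.ndarray:
    """Dirichlet draw conditioned on having no predominant pattern."""
    for _ in range(1000):
        p = rng.dirichlet(np.full(N_PATTERNS, alpha))
        if p.max() < max_p:
            return p
    raise RuntimeError(
        f"could not draw a disordered distribution with max < {max_p} "
        f"at alpha={alpha}"
    )


def _near_uniform(rng: np.random.Generator) -> np.ndarray:
    return rng.dirichlet(np.full(N_PATTERNS, 60.0))


def _strong_dominant(
    rng: np.random.Generator, pattern: int | None = None
) -> np.ndarray:
    return _dominant(rng, pattern, lo=0.97, hi=0.995)


def jitter(
    dist: np.ndarray, rng: np.random.Generator, concentration: float
) -> np.ndarray:
    """Dirichlet perturbation centered on ``dist``."""
    return rng.dirichlet(np.asarray(dist) * concentration + 1e-2)


def _baseline(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    w = np.asarray(cfg.archetype_weights, dtype=float)
    kind = rng.choice(3, p=w / w.sum())
    if kind == 0:
        return _bimodal_concordant(rng)
    if kind == 1:
        return _dominant(rng)
    return _disordered(rng, cfg.dirichlet_alpha, max_p=1.0)


def realize_event(
    category: str,
    baseline: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (stage1, stage2) true distributions for a planted event.

    For shift categories the baseline is replaced by the composition the
    category requires at stage 1; ``null`` keeps the supplied baseline.
    """
    if category == "null":
        return baseline, jitter(baseline, rng, cfg.null_jitter_concentration)
    if category == "hyper_shift":
        return _strong_dominant(rng, pattern=0), _near_uniform(rng)
    if category == "hypo_shift":
        return _strong_dominant(rng, pattern=N_PATTERNS - 1), _near_uniform(rng)
    if category == "disorder":
        return _strong_dominant(rng), _near_uniform(rng)
    if category == "selection":
        return _near_uniform(rng), _strong_dominant(rng)
    if category == "switch":
        k1 = int(rng.integers(N_PATTERNS))
        k2 = int((k1 + 1 + rng.integers(N_PATTERNS - 1)) % N_PATTERNS)
        return _dominant(rng, k1, 0.85, 0.95), _dominant(rng, k2, 0.85, 0.95)
    if category == "disorder_maintenance":
        return (
            _disordered(rng, 4.0, max_p=0.25),
            _disordered(rng, 4.0, max_p=0.25),
        )
    raise ValueError(f"unknown event category {category!r}")


def _gene_promoter_dist(
    rng: np.random.Generator, hyper: bool, decoupled: bool
) -> np.ndarray:
    """Promoter locus composition with extreme mean methylation.

    Coupled promoters are concordant (dominant fully-M or fully-U pattern,
    PDR ~ 0.05); decoupled promoters spread the same mean methylation over
    discordant patterns (PDR ~ 0.8).
    """
    if not decoupled:
        return _dominant(rng, N_PATTERNS - 1 if hyper else 0, 0.92, 0.97)
    # disordered support with popcount 3..4 (hyper, mean meth ~0.8)
    # or 0..1 (hypo, mean meth ~0.2)
    support = (
        np.flatnonzero(PATTERN_POPCOUNT >= 3)
        if hyper
        else np.flatnonzero(PATTERN_POPCOUNT <= 1)
    )
    p = np.zeros(N_PATTERNS)
    p[support] = rng.dirichlet(np.full(support.size, 30.0))
    return p


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _plant_categories(
    n: int, events: tuple[tuple[float, str], ...], rng: np.random.Generator
) -> list[str]:
    categories = ["null"] * n
    order = rng.permutation(n)
    cursor = 0
    for frac, cat in events:
        k = int(round(frac * n))
        for i in order[cursor : cursor + k]:
            categories[i] = cat
        cursor += k
    return categories


def _pmd_regions(
    chrom: str, size: int, cfg: SimulationConfig, rng: np.random.Generator
) -> list[GenomicInterval]:
    """Alternating PMD / non-PMD segments targeting the genome fraction."""
    f = cfg.pmd_genome_fraction
    if f == 0:
        return []
    if f == 1:
        return [GenomicInterval(chrom, 0, size)]
    out = []
    pos = 0
    in_pmd = rng.random() < f
    mean_out = cfg.pmd_length_mean * (1 - f) / f
    while pos < size:
        mean = cfg.pmd_length_mean if in_pmd else mean_out
        length = max(200, int(rng.exponential(mean)))
        end = min(size, pos + length)
        if in_pmd:
            out.append(GenomicInterval(chrom, pos, end))
        pos = end
        in_pmd = not in_pmd
    return out


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticCohort:
    """Generate a full cohort; optionally write it to ``out_dir``.

    Deterministic given the config (all randomness flows from
    ``config.seed`` through a single generator).  Samples are named
    ``NPC1..NPCn``, ``MMD`` (diagnosis) and ``MMR`` (relapse).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = [f"NPC{i + 1}" for i in range(cfg.n_npc)] + ["MMD", "MMR"]

    # --- locus layout: background shift loci spread over chromosomes,
    #     gene promoter loci on a dedicated chromosome
    locus_truths: list[LocusTruth] = []
    placements: list[tuple[str, int]] = []  # (chrom, start position)
    chrom_sizes: dict[str, int] = {}
    n_chrom = max(1, cfg.n_chromosomes)
    per_chrom = -(-cfg.n_loci // n_chrom) if cfg.n_loci else 0
    for ci in range(n_chrom):
        chrom = f"chrS{ci + 1}"
        n_here = min(per_chrom, cfg.n_loci - ci * per_chrom) if cfg.n_loci else 0
        n_here = max(0, n_here)
        chrom_sizes[chrom] = max((n_here + 1) * cfg.locus_spacing, 10 * cfg.locus_spacing)
        for li in range(n_here):
            placements.append((chrom, (li + 1) * cfg.locus_spacing))
    gene_chrom = "chrSG"
    gene_spacing = max(cfg.locus_spacing, 12000)  # keep promoters distinct
    chrom_sizes[gene_chrom] = max((cfg.n_genes + 1) * gene_spacing, 10 * gene_spacing)

    def make_locus(chrom: str, start: int) -> EpialleleLocus:
        gaps = rng.integers(4, 30, size=3)
        pos = start + np.concatenate(([0], np.cumsum(gaps)))
        return EpialleleLocus(chrom, tuple(int(p) for p in pos))

    # --- PMD segmentation (over shift chromosomes only; the gene
    #     chromosome gets its own so promoter loci also have membership)
    pmd_ivs: list[GenomicInterval] = []
    for chrom, size in chrom_sizes.items():
        pmd_ivs.extend(_pmd_regions(chrom, size, cfg, rng))
    pmds = GenomicRegionSet(pmd_ivs)

    # --- background (shift-analysis) loci
    categories = _plant_categories(len(placements), cfg.planted_events, rng)
    relapse_categories = _plant_categories(
        len(placements), cfg.relapse_events, rng
    )
    for (chrom, start), cat, rcat in zip(placements, categories, relapse_categories):
        locus = make_locus(chrom, start)
        baseline = _baseline(cfg, rng)
        stage1, diagnosis = realize_event(cat, baseline, cfg, rng)
        # a relapse event redefines both its stages (diagnosis included)
        diagnosis, relapse = realize_event(rcat, diagnosis, cfg, rng)
        locus_truths.append(
            LocusTruth(
                locus=locus,
                role="shift",
                category=cat,
                relapse_category=rcat,
                npc_dist=stage1,
                diagnosis_dist=diagnosis,
                relapse_dist=relapse,
                in_pmd=pmds.contains(chrom, locus.center - 1),
            )
        )

    # --- gene promoter loci, genes, CGIs
    gene_truths: list[GeneTruth] = []
    genes: list[GeneModel] = []
    cgi_ivs: list[GenomicInterval] = []
    n_hyper = int(round(cfg.fraction_hyper_promoters * cfg.n_genes))
    n_decoupled = int(round(cfg.fraction_decoupled * cfg.n_genes))
    hyper_flags = np.zeros(cfg.n_genes, dtype=bool)
    hyper_flags[:n_hyper] = True
    rng.shuffle(hyper_flags)
    decoupled_flags = np.zeros(cfg.n_genes, dtype=bool)
    decoupled_flags[:n_decoupled] = True
    rng.shuffle(decoupled_flags)
    for gi in range(cfg.n_genes):
        start = (gi + 1) * gene_spacing
        locus = make_locus(gene_chrom, start)
        dist = _gene_promoter_dist(rng, bool(hyper_flags[gi]), bool(decoupled_flags[gi]))
        gene_id = f"G{gi + 1:04d}"
        tss = locus.center - 1  # 0-based TSS right at the promoter locus
        tts = tss + 5000
        genes.append(
            GeneModel(
                gene_id,
                gene_chrom,
                "+",
                tss,
                tts,
                ((tss, tss + 200), (tts - 800, tts)),
            )
        )
        cgi_ivs.append(
            GenomicInterval(gene_chrom, max(0, locus.start - 1 - 200), locus.end + 200)
        )
        pdr_true = float(1.0 - dist[0] - dist[N_PATTERNS - 1])
        gene_truths.append(
            GeneTruth(
                gene_id=gene_id,
                locus_id=locus.locus_id,
                coupling="decoupled" if decoupled_flags[gi] else "coupled",
                methylation_state="hyper" if hyper_flags[gi] else "hypo",
                promoter_pdr_true=pdr_true,
            )
        )
        locus_truths.append(
            LocusTruth(
                locus=locus,
                role="gene_promoter",
                category="null",
                relapse_category="null",
                npc_dist=dist,
                diagnosis_dist=dist,
                relapse_dist=dist,
                in_pmd=pmds.contains(gene_chrom, locus.center - 1),
            )
        )
    cgis = GenomicRegionSet(cgi_ivs)

    # --- per-sample pattern counts
    n_total = len(locus_truths)
    counts = {s: np.zeros((n_total, N_PATTERNS), dtype=np.int64) for s in samples}
    for li, truth in enumerate(locus_truths):
        for sample in samples:
            if sample.startswith("NPC"):
                dist = jitter(truth.npc_dist, rng, cfg.npc_jitter_concentration)
            elif sample == "MMD":
                dist = truth.diagnosis_dist
            else:
                dist = truth.relapse_dist
            depth = max(cfg.min_locus_depth, int(rng.poisson(cfg.depth_mean)))
            counts[sample][li] = rng.multinomial(depth, dist)

    # --- expression
    expression = simulate_expression(
        gene_truths, locus_truths, samples, cfg, rng
    )

    cohort = SyntheticCohort(
        config=cfg,
        samples=samples,
        locus_truths=locus_truths,
        gene_truths=gene_truths,
        counts=counts,
        genes=genes,
        expression=expression,
        pmds=pmds,
        cgis=cgis,
        chromosome_sizes=chrom_sizes,
    )
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


def simulate_expression(
    gene_truths: list[GeneTruth],
    locus_truths: list[LocusTruth],
    samples: list[str],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> ExpressionTable:
    """FPM table whose methylation coupling depends on promoter PDR.

    Coupled genes: ``log2 FPM = base - slope * promoter_methylation +
    N(0, sd_coupled)``.  Decoupled genes: ``log2 FPM ~
    N(decoupled_mean, sd_decoupled)``, independent of methylation and with
    larger spread (the excess expression variability of disordered
    promoters).
    """
    meth_by_locus = {}
    for t in locus_truths:
        if t.role == "gene_promoter":
            meth_by_locus[t.locus.locus_id] = float(
                np.dot(t.diagnosis_dist, PATTERN_POPCOUNT) / 4.0
            )
    data = np.zeros((len(gene_truths), len(samples)))
    for gi, g in enumerate(gene_truths):
        meth = meth_by_locus[g.locus_id]
        for si in range(len(samples)):
            if g.coupling == "coupled":
                mu = cfg.expression_log2_base - cfg.expression_log2_slope * meth
                x = mu + rng.normal(0, cfg.expression_noise_sd_coupled)
            else:
                x = cfg.expression_decoupled_log2_mean + rng.normal(
                    0, cfg.expression_noise_sd_decoupled
                )
            data[gi, si] = 2.0**x
    df = pd.DataFrame(
        data, index=[g.gene_id for g in gene_truths], columns=samples
    )
    return ExpressionTable(df)
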