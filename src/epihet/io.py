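"""On-disk formats for read-level methylation analysis.

All parsers are strict about coordinate conventions:

* per-CpG positions are **1-based** (the position of the C on the + strand;
  G-strand calls are assumed collapsed onto the C by the upstream caller);
* interval files (BED) are **0-based half-open**.

The epiread dialect is a TSV with one row per sequenced fragment (one row
per read *pair* for paired-end data): chromosome, read id, comma-separated
CpG positions, and a call string over ``M`` (methylated), ``U``
(unmethylated) and ``.`` (missing/low quality).  An optional fifth column
carries comma-separated PHRED base qualities; calls below ``min_base_quality``
are demoted to missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: call codes used throughout the package
METHYLATED: int = 1
UNMETHYLATED: int = 0
MISSING: int = -1

_CALL_FROM_CHAR = {"M": METHYLATED, "U": UNMETHYLATED, ".": MISSING}
_CHAR_FROM_CALL = {v: k for k, v in _CALL_FROM_CHAR.items()}

#: default PHRED threshold applied when an epiread file carries qualities
DEFAULT_MIN_BASE_QUALITY = 20


class ParseError(ValueError):
    """A malformed record in an input file, with its line number."""


@dataclass(frozen=True)
class EpiRead:
    """Ordered CpG methylation calls carried by a single read (pair).

    Parameters
    ----------
    chrom
        Chromosome name.
    read_id
        Opaque identifier; uniqueness is not enforced.
    cpg_positions
        Strictly ascending 1-based positions of the C of each CpG.
    calls
        One of :data:`METHYLATED`, :data:`UNMETHYLATED`, :data:`MISSING`
        per position.
    """

    chrom: str
    read_id: str
    cpg_positions: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.cpg_positions, dtype=np.int64)
        calls = np.asarray(self.calls, dtype=np.int8)
        object.__setattr__(self, "cpg_positions", pos)
        object.__setattr__(self, "calls", calls)
        if pos.size == 0:
            raise ValueError("epiread must cover at least one CpG")
        if calls.shape != pos.shape:
            raise ValueError(
                f"length mismatch: {pos.size} positions vs {calls.size} calls"
            )
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("CpG positions must be strictly ascending")
        if not np.all(np.isin(calls, (METHYLATED, UNMETHYLATED, MISSING))):
            raise ValueError("calls must be METHYLATED/UNMETHYLATED/MISSING")

    @property
    def n_cpgs(self) -> int:
        return int(self.cpg_positions.size)

    def call_string(self) -> str:
        return "".join(_CHAR_FROM_CALL[int(c)] for c in self.calls)


@dataclass(frozen=True)
class CpGMethylationRecord:
    """Per-CpG methylation counts (bedGraph-like, 1-based position)."""

    chrom: str
    pos: int
    methylated_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.total_count <= 0:
            raise ValueError("total_count must be positive")
        if not 0 <= self.methylated_count <= self.total_count:
            raise ValueError("methylated_count must be in [0, total_count]")

    @property
    def methylation_level(self) -> float:
        return self.methylated_count / self.total_count


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


class GenomicRegionSet:
    """A per-chromosome sorted collection of intervals (BED semantics).

    Overlapping input intervals are preserved as-is; :meth:`merge` returns a
    flattened copy.  Set algebra is delegated to :mod:`pyranges`.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        ivs = list(intervals)
        ivs.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        self._intervals: list[GenomicInterval] = ivs
        self._merged_index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    # -- basic container protocol ------------------------------------
    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomicRegionSet):
            return NotImplemented
        return [(iv.chrom, iv.start, iv.end) for iv in self] == [
            (iv.chrom, iv.start, iv.end) for iv in other
        ]

    def chromosomes(self) -> list[str]:
        return sorted({iv.chrom for iv in self._intervals})

    # -- pyranges bridge ----------------------------------------------
    def to_pyranges(self):
        import pyranges as pr

        if not self._intervals:
            return pr.PyRanges(
                pd.DataFrame({"Chromosome": [], "Start": [], "End": []})
            )
        df = pd.DataFrame(
            {
                "Chromosome": [iv.chrom for iv in self._intervals],
                "Start": [iv.start for iv in self._intervals],
                "End": [iv.end for iv in self._intervals],
            }
        )
        return pr.PyRanges(df)

    @classmethod
    def from_pyranges(cls, gr) -> "GenomicRegionSet":
        df = gr.df
        if df.empty:
            return cls()
        return cls(
            GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End))
            for r in df.itertuples()
        )

    @classmethod
    def from_tuples(
        cls, tuples: Iterable[tuple[str, int, int]]
    ) -> "GenomicRegionSet":
        return cls(GenomicInterval(c, s, e) for c, s, e in tuples)

    # -- set algebra ---------------------------------------------------
    def merge(self) -> "GenomicRegionSet":
        if not self._intervals:
            return GenomicRegionSet()
        return self.from_pyranges(self.to_pyranges().merge())

    def intersect(self, other: "GenomicRegionSet") -> "GenomicRegionSet":
        if not self._intervals or not len(other):
            return GenomicRegionSet()
        return self.from_pyranges(self.to_pyranges().intersect(other.to_pyranges()))

    def subtract(self, other: "GenomicRegionSet") -> "GenomicRegionSet":
        if not self._intervals:
            return GenomicRegionSet()
        if not len(other):
            return self.merge()
        return self.from_pyranges(self.to_pyranges().subtract(other.to_pyranges()))

    def union(self, other: "GenomicRegionSet") -> "GenomicRegionSet":
        return GenomicRegionSet(list(self) + list(other)).merge()

    def total_bases(self) -> int:
        """Number of distinct bases covered (overlaps merged first)."""
        return sum(len(iv) for iv in self.merge())

    def _index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self._merged_index is None:
            idx: dict[str, tuple[list[int], list[int]]] = {}
            for iv in self.merge():
                idx.setdefault(iv.chrom, ([], []))
                idx[iv.chrom][0].append(iv.start)
                idx[iv.chrom][1].append(iv.end)
            self._merged_index = {
                c: (np.asarray(s), np.asarray(e)) for c, (s, e) in idx.items()
            }
        return self._merged_index

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 0-based point coordinate."""
        idx = self._index().get(chrom)
        if idx is None:
            return False
        starts, ends = idx
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]

    def containing_interval(self, chrom: str, pos: int) -> GenomicInterval | None:
        """Merged interval containing a 0-based point, or None."""
        idx = self._index().get(chrom)
        if idx is None:
            return None
        starts, ends = idx
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return GenomicInterval(chrom, int(starts[i]), int(ends[i]))
        return None


@dataclass
class ExpressionTable:
    """Gene-by-sample FPM matrix (fragments per million, non-negative)."""

    data: pd.DataFrame  # index = gene_id, columns = sample names

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("FPM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def fpm(self, gene_id: str, sample: str) -> float:
        return float(self.data.at[gene_id, sample])


# ---------------------------------------------------------------------------
# epiread dialect
# ---------------------------------------------------------------------------

def parse_epiread_line(
    line: str,
    lineno: int = 0,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> EpiRead:
    fields = line.rstrip("\n").split("\t")
    if len(fields) not in (4, 5):
        raise ParseError(
            f"line {lineno}: expected 4 or 5 tab-separated fields, got {len(fields)}"
        )
    chrom, read_id, pos_field, call_field = fields[:4]
    try:
        positions = np.array([int(p) for p in pos_field.split(",")], dtype=np.int64)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: bad position field {pos_field!r}") from exc
    try:
        calls = np.array([_CALL_FROM_CHAR[c] for c in call_field], dtype=np.int8)
    except KeyError as exc:
        raise ParseError(
            f"line {lineno}: invalid call character in {call_field!r}"
        ) from exc
    if calls.size != positions.size:
        raise ParseError(
            f"line {lineno}: length mismatch ({positions.size} positions, "
            f"{calls.size} calls)"
        )
    if len(fields) == 5:
        try:
            quals = np.array([int(q) for q in fields[4].split(",")], dtype=np.int64)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad quality field") from exc
        if quals.size != positions.size:
            raise ParseError(f"line {lineno}: quality field length mismatch")
        calls = np.where(quals < min_base_quality, MISSING, calls).astype(np.int8)
    try:
        return EpiRead(chrom, read_id, positions, calls)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def parse_epireads(
    path: str | Path,
    strict: bool = True,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> Iterator[EpiRead]:
    """Stream :class:`EpiRead` records from an epiread TSV, in file order.

    With ``strict=False`` malformed lines are skipped with a warning rather
    than aborting the parse.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                yield parse_epiread_line(line, lineno, min_base_quality)
            except ParseError:
                if strict:
                    raise
                logger.warning("skipping malformed epiread at %s:%d", path, lineno)


def write_epireads(reads: Iterable[EpiRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tread_id\tcpg_positions\tcalls\n")
        for r in reads:
            fh.write(
                f"{r.chrom}\t{r.read_id}\t"
                f"{','.join(str(p) for p in r.cpg_positions)}\t{r.call_string()}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def parse_bed(path: str | Path) -> GenomicRegionSet:
    """Parse BED3/BED6 into a sorted region set (overlaps preserved)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: BED needs at least 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(
                    f"line {lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else None
            intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
    return GenomicRegionSet(intervals)


def write_bed(regions: GenomicRegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# per-CpG counts, expression, pattern tables
# ---------------------------------------------------------------------------

def parse_cpg_bedgraph(path: str | Path) -> Iterator[CpGMethylationRecord]:
    """Per-CpG counts: chrom, pos (1-based), methylated_count, total_count."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ParseError(f"line {lineno}: expected 4 fields")
            try:
                rec = CpGMethylationRecord(
                    fields[0], int(fields[1]), int(fields[2]), int(fields[3])
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            yield rec


def write_cpg_bedgraph(
    records: Iterable[CpGMethylationRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tmethylated_count\ttotal_count\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.methylated_count}\t{r.total_count}\n")


def parse_expression(path: str | Path) -> ExpressionTable:
    """Expression TSV: header ``gene_id <sample> ...``, one row per gene."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.columns.empty:
        raise ParseError("expression table has no sample columns")
    if (df.to_numpy() < 0).any():
        raise ParseError("negative FPM value in expression table")
    return ExpressionTable(df)


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


# ---------------------------------------------------------------------------
# pattern tables (defined here so every on-disk dialect lives in one module;
# the PatternCounts container itself lives in epihet.loci)
# ---------------------------------------------------------------------------

PATTERN_TABLE_COLUMNS = (
    ["chrom", "start", "end", "positions"] + [f"n{i}" for i in range(16)]
)


def write_pattern_table(pattern_counts: Sequence, path: str | Path) -> None:
    """Write locus pattern counts as TSV (start/end are the 1-based first
    and last CpG positions; ``positions`` the comma-joined 4 CpGs)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PATTERN_TABLE_COLUMNS) + "\n")
        for pc in pattern_counts:
            loc = pc.locus
            fh.write(
                f"{loc.chrom}\t{loc.cpg_positions[0]}\t{loc.cpg_positions[-1]}\t"
                + ",".join(str(p) for p in loc.cpg_positions)
                + "\t"
                + "\t".join(str(int(c)) for c in pc.counts)
                + "\n"
            )


def read_pattern_table(path: str | Path) -> list:
    from .loci import EpialleleLocus, PatternCounts

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(PATTERN_TABLE_COLUMNS):
                raise ParseError(
                    f"line {lineno}: expected {len(PATTERN_TABLE_COLUMNS)} fields"
                )
            positions = tuple(int(p) for p in fields[3].split(","))
            counts = np.array([int(c) for c in fields[4:]], dtype=np.int64)
            if (counts < 0).any():
                raise ParseError(f"line {lineno}: negative pattern count")
            locus = EpialleleLocus(fields[0], positions)
            if int(fields[1]) != positions[0] or int(fields[2]) != positions[-1]:
                raise ParseError(f"line {lineno}: start/end inconsistent with positions")
            out.append(PatternCounts(locus, counts))
    return out


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Minimal transcript model for annotation.

    ``tss``/``tts`` are 0-based point coordinates; exons are 0-based
    half-open intervals within the gene span.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.strand == "+" and self.tss > self.tts:
            raise ValueError("on + strand TSS must not exceed TTS")
        if self.strand == "-" and self.tss < self.tts:
            raise ValueError("on - strand TSS must not precede TTS")
        lo, hi = min(self.tss, self.tts), max(self.tss, self.tts)
        for s, e in self.exons:
            if s >= e:
                raise ValueError("empty exon")
            if s < lo or e > hi + 1:
                raise ValueError("exon outside gene span")


def parse_gene_models(path: str | Path) -> list[GeneModel]:
    """Gene TSV: gene_id, chrom, strand, tss, tts, exons ('s-e,s-e' or '.')."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ParseError(f"line {lineno}: expected >=5 fields")
            exons: tuple[tuple[int, int], ...] = ()
            if len(fields) > 5 and fields[5] not in (".", ""):
                exons = tuple(
                    (int(s), int(e))
                    for s, e in (x.split("-") for x in fields[5].split(","))
                )
            try:
                genes.append(
                    GeneModel(
                        fields[0], fields[1], fields[2],
                        int(fields[3]), int(fields[4]), exons,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tchrom\tstrand\ttss\ttts\texons\n")
        for g in genes:
            exon_field = (
                ",".join(f"{s}-{e}" for s, e in g.exons) if g.exons else "."
            )
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tts}\t{exon_field}\n"
            )
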