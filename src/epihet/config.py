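"""Analysis configuration.

Every numeric threshold used anywhere in the pipeline lives here so that a
run's parameters can be snapshotted into its outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path
from typing import Any


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and scales for the epiallele heterogeneity pipeline.

    Attributes
    ----------
    min_locus_depth
        Minimum reads covering all 4 CpGs for a locus to be called.
    min_cpg_coverage
        Minimum reads covering an individual CpG for it to enter the
        CpG map used for locus windowing.
    elocus_delta_s_threshold
        A locus is an elocus when the (signed or negated-absolute) entropy
        difference falls strictly below this value.
    meth_diff_threshold
        Minimum absolute locus methylation difference for a hyper-/
        hypomethylated call.
    dominant_threshold, minor_threshold
        Pattern-proportion cutoffs defining "highly predominant"
        (strictly above) and "no predominant pattern" (all strictly
        below) for the pattern-change categories.
    entropy_scale
        Per-locus entropy units per bit; with 4 CpGs and the default 25,
        combinatorial entropy S spans [-100, 0].
    elocus_on_absolute_delta_s
        When True, eloci are called on -|S2 - S1| so entropy shifts in
        either direction qualify; the default uses the signed S2 - S1.
    fpm_expressed_threshold
        FPM strictly above this marks a gene expressed.
    promoter_meth_low, promoter_meth_high
        Promoter mean-methylation cutoffs for the unmethylated /
        methylated classes of the expression odds-ratio table; genes in
        between are excluded.
    promoter_flank
        Half-width of the promoter window around the TSS (bp).
    shore_width, shelf_width
        Widths of the CpG-island shore and shelf annuli (bp).
    discordant_locus_fraction
        PDR cutoff above which a locus counts as predominantly
        discordant in sample summaries.
    n_controls
        Number of control (normal plasma cell) samples required for the
        consensus elocus rule.
    """

    min_locus_depth: int = 60
    min_cpg_coverage: int = 10
    elocus_delta_s_threshold: float = -70.0
    meth_diff_threshold: float = 0.25
    dominant_threshold: float = 0.70
    minor_threshold: float = 0.30
    entropy_scale: float = 25.0
    elocus_on_absolute_delta_s: bool = False
    fpm_expressed_threshold: float = 1.0
    promoter_meth_high: float = 0.75
    promoter_meth_low: float = 0.25
    promoter_flank: int = 2000
    shore_width: int = 2000
    shelf_width: int = 2000
    discordant_locus_fraction: float = 0.50
    n_controls: int = 3

    def __post_init__(self) -> None:
        if self.min_locus_depth < 1:
            raise ValueError("min_locus_depth must be >= 1")
        if self.min_cpg_coverage < 1:
            raise ValueError("min_cpg_coverage must be >= 1")
        if not 0 < self.minor_threshold < self.dominant_threshold < 1:
            raise ValueError(
                "need 0 < minor_threshold < dominant_threshold < 1"
            )
        if self.entropy_scale <= 0:
            raise ValueError("entropy_scale must be positive")
        if not 0 <= self.promoter_meth_low < self.promoter_meth_high <= 1:
            raise ValueError("promoter methylation cutoffs out of order")
        if self.meth_diff_threshold <= 0:
            raise ValueError("meth_diff_threshold must be positive")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Read a plain ``key = value`` config file (# comments allowed)."""
        values: dict[str, Any] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, raw = (s.strip() for s in line.split("=", 1))
            values[key] = _coerce(raw)
        return cls.from_dict(values)


def _coerce(raw: str) -> Any:
    low = raw.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        return raw


DEFAULT_CONFIG = AnalysisConfig()
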