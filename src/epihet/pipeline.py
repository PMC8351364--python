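"""End-to-end patient analysis.

Orchestrates the stages for the study design this package targets: a
tumor sample at diagnosis is compared against each of three normal
plasma-cell controls (consensus elocus rule), and against the matched
relapse sample; eloci are split by methylation direction and
pattern-change category, annotated by genomic context, and summarized.

Reports are plain dictionaries serialized as sorted-key JSON, with the
full configuration and input digests embedded so a run is reproducible
from its own output.  Timestamps are deliberately excluded: identical
inputs and configuration must produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

from . import __version__
from .annotation import ContextTracks, annotate_locus_center, build_context_tracks
from .config import AnalysisConfig, DEFAULT_CONFIG
from .io import GenomicRegionSet, parse_bed, parse_epireads, parse_gene_models
from .loci import PatternCounts, enumerate_loci
from .metrics import locus_metrics, sample_summary
from .shifts import (
    Direction,
    PairedLocusComparison,
    category_fractions,
    compare_samples,
    consensus_eloci,
)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    inputs: dict[str, str | Path],
    config: AnalysisConfig,
    seed: int | None = None,
) -> dict:
    """Run manifest: config snapshot, input digests and tool version."""
    return {
        "tool": "epihet",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "inputs": {name: file_digest(p) for name, p in sorted(inputs.items())},
    }


def _direction_counts(comparisons: Sequence[PairedLocusComparison]) -> dict:
    out = {d.value: 0 for d in Direction}
    for c in comparisons:
        out[c.direction.value] += 1
    return out


def _comparison_block(
    comparisons: Sequence[PairedLocusComparison],
) -> dict:
    eloci = [c for c in comparisons if c.is_elocus]
    n_shared = len(comparisons)
    block = {
        "n_shared_loci": n_shared,
        "n_eloci": len(eloci),
        "epm": 1e6 * len(eloci) / n_shared if n_shared else None,
        "eloci_direction_counts": _direction_counts(eloci),
    }
    if eloci:
        block["elocus_category_fractions"] = {
            cat.value: frac for cat, frac in category_fractions(eloci).items()
        }
    return block


def analyze_patient(
    npc_counts: Sequence[Sequence[PatternCounts]],
    diagnosis_counts: Sequence[PatternCounts],
    relapse_counts: Sequence[PatternCounts] | None = None,
    tracks: ContextTracks | None = None,
    region_sets: dict[str, GenomicRegionSet] | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict:
    """Core patient analysis on in-memory pattern counts.

    Returns a report dictionary with per-sample heterogeneity summaries,
    the consensus elocus set versus the controls, the diagnosis/relapse
    comparison, direction and category breakdowns, and (when annotation
    tracks or region sets are supplied) genomic-context breakdowns of the
    consensus eloci.
    """
    chroms = {pc.locus.chrom for pc in diagnosis_counts}
    for sample_counts in list(npc_counts) + (
        [relapse_counts] if relapse_counts else []
    ):
        sample_chroms = {pc.locus.chrom for pc in sample_counts}
        if chroms and sample_chroms and not (sample_chroms & chroms):
            raise ValueError(
                "sample shares no chromosome with the diagnosis sample: "
                f"{sorted(sample_chroms)}"
            )

    report: dict = {"samples": {}}
    sample_sets = {f"NPC{i + 1}": c for i, c in enumerate(npc_counts)}
    sample_sets["diagnosis"] = diagnosis_counts
    if relapse_counts is not None:
        sample_sets["relapse"] = relapse_counts
    for name, counts in sample_sets.items():
        metrics = [locus_metrics(pc, config) for pc in counts]
        report["samples"][name] = (
            sample_summary(metrics, config) if metrics else {"n_loci": 0}
        )

    # tumor vs each control; stage 1 = control, stage 2 = diagnosis
    npc_comparisons = []
    report["npc_comparisons"] = {}
    for i, control in enumerate(npc_counts):
        comps, _ = compare_samples(control, diagnosis_counts, config)
        npc_comparisons.append(comps)
        report["npc_comparisons"][f"NPC{i + 1}"] = _comparison_block(comps)

    consensus = consensus_eloci(npc_comparisons, config)
    # per-locus attributes of consensus eloci, read off the first control
    by_locus = {c.locus: c for c in npc_comparisons[0]} if npc_comparisons else {}
    consensus_comps = [by_locus[loc] for loc in consensus if loc in by_locus]
    consensus_comps.sort(key=lambda c: (c.locus.chrom, c.locus.cpg_positions))
    report["consensus"] = {
        "n_eloci": len(consensus),
        "direction_counts": _direction_counts(consensus_comps),
    }
    if consensus_comps:
        report["consensus"]["category_fractions"] = {
            cat.value: frac
            for cat, frac in category_fractions(consensus_comps).items()
        }

    if relapse_counts is not None:
        comps, _ = compare_samples(diagnosis_counts, relapse_counts, config)
        report["diagnosis_vs_relapse"] = _comparison_block(comps)

    if tracks is not None or region_sets:
        report["consensus"]["annotation"] = _annotate_eloci(
            consensus_comps, tracks, region_sets
        )

    report["config"] = config.to_dict()
    return report


def _annotate_eloci(
    comps: Sequence[PairedLocusComparison],
    tracks: ContextTracks | None,
    region_sets: dict[str, GenomicRegionSet] | None,
) -> dict:
    genic: dict[str, int] = {}
    cpg: dict[str, int] = {}
    in_region: dict[str, dict[str, int]] = {
        name: {"hyper": 0, "hypo": 0, "none": 0, "total": 0}
        for name in (region_sets or {})
    }
    for c in comps:
        if tracks is not None:
            ann = annotate_locus_center(c.locus, tracks)
            genic[ann.genic_feature.value] = genic.get(ann.genic_feature.value, 0) + 1
            cpg[ann.cpg_context.value] = cpg.get(ann.cpg_context.value, 0) + 1
        for name, regions in (region_sets or {}).items():
            if regions.contains(c.locus.chrom, c.locus.center - 1):
                in_region[name][c.direction.value] += 1
                in_region[name]["total"] += 1
    out: dict = {}
    if tracks is not None:
        out["genic_feature_counts"] = genic
        out["cpg_context_counts"] = cpg
    if region_sets:
        n_hyper = sum(c.direction is Direction.HYPER for c in comps)
        n_hypo = sum(c.direction is Direction.HYPO for c in comps)
        for name, counts in in_region.items():
            out[f"{name}_elocus_counts"] = counts
            out[f"{name}_fraction_of_hyper"] = (
                counts["hyper"] / n_hyper if n_hyper else None
            )
            out[f"{name}_fraction_of_hypo"] = (
                counts["hypo"] / n_hypo if n_hypo else None
            )
    return out


def run_patient_analysis(
    npc_files: Sequence[str | Path],
    diagnosis_file: str | Path,
    relapse_file: str | Path | None = None,
    genes_file: str | Path | None = None,
    cgi_file: str | Path | None = None,
    region_files: dict[str, str | Path] | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    out_dir: str | Path | None = None,
) -> dict:
    """File-level wrapper: parse, build loci, analyze, optionally write.

    With ``out_dir`` set, emits ``report.json`` plus per-sample
    ``loci_<sample>.tsv`` pattern tables and an ``eloci.bed`` (0-based)
    of the consensus eloci.
    """
    if len(npc_files) != config.n_controls:
        raise ValueError(
            f"expected {config.n_controls} control epiread files, got {len(npc_files)}"
        )
    inputs: dict[str, str | Path] = {
        f"npc{i + 1}": p for i, p in enumerate(npc_files)
    }
    inputs["diagnosis"] = diagnosis_file
    if relapse_file is not None:
        inputs["relapse"] = relapse_file

    npc_counts = [
        enumerate_loci(parse_epireads(p), config) for p in npc_files
    ]
    diagnosis_counts = enumerate_loci(parse_epireads(diagnosis_file), config)
    relapse_counts = (
        enumerate_loci(parse_epireads(relapse_file), config)
        if relapse_file is not None
        else None
    )

    tracks = None
    if genes_file is not None and cgi_file is not None:
        inputs["genes"] = genes_file
        inputs["cgi"] = cgi_file
        tracks = build_context_tracks(
            parse_gene_models(genes_file), parse_bed(cgi_file), config
        )
    region_sets = None
    if region_files:
        region_sets = {}
        for name, p in region_files.items():
            inputs[name] = p
            region_sets[name] = parse_bed(p)

    report = analyze_patient(
        npc_counts, diagnosis_counts, relapse_counts, tracks, region_sets, config
    )
    report["manifest"] = build_manifest(inputs, config)

    if out_dir is not None:
        write_report(report, npc_counts, diagnosis_counts, relapse_counts, out_dir, config)
    return report


def write_report(
    report: dict,
    npc_counts: Sequence[Sequence[PatternCounts]],
    diagnosis_counts: Sequence[PatternCounts],
    relapse_counts: Sequence[PatternCounts] | None,
    out_dir: str | Path,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> None:
    from .io import write_pattern_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(report_json(report))
    for i, counts in enumerate(npc_counts):
        write_pattern_table(counts, out_dir / f"loci_NPC{i + 1}.tsv")
    write_pattern_table(diagnosis_counts, out_dir / "loci_diagnosis.tsv")
    if relapse_counts is not None:
        write_pattern_table(relapse_counts, out_dir / "loci_relapse.tsv")

    # consensus eloci as BED (0-based half-open over the CpG span)
    comps = [
        c
        for c in compare_samples(npc_counts[0], diagnosis_counts, config)[0]
    ]
    consensus = consensus_eloci(
        [compare_samples(c, diagnosis_counts, config)[0] for c in npc_counts],
        config,
    )
    with open(out_dir / "eloci.bed", "w") as fh:
        for c in sorted(comps, key=lambda c: (c.locus.chrom, c.locus.cpg_positions)):
            if c.locus in consensus:
                fh.write(
                    f"{c.locus.chrom}\t{c.locus.start - 1}\t{c.locus.end}\t"
                    f"{c.locus.locus_id}\t{c.delta_s:.3f}\t{c.direction.value}\n"
                )


def report_json(report: dict) -> str:
    """Deterministic JSON serialization (sorted keys, fixed separators)."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"
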