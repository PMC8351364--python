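# epihet

Epiallele-based analysis of DNA methylation heterogeneity from read-level
bisulfite sequencing data.

A sequencing read that covers four adjacent CpGs carries one of 16 possible
methylation patterns (an *epiallele*). The composition of epialleles at a
locus measures epigenetic disorder in the cell population — information that
is invisible to average methylation. `epihet` implements the full analysis
chain:

- **Locus construction** — parse epiread-format files, derive the CpG map
  from the data, and enumerate 4-CpG epiallele loci (sliding windows of four
  consecutive mapped CpGs, read depth ≥ 60 by default).
- **Heterogeneity metrics** — per locus: epipolymorphism
  `Epi = 1 − Σ pᵢ²` (maximum 0.9375 at the uniform 16-pattern
  distribution), proportion of discordant reads (PDR), combinatorial entropy
  `S = 25 · Σ pᵢ log₂ pᵢ` (scaled to [−100, 0]), and mean methylation. An
  envelope utility gives the feasible epipolymorphism range at a given mean
  methylation.
- **Entropy shifts** — paired sample comparison: ΔS = S₂ − S₁ per shared
  locus, epigenetically shifted loci (*eloci*) at ΔS < −70, normalized as
  *EPM* (eloci per million shared loci), consensus calling against a panel
  of three controls (a locus must be an elocus versus every control),
  hyper-/hypo-methylated direction at a ±0.25 mean-methylation difference,
  and classification of each elocus's pattern change
  (disorder, selection, switch, disorder maintenance, unclassified).
- **Genomic annotation** — promoters (TSS ± 2 kb), TTS windows, exons,
  introns, CpG islands, shores (2 kb flanks) and shelves (next 2 kb), with
  deterministic precedence, plus arbitrary BED region sets (e.g. partially
  methylated domains).
- **Expression association** — gene-level promoter methylation/PDR from
  promoter loci, 2×2 expressed × methylated tables, odds ratios with
  Haldane–Anscombe correction and Woolf confidence intervals, stratified by
  promoter PDR.
- **Synthetic cohorts** — a fully seeded generator producing a
  three-control + diagnosis/relapse cohort with known per-locus truth
  (planted entropy shifts and pattern changes, coupled/decoupled promoter
  expression), used throughout the test suite.

## Worked example: library

Epiread format is tab-separated: chromosome, read id, comma-separated CpG
positions (1-based), and one call character per CpG (`M` methylated, `U`
unmethylated, `.` missing).

```python
from epihet.io import parse_epiread_line
from epihet.loci import enumerate_loci
from epihet.metrics import locus_metrics

lines = []
for i in range(40):
    lines.append(f"chr4\tr{i}\t163266538,163266541,163266549,163266552\tMUMU")
for i in range(40, 70):
    lines.append(f"chr4\tr{i}\t163266538,163266541,163266549,163266552\tMMMM")
reads = [parse_epiread_line(l) for l in lines]

(locus_counts,) = enumerate_loci(reads)
m = locus_metrics(locus_counts)
print(f"locus          {locus_counts.locus.locus_id}")
print(f"depth          {m.depth}")
print(f"epipolymorphism {m.epipolymorphism:.4f}")
print(f"PDR            {m.pdr:.4f}")
print(f"entropy S      {m.entropy:.2f}")
print(f"mean methylation {m.mean_methylation:.4f}")
```

Output:

```
locus          chr4:163266538-163266552
depth          70
epipolymorphism 0.4898
PDR            0.5714
entropy S      -24.63
mean methylation 0.7143
```

`MUMU` is a discordant pattern, so PDR counts those 40 of 70 reads
(0.5714); the two-pattern mixture gives `Epi = 1 − (4/7)² − (3/7)² = 0.4898`
and an entropy of one bit scaled by 25 times the binary entropy of 4/7.

## Worked example: command line

Simulate a cohort and run the end-to-end patient analysis (diagnosis vs.
three controls, plus the diagnosis/relapse pair):

```sh
$ epihet simulate --seed 7 --n-loci 50 --n-genes 20 --out-dir cohort
wrote 5 samples, 70 loci to cohort

$ epihet run \
    --npc cohort/NPC1.epiread --npc cohort/NPC2.epiread --npc cohort/NPC3.epiread \
    --diagnosis cohort/MMD.epiread --relapse cohort/MMR.epiread \
    --genes cohort/genes.tsv --cgi cohort/cgi.bed --pmd cohort/pmd.bed \
    --out-dir analysis
```

The output directory contains `report.json`, per-sample pattern tables and
the consensus eloci as BED:

```
$ cat analysis/eloci.bed
chrS1	16999	17070	chrS1:17000-17070	-92.289	hyper
chrS2	15999	16041	chrS2:16000-16041	-87.929	hypo
chrS2	19999	20064	chrS2:20000-20064	-97.997	none
```

Report highlights (from `analysis/report.json`):

```
samples.diagnosis: {"mean_epipolymorphism": 0.3903, "mean_pdr": 0.4856,
                    "fraction_loci_pdr_above_threshold": 0.5143, "n_loci": 70}
npc_comparisons.NPC1: {"n_shared_loci": 70, "n_eloci": 3, "epm": 42857.14,
                       "eloci_direction_counts": {"hyper": 1, "hypo": 1, "none": 1}}
consensus: {"n_eloci": 3,
            "category_fractions": {"disorder": 1.0, ...},
            "direction_counts": {"hyper": 1, "hypo": 1, "none": 1}}
```

The three consensus eloci are exactly the cohort's planted strong shifts
(one hyper, one hypo, one direction-free disorder event). Individual steps
are also available as subcommands: `epihet loci`, `metrics`, `compare`,
`consensus`, `annotate`, `associate`.

## Reproducing results

Reports are deterministic: identical inputs and configuration produce
byte-identical `report.json` files (no timestamps; the embedded manifest
records the tool version, configuration and SHA-256 digests of all inputs).
The simulator is fully seeded — `epihet simulate --seed N` writes the same
bytes every time.

```sh
pytest                                   # full suite, ~20 s
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the epipolymorphism extreme values by
running the actual pipeline (epiread text → loci → metrics) on constructed
inputs; the results are seed-invariant and exact.

See `docs/methods.md` for the statistical model, parameter defaults and
numerical choices.
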