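# Methods

This document records the statistical model implemented by `epihet`, the
default parameters, the scope of the synthetic-data generator, and the
numerical choices the implementation makes.

## Epiallele loci

A locus is a window of 4 consecutive CpGs. The CpG map is derived from the
data: a position enters the map when at least `min_cpg_coverage` (default
10) reads carry a determinate call there. Within each chromosome, every
run of consecutive mapped CpGs is scanned with stride-1 windows of length
4. A read contributes to a window only if it has a determinate (non-missing)
call at all four positions; windows with fewer than `min_locus_depth`
(default 60) contributing reads are discarded. Overlapping windows are
intentional — adjacent loci share up to 3 CpGs.

Patterns are encoded bitwise with the first genomic CpG as the most
significant bit: `UUUU → 0`, `MUUU → 8`, `MMMM → 15`. The pattern space is
exactly the integers 0–15, and encoding/decoding is bijective.

## Per-locus metrics

With `p₀ … p₁₅` the pattern proportions at a locus:

- **Epipolymorphism** `Epi = 1 − Σ pᵢ²`, ranging from 0 (single pattern)
  to `1 − 16·(1/16)² = 0.9375` (uniform).
- **PDR** (proportion of discordant reads) = fraction of reads carrying
  neither the fully unmethylated (0) nor fully methylated (15) pattern.
- **Combinatorial entropy** `S = scale · Σ pᵢ log₂ pᵢ` with
  `entropy_scale = 25` by default, so `S ∈ [−100, 0]`: 0 for a single
  pattern, −100 at the uniform distribution (log₂16 = 4 bits × 25). The
  scale is configurable; analyses that prefer raw bits can set it to 1.
  The elocus threshold below is calibrated to the default scale and should
  be rescaled together with it.
- **Mean methylation** = `Σ pᵢ · popcount(i) / 4`.

### Epipolymorphism envelope

For a given mean methylation `m`, the attainable epipolymorphism lies
between the concordant bimodal value `2m(1 − m)` (mass only on patterns 0
and 15 — the minimum over distributions whose discordant mass is zero) and
a maximum obtained by minimizing `Σ pᵢ²` subject to the mean constraint.
By symmetry the minimizer splits mass equally within each
methylated-CpG-count class (class sizes 1, 4, 6, 4, 1), reducing the
problem to a 5-variable quadratic program, solved with SciPy's SLSQP. The
test suite checks the solver against a closed-form active-set enumeration
(solving the KKT system on every support set), with agreement to 1e-6.

## Entropy shifts and eloci

For two samples sharing a locus, `ΔS = S₂ − S₁`. A locus is an *elocus*
when the effective ΔS is strictly below `elocus_delta_s_threshold`
(default −70, i.e. a loss of more than 2.8 bits at the default scale).

Two calling modes exist:

- **signed** (default): the criterion is `S₂ − S₁ < −70`; only entropy
  *losses* in the stage-1 → stage-2 direction are called. For
  control-versus-tumor comparisons (stage 1 = control) this calls loci
  where the tumor is *more ordered*; gains of disorder are invisible.
- **absolute** (`elocus_on_absolute_delta_s = True`): the criterion is
  `−|ΔS| < −70`, symmetric in the two samples. This mode calls any strong
  entropy change regardless of direction and is what the simulation
  recovery tests use, since planted events include both losses and gains.

Both modes are first-class because the signed convention matches the
historical definition of the statistic while the absolute convention is
what a symmetric "shift" notion requires; the report and the CLI
(`--absolute`) state which mode produced the numbers.

**EPM** normalizes elocus counts by comparison breadth:
`EPM = 10⁶ · E / C`, with `E` the number of eloci and `C` the number of
shared loci in the comparison. EPM is undefined (reported as null) when
`C = 0`.

**Consensus**: against a panel of `n_controls` (default 3) controls, the
consensus elocus set is the intersection — a locus must be an elocus
versus every control. Directionality uses the locus mean-methylation
difference: hyper if `meth₂ − meth₁ > 0.25`, hypo if `< −0.25`, otherwise
no direction.

### Pattern-change classification

Call a distribution *disordered* when its maximum proportion is strictly
below 0.30, and *dominated* when some proportion is strictly above 0.70.
For an elocus with stage-1 distribution `d₁` and stage-2 `d₂`:

| category | condition |
|---|---|
| disorder_maintenance | both disordered |
| selection | `d₁` disordered, `d₂` dominated |
| disorder | `d₁` dominated, `d₂` disordered |
| switch | both dominated, different dominant patterns |
| unclassified | anything else (including same dominant pattern twice) |

Thresholds are strict inequalities, so proportions exactly at 0.30 or 0.70
fall to `unclassified`; the tests probe 0.29/0.30/0.31 and 0.69/0.70/0.71.

## Genomic annotation

A locus is annotated at its center, `floor((first_cpg + last_cpg)/2)`
(1-based; converted to 0-based for interval membership). Two independent
labels with deterministic precedence:

- genic: `promoter_tss` (TSS ± `promoter_flank`, default 2 kb) >
  `tts` > `exon` > `intron` (gene span minus exons) > `intergenic`;
- CpG: `cgi` > `shore` (2 kb flanks minus islands) > `shelf` (the next
  2 kb, minus islands and shores) > `open_sea`.

Flanks are clipped at position 0. Shores and shelves are constructed per
merged island and then subtracted so the three classes are pairwise
disjoint even when islands crowd each other. Interval algebra is delegated
to pyranges behind a small `GenomicRegionSet` wrapper.

## Expression association

Per gene and sample, promoter methylation and PDR are the unweighted means
over loci whose center lies in TSS ± 2 kb. Genes are cross-tabulated as
expressed (`FPM > 1`) × methylated (promoter methylation `> 0.75`;
unmethylated `< 0.25`; intermediate promoters are excluded from the
table). The odds ratio is `ad/bc` with a Haldane–Anscombe +0.5 correction
applied to all cells when any cell is zero, and a 95% Woolf (log-scale
normal) confidence interval; the tests cross-check both against
statsmodels' `Table2x2`. Tables are computed separately for genes above
and at-or-below the cohort mean promoter PDR.

## Synthetic cohorts

The generator (`epihet.simulate`) produces a cohort of three control
samples (NPC1–3), a diagnosis sample (MMD) and a relapse sample (MMR),
with known truth at every locus:

- background loci mix three archetypes (concordant bimodal, single
  dominant pattern, Dirichlet-disordered) with weights 0.45/0.35/0.20;
- planted events (10% of background loci by default) rewrite the
  baseline → diagnosis pair: hyper/hypo shifts (a concordant dominant
  pattern collapsing into near-uniform disorder, |ΔS_true| ≈ 90–96 with a
  ≥ 25% methylation change), disorder, selection, switch, and
  disorder-maintenance events; an optional second event layer applies
  between diagnosis and relapse;
- controls draw Dirichlet jitter (concentration 400) around a shared
  baseline; read counts are multinomial at Poisson depth (mean 80,
  clamped at the 60-read locus floor so depth filtering never interacts
  with recovery measurements);
- gene promoters get dedicated loci: *coupled* promoters are concordant
  (PDR ≈ 0.05) with `log₂ FPM = 3 − 5·methylation + N(0, 0.5)`;
  *decoupled* promoters are disordered (PDR ≈ 0.8) with
  `log₂ FPM ~ N(0, 1.5)`, independent of methylation;
- PMD-like region sets are alternating exponential-length segments
  covering a target genome fraction (default 0.65).

Everything is driven by one `numpy` generator seeded from the config, so
identical configs write byte-identical files. Reads are materialized
lazily per sample; an optional per-CpG dropout rate demotes calls to
missing to exercise the determinate-at-all-4 rule.

**Scope**: the generator validates the analysis chain; it is not a
biological simulator. It has no sequencing error model, no strand or
fragment-length structure, no linkage between neighboring loci, and its
planted effect sizes are deliberately strong so that recovery measures the
pipeline rather than statistical power at marginal effect sizes.

## Validation problem sizes

The acceptance tests fix their own problem sizes:

- recovery: one 1,000-locus cohort at depth 100 (seed 1), absolute mode;
  sensitivity ≥ 0.9 on planted events with |ΔS_true| ≥ 90 and a ≤ 2%
  elocus rate on null loci;
- odds-ratio contrast: 20 cohorts (seeds 0–19) of 200 genes each; the
  low-PDR stratum's OR must fall below 1 in every replicate and the
  high-PDR stratum's confidence interval must cover 1 in at least 80% of
  replicates. 200 genes per replicate keeps the 2×2 cells large enough
  that the Woolf interval is informative on a single replicate.

## Numerical choices

- Pattern distributions must sum to 1 within 1e-9; proportions 1/16 and
  read-count ratios with power-of-two denominators are dyadic, so the
  extreme epipolymorphism values 0.9375 and 0 are exact in float64.
- PDR and mean methylation are ratios of integers and match per-read
  recomputation bitwise; epipolymorphism and entropy match per-read
  recomputation to float summation order (≤ 4 ulp / 1e-9 respectively).
- `0 log 0 = 0` in the entropy (zero-proportion terms are dropped).
- Reports serialize as sorted-key JSON with fixed separators and no
  timestamps; the manifest embeds SHA-256 input digests, the tool version
  and the full configuration.
- Quantile summaries default to numpy's `linear` interpolation; the
  convention is a parameter because discrete conventions (`nearest`)
  change third-quartile-style summaries noticeably on small inputs.

## Limitations

- Metrics are computed per 4-CpG window; no smoothing or aggregation
  across windows is attempted, and overlapping windows are not
  independent observations.
- Elocus calling is a fixed-threshold rule with no multiple-testing
  control; EPM comparisons across samples assume comparable shared-locus
  sets.
- The consensus rule is a hard intersection; a single noisy control
  removes a locus.
- Promoter-level methylation averages loci unweighted by depth.
- The expression association is a 2×2 odds ratio, not a regression; it
  discards intermediate-methylation promoters by design.
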