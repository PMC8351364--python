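"""Synthetic cohort generator: determinism, truth consistency, recovery."""

import filecmp

import numpy as np
import pytest

from epihet.config import AnalysisConfig
from epihet.loci import PATTERN_POPCOUNT, enumerate_loci
from epihet.metrics import entropy
from epihet.shifts import ChangeCategory, classify_change, compare_samples
from epihet.simulate import SimulationConfig, realize_event, simulate_cohort


class TestConfigValidation:
    def test_planted_fractions_must_sum_below_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(planted_events=((0.7, "null"), (0.6, "disorder")))

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(planted_events=((0.1, "teleportation"),))

    def test_depth_mean_must_cover_the_floor(self):
        with pytest.raises(ValueError):
            SimulationConfig(depth_mean=30.0)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_loci=20, n_genes=5)
        simulate_cohort(cfg, tmp_path / "a")
        simulate_cohort(cfg, tmp_path / "b")
        for name in sorted(p.name for p in (tmp_path / "a").iterdir()):
            assert filecmp.cmp(
                tmp_path / "a" / name, tmp_path / "b" / name, shallow=False
            ), name

    def test_different_seeds_differ(self, tmp_path):
        c1 = simulate_cohort(SimulationConfig(seed=1, n_loci=10, n_genes=0))
        c2 = simulate_cohort(SimulationConfig(seed=2, n_loci=10, n_genes=0))
        assert any(
            not np.array_equal(c1.counts["MMD"][i], c2.counts["MMD"][i])
            for i in range(10)
        )


class TestTruthConsistency:
    def test_planted_categories_classify_on_true_distributions(self, rng):
        cfg = SimulationConfig(seed=3)
        expected = {
            "selection": ChangeCategory.SELECTION,
            "disorder": ChangeCategory.DISORDER,
            "switch": ChangeCategory.SWITCH,
            "disorder_maintenance": ChangeCategory.DISORDER_MAINTENANCE,
        }
        for category, label in expected.items():
            for _ in range(20):
                d1, d2 = realize_event(category, None, cfg, rng)
                assert classify_change(d1, d2) is label

    def test_shift_events_have_strong_entropy_loss_and_direction(self, rng):
        cfg = SimulationConfig(seed=3)
        for category, sign in (("hyper_shift", 1), ("hypo_shift", -1)):
            for _ in range(20):
                d1, d2 = realize_event(category, None, cfg, rng)
                delta = entropy(d2, 25.0) - entropy(d1, 25.0)
                assert delta < -85.0
                meth_diff = float(
                    np.dot(d2 - d1, PATTERN_POPCOUNT) / 4.0
                )
                assert sign * meth_diff >= 0.25

    def test_every_planted_event_appears_in_truth(self):
        cfg = SimulationConfig(seed=7, n_loci=100, n_genes=0)
        cohort = simulate_cohort(cfg)
        planted = [t.category for t in cohort.locus_truths]
        for frac, category in cfg.planted_events:
            assert planted.count(category) == round(frac * 100)

    def test_depth_respects_the_sixty_read_clamp(self):
        cohort = simulate_cohort(
            SimulationConfig(seed=2, n_loci=50, n_genes=0, depth_mean=60.0)
        )
        for sample in cohort.samples:
            assert cohort.counts[sample].sum(axis=1).min() >= 60

    def test_pmd_membership_matches_regions(self):
        cohort = simulate_cohort(SimulationConfig(seed=4, n_loci=50, n_genes=10))
        for t in cohort.locus_truths:
            assert t.in_pmd == cohort.pmds.contains(
                t.locus.chrom, t.locus.center - 1
            )


class TestParameterRecovery:
    def test_empirical_distribution_close_to_truth_at_high_depth(self):
        cfg = SimulationConfig(
            seed=9, n_loci=20, n_genes=0, depth_mean=10_000.0
        )
        cohort = simulate_cohort(cfg)
        for i, truth in enumerate(cohort.locus_truths):
            counts = cohort.counts["MMD"][i]
            empirical = counts / counts.sum()
            tv = 0.5 * np.abs(empirical - truth.diagnosis_dist).sum()
            assert tv <= 0.02

    def test_npc_jitter_small_in_total_variation(self):
        cfg = SimulationConfig(seed=9, n_loci=30, n_genes=0, depth_mean=5000.0)
        cohort = simulate_cohort(cfg)
        tvs = []
        for i, truth in enumerate(cohort.locus_truths):
            counts = cohort.counts["NPC1"][i]
            empirical = counts / counts.sum()
            tvs.append(0.5 * np.abs(empirical - truth.npc_dist).sum())
        assert np.median(tvs) < 0.08


class TestNullCohort:
    def test_all_null_cohort_has_low_elocus_rate(self):
        cfg = SimulationConfig(
            seed=1, n_loci=500, n_genes=0, depth_mean=100.0, planted_events=()
        )
        cohort = simulate_cohort(cfg)
        config = AnalysisConfig(elocus_on_absolute_delta_s=True)
        comps, summary = compare_samples(
            cohort.counts_for("NPC1"), cohort.counts_for("MMD"), config
        )
        assert summary.n_shared_loci == 500
        assert summary.n_eloci / summary.n_shared_loci <= 0.02


class TestExpressionCoupling:
    def test_coupled_genes_anticorrelate_with_methylation(self):
        cfg = SimulationConfig(
            seed=1, n_loci=0, n_genes=300, fraction_decoupled=0.0
        )
        cohort = simulate_cohort(cfg)
        meth = {
            t.locus.locus_id: float(np.dot(t.diagnosis_dist, PATTERN_POPCOUNT) / 4)
            for t in cohort.locus_truths
        }
        x = np.array([meth[g.locus_id] for g in cohort.gene_truths])
        y = np.log2(
            np.array([
                cohort.expression.fpm(g.gene_id, "MMD") for g in cohort.gene_truths
            ])
        )
        r = np.corrcoef(x, y)[0, 1]
        assert r < -0.9

    def test_decoupled_genes_uncorrelated(self):
        cfg = SimulationConfig(
            seed=1, n_loci=0, n_genes=500, fraction_decoupled=1.0
        )
        cohort = simulate_cohort(cfg)
        meth = {
            t.locus.locus_id: float(np.dot(t.diagnosis_dist, PATTERN_POPCOUNT) / 4)
            for t in cohort.locus_truths
        }
        x = np.array([meth[g.locus_id] for g in cohort.gene_truths])
        y = np.log2(
            np.array([
                cohort.expression.fpm(g.gene_id, "MMD") for g in cohort.gene_truths
            ])
        )
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.1

    def test_zero_noise_coupled_is_exactly_monotone(self):
        cfg = SimulationConfig(
            seed=1, n_loci=0, n_genes=50, fraction_decoupled=0.0,
            expression_noise_sd_coupled=0.0,
        )
        cohort = simulate_cohort(cfg)
        meth = {
            t.locus.locus_id: float(np.dot(t.diagnosis_dist, PATTERN_POPCOUNT) / 4)
            for t in cohort.locus_truths
        }
        pairs = sorted(
            (meth[g.locus_id], cohort.expression.fpm(g.gene_id, "MMD"))
            for g in cohort.gene_truths
        )
        fpms = [fpm for _, fpm in pairs]
        assert all(a >= b - 1e-12 for a, b in zip(fpms, fpms[1:]))

    def test_promoter_pdr_separates_coupling_classes(self):
        cohort = simulate_cohort(SimulationConfig(seed=1, n_loci=0, n_genes=100))
        pdrs = {"coupled": [], "decoupled": []}
        for g in cohort.gene_truths:
            pdrs[g.coupling].append(g.promoter_pdr_true)
        assert max(pdrs["coupled"]) < min(pdrs["decoupled"])


class TestReadMaterialization:
    def test_reads_reproduce_pattern_counts(self):
        cfg = SimulationConfig(seed=6, n_loci=10, n_genes=0)
        cohort = simulate_cohort(cfg)
        loci = enumerate_loci(cohort.reads("MMD"))
        assert len(loci) == 10
        by_locus = {pc.locus: pc.counts for pc in loci}
        for i, truth in enumerate(cohort.locus_truths):
            assert np.array_equal(by_locus[truth.locus], cohort.counts["MMD"][i])

    def test_dropout_demotes_calls_to_missing(self):
        cfg = SimulationConfig(seed=6, n_loci=5, n_genes=0, cpg_dropout_rate=0.3)
        cohort = simulate_cohort(cfg)
        reads = cohort.reads("MMD")
        missing = sum((r.calls == -1).sum() for r in reads)
        total = sum(r.calls.size for r in reads)
        assert 0.2 < missing / total < 0.4
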