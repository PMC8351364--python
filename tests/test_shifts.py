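"""Entropy-shift algebra, elocus calling, consensus and classification."""

import numpy as np
import pytest

from epihet.config import AnalysisConfig
from epihet.loci import EpialleleLocus
from epihet.shifts import (
    ChangeCategory,
    Direction,
    category_fractions,
    classify_change,
    compare_locus,
    compare_samples,
    consensus_eloci,
    epm,
)

from conftest import make_counts


def dist(masses: dict[int, float]) -> np.ndarray:
    p = np.zeros(16)
    for k, v in masses.items():
        p[k] = v
    return p


SINGLE = make_counts({7: 60})
UNIFORM = make_counts({i: 4 for i in range(16)})


class TestDeltaS:
    def test_identical_distributions_no_shift(self):
        c = compare_locus(SINGLE, SINGLE)
        assert c.delta_s == 0.0
        assert not c.is_elocus

    def test_single_to_uniform_is_a_full_shift(self):
        c = compare_locus(SINGLE, UNIFORM)
        assert c.delta_s == pytest.approx(-100.0)
        assert c.is_elocus  # -100 < -70

    def test_signed_mode_antisymmetric(self):
        fwd = compare_locus(SINGLE, UNIFORM)
        rev = compare_locus(UNIFORM, SINGLE)
        assert fwd.delta_s == pytest.approx(-rev.delta_s)
        assert not rev.is_elocus  # entropy gain is invisible to the signed rule

    def test_absolute_mode_symmetric_and_nonpositive(self):
        config = AnalysisConfig(elocus_on_absolute_delta_s=True)
        fwd = compare_locus(SINGLE, UNIFORM, config)
        rev = compare_locus(UNIFORM, SINGLE, config)
        assert fwd.delta_s_effective == rev.delta_s_effective == pytest.approx(-100.0)
        assert fwd.is_elocus and rev.is_elocus

    def test_threshold_is_strict(self):
        # two patterns at 50/50 vs single: dS = -25; a -25 threshold must
        # not fire, anything looser must
        half = make_counts({0: 30, 15: 30})
        config = AnalysisConfig(elocus_delta_s_threshold=-25.0)
        assert not compare_locus(SINGLE, half, config).is_elocus
        config = AnalysisConfig(elocus_delta_s_threshold=-24.999)
        assert compare_locus(SINGLE, half, config).is_elocus

    def test_elocus_set_monotone_in_threshold(self, rng):
        pairs = []
        for _ in range(60):
            a = make_counts({int(k): int(v) for k, v in
                             enumerate(rng.multinomial(100, rng.dirichlet(np.ones(16) * 0.3)))
                             if v})
            b = make_counts({int(k): int(v) for k, v in
                             enumerate(rng.multinomial(100, rng.dirichlet(np.ones(16) * 0.3)))
                             if v})
            pairs.append((a, b))
        sets = {}
        for thr in (-60.0, -70.0, -90.0):
            config = AnalysisConfig(
                elocus_delta_s_threshold=thr, elocus_on_absolute_delta_s=True
            )
            sets[thr] = {
                i for i, (a, b) in enumerate(pairs)
                if compare_locus(a, b, config).is_elocus
            }
        assert sets[-90.0] <= sets[-70.0] <= sets[-60.0]

    def test_direction_thresholds(self):
        hypo = compare_locus(make_counts({15: 60}), make_counts({0: 45, 15: 15}))
        assert hypo.meth_diff == pytest.approx(-0.75)
        assert hypo.direction is Direction.HYPO
        small = compare_locus(make_counts({15: 60}), make_counts({15: 50, 14: 10}))
        assert small.direction is Direction.NONE


class TestEpm:
    @pytest.mark.parametrize(
        "e,c,expected", [(0, 10**6, 0.0), (250, 10**6, 250.0), (1, 2 * 10**6, 0.5)]
    )
    def test_examples(self, e, c, expected):
        assert epm(e, c) == expected

    def test_homogeneity_and_linearity(self):
        assert epm(500, 10**6) == epm(1000, 2 * 10**6)
        assert epm(1000, 10**6) == 2 * epm(500, 10**6)

    def test_undefined_without_coverage(self):
        with pytest.raises(ValueError):
            epm(0, 0)
        with pytest.raises(ValueError):
            epm(5, 3)


class TestCompareSamples:
    def _loci(self, n, chrom="chr1"):
        out = []
        for i in range(n):
            locus = EpialleleLocus(chrom, tuple(1000 * i + np.array([0, 10, 20, 30])))
            out.append(make_counts({15: 60}, locus))
        return out

    def test_shared_locus_matching_is_by_positions(self):
        a = self._loci(5)
        b = self._loci(3)
        comps, summary = compare_samples(a, b)
        assert summary.n_shared_loci == 3
        assert summary.n_eloci == 0
        assert summary.epm == 0.0

    def test_no_shared_loci_reports_missing_epm(self):
        comps, summary = compare_samples(self._loci(3, "chr1"), self._loci(3, "chr2"))
        assert comps == []
        assert summary.n_shared_loci == 0
        assert summary.epm is None


class TestConsensus:
    def _comparison(self, locus, elocus):
        a = make_counts({7: 60}, locus)
        b = make_counts({i: 4 for i in range(16)}, locus) if elocus else a
        return compare_locus(a, b)

    def test_requires_all_controls(self):
        l1 = EpialleleLocus("chr1", (10, 20, 30, 40))
        l2 = EpialleleLocus("chr1", (100, 120, 130, 150))
        comps = [
            [self._comparison(l1, True), self._comparison(l2, True)],
            [self._comparison(l1, True), self._comparison(l2, False)],
            [self._comparison(l1, True), self._comparison(l2, True)],
        ]
        assert consensus_eloci(comps) == {l1}

    def test_empty_lists_give_empty_set(self):
        assert consensus_eloci([[], [], []]) == set()

    def test_wrong_number_of_controls_is_a_config_error(self):
        with pytest.raises(ValueError, match="control"):
            consensus_eloci([[], []])
        config = AnalysisConfig(n_controls=2)
        assert consensus_eloci([[], []], config) == set()


class TestClassifier:
    def test_disorder_maintenance_boundary(self):
        # max proportion 0.29 at both stages: strictly below 0.30
        d = dist({0: 0.29, 1: 0.29, 2: 0.29, 3: 0.13})
        assert classify_change(d, d) is ChangeCategory.DISORDER_MAINTENANCE

    def test_max_at_030_is_not_disordered(self):
        d31 = dist({0: 0.31, 1: 0.25, 2: 0.25, 3: 0.19})
        d29 = dist({0: 0.29, 1: 0.29, 2: 0.29, 3: 0.13})
        assert classify_change(d31, d29) is ChangeCategory.UNCLASSIFIED
        d30 = dist({0: 0.30, 1: 0.25, 2: 0.25, 3: 0.20})
        assert classify_change(d30, d29) is ChangeCategory.UNCLASSIFIED

    def test_selection_requires_dominance_above_070(self):
        disordered = dist({i: 1 / 16 for i in range(16)})
        dominant71 = dist({5: 0.71, 0: 0.29})
        dominant69 = dist({5: 0.69, 0: 0.31})
        dominant70 = dist({5: 0.70, 0: 0.30})
        assert classify_change(disordered, dominant71) is ChangeCategory.SELECTION
        assert classify_change(disordered, dominant69) is ChangeCategory.UNCLASSIFIED
        assert classify_change(disordered, dominant70) is ChangeCategory.UNCLASSIFIED

    def test_disorder_is_the_reverse_of_selection(self):
        disordered = dist({i: 1 / 16 for i in range(16)})
        dominant = dist({5: 0.9, 0: 0.1})
        assert classify_change(dominant, disordered) is ChangeCategory.DISORDER

    def test_switch_requires_different_dominant_patterns(self):
        a = dist({3: 1.0})
        b = dist({12: 1.0})
        assert classify_change(a, b) is ChangeCategory.SWITCH
        assert classify_change(a, a) is ChangeCategory.UNCLASSIFIED

    def test_exactly_one_label(self, rng):
        for _ in range(100):
            p1 = rng.dirichlet(np.ones(16) * rng.uniform(0.1, 5))
            p2 = rng.dirichlet(np.ones(16) * rng.uniform(0.1, 5))
            assert classify_change(p1, p2) in ChangeCategory


class TestCategoryFractions:
    def _elocus(self, category):
        mapping = {
            ChangeCategory.SELECTION: (
                make_counts({i: 4 for i in range(16)}),
                make_counts({3: 60}),
            ),
            ChangeCategory.SWITCH: (make_counts({3: 60}), make_counts({12: 60})),
            ChangeCategory.UNCLASSIFIED: (make_counts({3: 60}), make_counts({3: 60})),
            ChangeCategory.DISORDER_MAINTENANCE: (
                make_counts({i: 4 for i in range(16)}),
                make_counts({i: 4 for i in range(16)}),
            ),
        }
        a, b = mapping[category]
        return compare_locus(a, b)

    def test_fraction_over_supplied_comparisons(self):
        comps = [
            self._elocus(ChangeCategory.SELECTION),
            self._elocus(ChangeCategory.SWITCH),
            self._elocus(ChangeCategory.SWITCH),
            self._elocus(ChangeCategory.UNCLASSIFIED),
        ]
        fractions = category_fractions(comps)
        assert fractions[ChangeCategory.SELECTION] == 0.25
        assert fractions[ChangeCategory.SWITCH] == 0.5
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_all_one_category(self):
        comps = [self._elocus(ChangeCategory.DISORDER_MAINTENANCE)] * 3
        assert category_fractions(comps)[ChangeCategory.DISORDER_MAINTENANCE] == 1.0

    def test_single_elocus_identity(self):
        comps = [self._elocus(ChangeCategory.SELECTION)]
        assert category_fractions(comps)[ChangeCategory.SELECTION] == 1.0

    def test_zero_eloci_undefined(self):
        with pytest.raises(ValueError):
            category_fractions([])
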