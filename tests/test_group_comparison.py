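"""ANOVA/Tukey chain, compact letters, fold-change and adult comparison."""

import numpy as np
import pytest

import juveri as jv
from juveri.panel_data import CALF_SUMMARY


class TestOneWayAnova:
    def test_identical_groups(self):
        f, p = jv.one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        f, p = jv.one_way_anova([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert f == pytest.approx(13.5)

    def test_constant_equal_groups_convention(self):
        f, p = jv.one_way_anova([[5.0, 5.0], [5.0, 5.0]])
        assert (f, p) == (0.0, 1.0)

    def test_constant_unequal_groups_convention(self):
        f, p = jv.one_way_anova([[5.0, 5.0], [6.0, 6.0]])
        assert np.isinf(f) and p == 0.0

    def test_power_against_shifted_group(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(3, 1, 50)]
        _, p = jv.one_way_anova(groups)
        assert p < 1e-6

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            jv.one_way_anova([[1.0, 2.0]])


class TestTukeyBonferroni:
    def test_identical_groups_all_one(self):
        p = jv.tukey_bonferroni([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]])
        assert np.all(p == 1.0)

    def test_only_shifted_pairs_significant(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, 1, 40), rng.normal(0, 1, 40), rng.normal(3, 1, 40)]
        p = jv.tukey_bonferroni(groups)
        assert p[0, 1] >= 0.05
        assert p[0, 2] < 0.05 and p[1, 2] < 0.05

    def test_panel_multiplier_scales_and_caps(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 1, 30), rng.normal(0.8, 1, 30), rng.normal(5, 1, 30)]
        plain = jv.tukey_bonferroni(groups, analyte_multiplier=1)
        panel = jv.tukey_bonferroni(groups, analyte_multiplier=13)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(panel[off], np.minimum(1.0, plain[off] * 13))

    def test_adjusted_dominates_plain_and_stays_probability(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(i * 0.5, 1, 25) for i in range(4)]
        plain = jv.tukey_bonferroni(groups, analyte_multiplier=1)
        panel = jv.tukey_bonferroni(groups, analyte_multiplier=5)
        assert np.all(panel >= plain)
        assert np.all((panel >= 0) & (panel <= 1))

    def test_unbalanced_groups_accepted(self):
        rng = np.random.default_rng(5)
        p = jv.tukey_bonferroni([rng.normal(0, 1, 30), rng.normal(0, 1, 45)])
        assert p.shape == (2, 2)

    def test_familywise_error_under_global_null(self):
        # ANOVA+Tukey chain at alpha 0.05, 4 groups of 50: family-wise
        # type-I error should sit near 0.05
        rng = np.random.default_rng(6)
        errors = 0
        reps = 2000
        for _ in range(reps):
            groups = [rng.normal(0, 1, 50) for _ in range(4)]
            p = jv.tukey_bonferroni(groups)
            off = ~np.eye(4, dtype=bool)
            errors += bool((p[off] < 0.05).any())
        assert errors / reps == pytest.approx(0.05, abs=0.015)


class TestCompactLetters:
    def test_all_nonsignificant_single_letter(self):
        p = np.ones((3, 3))
        assert jv.compact_letters(p) == ("a", "a", "a")

    def test_chain_pattern(self):
        p = np.array([[1.0, 0.01, 0.02], [0.01, 1.0, 0.5], [0.02, 0.5, 1.0]])
        assert jv.compact_letters(p) == ("a", "b", "b")

    def test_all_mutually_significant(self):
        p = np.full((4, 4), 0.001)
        np.fill_diagonal(p, 1.0)
        assert jv.compact_letters(p) == ("a", "b", "c", "d")

    def test_minimality_over_all_three_group_patterns(self):
        # exhaustive check at k=3: the number of distinct letters equals
        # the known minimum for every significance pattern (0 significant
        # pairs -> 1 letter, 1 or 2 pairs -> 2, all 3 pairs -> 3)
        from itertools import product

        for sig in product([True, False], repeat=3):
            p = np.ones((3, 3))
            for (i, j), s in zip([(0, 1), (0, 2), (1, 2)], sig):
                p[i, j] = p[j, i] = 0.01 if s else 0.5
            letters = jv.compact_letters(p)
            n_letters = len(set("".join(letters)))
            expected = {0: 1, 1: 2, 2: 2, 3: 3}[sum(sig)]
            assert n_letters == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_consistency_properties(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 6))
        p = rng.random((k, k))
        p = (p + p.T) / 2
        np.fill_diagonal(p, 1.0)
        letters = jv.compact_letters(p, alpha=0.3)
        for i in range(k):
            for j in range(i + 1, k):
                shared = set(letters[i]) & set(letters[j])
                if p[i, j] < 0.3:
                    assert not shared  # significant pairs never share
                else:
                    assert shared  # connected pairs always share


class TestFoldChangeScreen:
    def test_calf_ast_medians_not_relevant(self):
        medians = [CALF_SUMMARY["AST"][a][1] for a in ("2w", "5w", "7w")]
        folds, flags = jv.fold_change_screen(medians, ("2w", "5w", "7w"))
        assert folds[("2w", "5w")] == pytest.approx(1.105, abs=1e-3)
        assert folds[("5w", "7w")] == pytest.approx(0.869, abs=1e-3)
        assert folds[("2w", "7w")] == pytest.approx(0.961, abs=1e-3)
        assert flags == ()

    def test_calf_ggt_collapse_flagged(self):
        medians = [CALF_SUMMARY["GGT"][a][1] for a in ("24h", "2w")]
        folds, flags = jv.fold_change_screen(medians, ("24h", "2w"))
        assert folds[("24h", "2w")] == pytest.approx(76.0 / 1303.0, rel=1e-6)
        assert flags == (("24h", "2w"),)

    def test_equal_medians_unflagged(self):
        folds, flags = jv.fold_change_screen([5.0, 5.0, 5.0])
        assert all(f == 1.0 for f in folds.values())
        assert flags == ()

    def test_scale_invariance(self):
        m = [3.1, 4.7, 2.2]
        f1, g1 = jv.fold_change_screen(m)
        f2, g2 = jv.fold_change_screen([100 * x for x in m])
        assert f1 == pytest.approx(f2)
        assert g1 == g2

    def test_nonpositive_median_refused(self):
        with pytest.raises(ValueError):
            jv.fold_change_screen([1.0, 0.0])


class TestCompareToAdult:
    def test_identical_intervals(self):
        adult = jv.AdultRI(1.0, 2.0)
        cmp_ = jv.compare_to_adult((1.0, 2.0), adult)
        assert cmp_.relation == "within_adult"
        assert cmp_.overlap_fraction == pytest.approx(1.0)
        assert cmp_.comparable

    def test_calf_creatinine_24h_overlapping(self):
        cmp_ = jv.compare_to_adult((0.93, 1.65), jv.AdultRI(1.0, 2.0))
        assert cmp_.relation == "overlapping"
        assert cmp_.overlap_fraction == pytest.approx(0.65 / 1.07, abs=1e-4)
        assert cmp_.comparable  # 0.607 >= 0.5

    def test_calf_urea_7w_disjoint_below(self):
        cmp_ = jv.compare_to_adult((6.8, 18.3), jv.AdultRI(20.0, 30.0))
        assert cmp_.relation == "disjoint_below"
        assert cmp_.overlap_fraction == 0.0
        assert not cmp_.comparable

    def test_contains_and_disjoint_above(self):
        assert jv.compare_to_adult((0.0, 10.0), jv.AdultRI(4.0, 6.0)).relation == "contains_adult"
        assert jv.compare_to_adult((40.0, 50.0), jv.AdultRI(4.0, 6.0)).relation == "disjoint_above"


class TestCompareAgeGroups:
    def test_full_chain_on_synthetic_analyte(self):
        rng = np.random.default_rng(1)
        groups = {
            "24h": rng.normal(125.8, 28.5, 30),
            "2w": rng.normal(110.6, 22.1, 188),
            "5w": rng.normal(101.8, 18.4, 193),
            "7w": rng.normal(93.0, 15.3, 134),
        }
        comp = jv.compare_age_groups(groups)
        assert comp.group_labels == ("24h", "2w", "5w", "7w")
        assert comp.anova_p < 1e-6
        assert len(comp.letters) == 4
        # 24h differs from 7w strongly: no shared letter
        assert not set(comp.letters[0]) & set(comp.letters[3])
        assert ("24h", "7w") in comp.relevance_flags

    def test_fence_cleaning_applied_before_anova(self):
        rng = np.random.default_rng(2)
        base = {"a": rng.normal(10, 1, 80), "b": rng.normal(10, 1, 80)}
        spiked = {"a": np.concatenate([base["a"], [1e4]]), "b": base["b"]}
        comp = jv.compare_age_groups(spiked)
        # the 1e4 spike sits far outside the 3 IQR fence and must not
        # drive the comparison
        assert comp.anova_p > 0.001
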