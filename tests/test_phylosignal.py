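"""Trait depth, dispersion D, and summary-statistic comparisons."""

import numpy as np
import pandas as pd
import pytest

from metaltrait import simulate
from metaltrait._trees import TreeArrays
from metaltrait.phylosignal import (
    ConsentraitConfig,
    DegenerateTraitError,
    cohens_d,
    classify_effect_size,
    consentrait_depth,
    consentrait_test,
    fritz_purvis_D,
    sister_difference_sum,
    welch_t,
)


def tr(labels, bits):
    return pd.Series(list(bits), index=list(labels)).astype(int)


class TestConsentraitDepth:
    def test_worked_examples_balanced_tree(self, balanced4):
        tau, clades = consentrait_depth(balanced4, tr("ABCD", [1, 1, 1, 1]))
        assert tau == pytest.approx(2.0) and len(clades) == 1
        tau, clades = consentrait_depth(balanced4, tr("ABCD", [1, 1, 0, 0]))
        assert tau == pytest.approx(1.0) and len(clades) == 1
        tau, clades = consentrait_depth(balanced4, tr("ABCD", [1, 0, 0, 0]))
        assert tau == pytest.approx(0.5) and clades == []

    def test_zero_positive_raises(self, balanced4):
        with pytest.raises(DegenerateTraitError):
            consentrait_depth(balanced4, tr("ABCD", [0, 0, 0, 0]))

    def test_all_positive_equals_mean_root_to_tip(self):
        for seed in range(100):
            ta = TreeArrays(simulate.gen_tree(simulate.SimTreeSpec(20, seed=seed)))
            tau, _ = consentrait_depth(ta, pd.Series(1, index=ta.tip_labels))
            assert tau == pytest.approx(ta.root_to_tip().mean(), rel=1e-10)

    def test_branch_length_scaling_equivariance(self, yule64):
        ta = TreeArrays(yule64)
        trait = simulate.gen_traits(yule64, simulate.TraitSimSpec("clumped", 0.25, seed=2))
        tau, _ = consentrait_depth(ta, trait)
        scaled = TreeArrays(yule64)
        scaled.edge_len = 3.0 * scaled.edge_len
        scaled._depths = None
        tau3, _ = consentrait_depth(scaled, trait)
        assert tau3 == pytest.approx(3.0 * tau, rel=1e-10)


class TestConsentraitTest:
    def test_single_tree_sd_zero(self, yule64):
        trait = simulate.gen_traits(yule64, simulate.TraitSimSpec("clumped", 0.25, seed=1))
        res = consentrait_test(yule64, trait, ConsentraitConfig(n_permutations=99, seed=0))
        assert res.tau_SD == 0.0

    def test_clumped_trait_significant(self, yule64):
        cfg = ConsentraitConfig(n_permutations=300, seed=5)
        hits = 0
        for seed in range(30):
            trait = simulate.gen_traits(
                yule64, simulate.TraitSimSpec("clumped", 0.25, seed=seed)
            )
            res = consentrait_test(yule64, trait, cfg)
            hits += res.p_perm < 0.1
        assert hits >= 27

    def test_random_trait_type_I_controlled(self, yule64):
        cfg = ConsentraitConfig(n_permutations=300, seed=5)
        hits = 0
        n = 60
        for seed in range(n):
            trait = simulate.gen_traits(
                yule64, simulate.TraitSimSpec("random", 0.25, seed=1000 + seed)
            )
            if trait.sum() == 0:
                continue
            res = consentrait_test(yule64, trait, cfg)
            hits += res.p_perm < 0.1
        assert hits <= 0.1 * n + 3 * np.sqrt(n * 0.1 * 0.9)

    def test_clumped_deeper_than_random_paired(self, yule64):
        ta = TreeArrays(yule64)
        wins = 0
        for seed in range(100):
            c = simulate.gen_traits(yule64, simulate.TraitSimSpec("clumped", 0.25, seed=seed))
            r = simulate.gen_traits(yule64, simulate.TraitSimSpec("random", 0.25, seed=seed))
            if r.sum() == 0:
                wins += 1
                continue
            tau_c, _ = consentrait_depth(ta, c)
            tau_r, _ = consentrait_depth(ta, r)
            wins += tau_c > tau_r
        assert wins >= 95

    def test_mismatched_tip_sets_raise(self, yule64):
        import dendropy

        other = simulate.gen_tree(simulate.SimTreeSpec(32, seed=0))
        trait = simulate.gen_traits(yule64, simulate.TraitSimSpec("random", 0.5, seed=0))
        from metaltrait.phylosignal import LabelMismatchError

        with pytest.raises(LabelMismatchError):
            consentrait_test([yule64, other], trait)


class TestSisterDifferenceSum:
    def test_hand_enumerated_values(self, balanced4):
        assert sister_difference_sum(balanced4, tr("ABCD", [1, 1, 0, 0])) == pytest.approx(1.0)
        assert sister_difference_sum(balanced4, tr("ABCD", [1, 0, 1, 0])) == pytest.approx(2.0)

    def test_constant_trait_raises(self, balanced4):
        with pytest.raises(DegenerateTraitError):
            sister_difference_sum(balanced4, tr("ABCD", [1, 1, 1, 1]))

    def test_polytomy_reduces_to_absolute_deviations(self):
        ta = TreeArrays.from_newick("(A:1,B:1,C:1);")
        # children values 1, 0, 0; mean 1/3; sum |dev| = 2/3 + 1/3 + 1/3
        val = sister_difference_sum(ta, tr("ABC", [1, 0, 0]))
        assert val == pytest.approx(4 / 3)


class TestFritzPurvisD:
    def test_brownian_calibration_near_zero(self, yule64, yule64_arrays):
        Ds = [
            fritz_purvis_D(
                yule64_arrays,
                simulate.gen_traits(yule64, simulate.TraitSimSpec("brownian_threshold", 0.5, seed=s)),
                n_random=300, n_brownian=300, seed=s,
            ).D
            for s in range(60)
        ]
        assert abs(np.mean(Ds)) < 0.15

    def test_random_calibration_near_one(self, yule64, yule64_arrays):
        rng = np.random.default_rng(0)
        Ds = []
        for s in range(60):
            bits = np.zeros(64, dtype=int)
            bits[rng.permutation(64)[:32]] = 1
            Ds.append(
                fritz_purvis_D(
                    yule64_arrays, pd.Series(bits, index=yule64_arrays.tip_labels),
                    n_random=300, n_brownian=300, seed=s,
                ).D
            )
        assert abs(np.mean(Ds) - 1.0) < 0.15

    def test_clumped_trait_negative_D(self, yule64, yule64_arrays):
        neg = 0
        for s in range(100):
            trait = simulate.gen_traits(yule64, simulate.TraitSimSpec("clumped", 0.25, seed=s))
            res = fritz_purvis_D(yule64_arrays, trait, n_random=200, n_brownian=200, seed=s)
            neg += res.D < 0
        assert neg >= 95

    def test_constant_trait_raises(self, balanced4):
        with pytest.raises(DegenerateTraitError):
            fritz_purvis_D(balanced4, tr("ABCD", [1, 1, 1, 1]))


class TestSummaryComparisons:
    def test_cohens_d_matches_frozen_formula_values(self):
        # values computed once by direct evaluation of the formula
        assert cohens_d(0.0400, 0.0025, 0.2785, 0.0127) == pytest.approx(26.0582, abs=1e-3)
        assert cohens_d(0.0414, 0.0020, 0.0407, 0.0017) == pytest.approx(0.37714, abs=1e-4)
        assert classify_effect_size(26.06) == "large"
        assert classify_effect_size(0.377) == "small"

    def test_cohens_d_equal_means_zero(self):
        assert cohens_d(1.0, 0.5, 1.0, 0.2) == 0.0

    def test_welch_identical_stats(self):
        t, df, p = welch_t(1.0, 0.5, 10, 1.0, 0.5, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_equal_variance_df_closed_form(self):
        _, df, _ = welch_t(1.0, 0.5, 12, 2.0, 0.5, 12)
        assert df == pytest.approx(22.0)

    def test_welch_matches_scipy_from_raw_samples(self):
        from scipy import stats as ss

        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 2, 25)
        t_ref, p_ref = ss.ttest_ind(x, y, equal_var=False)
        t, df, p = welch_t(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        assert t == pytest.approx(t_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)

    def test_welch_small_n_raises(self):
        with pytest.raises(ValueError):
            welch_t(0, 1, 1, 0, 1, 5)
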