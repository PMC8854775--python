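"""Trisomy merging, shared/mirrored DEG logic and the permutation null."""

import numpy as np
import pandas as pd
import pytest

from mirror21.diffexpr import DEGThresholds, nb_wald
from mirror21.mirror import (
    AlignmentError,
    merge_trisomy,
    mirrored_fraction,
    permutation_test,
    shared_and_mirrored,
    venn_counts,
)


def de_table(statuses, log2_fc=None, adj_p=None, base_mean=None):
    """Small DE table with explicit statuses (statistics consistent with them)."""
    n = len(statuses)
    index = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
    if log2_fc is None:
        log2_fc = [
            1.0 if s == "UP" else -1.0 if s == "DOWN" else 0.0 for s in statuses
        ]
    if adj_p is None:
        adj_p = [0.001 if s in ("UP", "DOWN") else 0.9 for s in statuses]
    if base_mean is None:
        base_mean = [100.0] * n
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fc": log2_fc,
            "adj_p": adj_p,
            "deg_status": statuses,
        },
        index=index,
    )


class TestMergeTrisomy:
    def test_two_lines_become_one_six_column_condition(self, small_experiment):
        counts, _, _ = small_experiment
        merged = merge_trisomy(counts, ["DS1", "DS2"])
        assert (merged.samples["line"] == "DSm").sum() == 6
        assert merged.counts.equals(counts.counts)  # column data untouched

    def test_merging_single_line_is_a_relabeling_identity(self, small_experiment):
        counts, _, _ = small_experiment
        merged = merge_trisomy(counts, ["DS1"], merged_line="DS1m")
        de_before = nb_wald(counts, ("trisomy", "control"))
        de_after = nb_wald(merged, ("trisomy", "control"))
        pd.testing.assert_frame_equal(de_before, de_after)

    def test_merging_zero_lines_raises(self, small_experiment):
        counts, _, _ = small_experiment
        with pytest.raises(ValueError):
            merge_trisomy(counts, [])

    def test_unknown_line_raises_key_error(self, small_experiment):
        counts, _, _ = small_experiment
        with pytest.raises(KeyError):
            merge_trisomy(counts, ["DS1", "DS9"])

    def test_non_trisomy_line_rejected(self, small_experiment):
        counts, _, _ = small_experiment
        with pytest.raises(ValueError, match="trisomy"):
            merge_trisomy(counts, ["DS1", "CTRL1"])


class TestSharedAndMirrored:
    def test_published_pattern_all_mirrored(self):
        a = de_table(["DOWN"] * 5)
        b = de_table(["UP"] * 5)
        result = shared_and_mirrored(a, b)
        assert result.mirrored == result.shared_degs
        assert len(result.mirrored) == 5

    def test_identical_signs_give_no_mirrored(self):
        a = de_table(["UP", "DOWN", "NOT_DE"])
        result = shared_and_mirrored(a, a.copy())
        assert result.shared_degs == frozenset({"g0", "g1"})
        assert result.mirrored == frozenset()

    def test_mismatched_universes_raise(self):
        a = de_table(["UP", "DOWN"])
        b = de_table(["UP", "DOWN", "NOT_DE"])
        with pytest.raises(AlignmentError):
            shared_and_mirrored(a, b)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        choices = ["UP", "DOWN", "NOT_DE", "FILTERED_LOW_EXPRESSION"]
        a = de_table(list(rng.choice(choices, 60)))
        b = de_table(list(rng.choice(choices, 60)))
        assert shared_and_mirrored(a, b).mirrored == shared_and_mirrored(b, a).mirrored

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(1)
        choices = ["UP", "DOWN", "NOT_DE"]
        a = de_table(list(rng.choice(choices, 80)))
        b = de_table(list(rng.choice(choices, 80)))
        result = shared_and_mirrored(a, b)
        expected_shared, expected_mirrored = set(), set()
        for g in a.index:
            sa, sb = a.loc[g, "deg_status"], b.loc[g, "deg_status"]
            if sa in ("UP", "DOWN") and sb in ("UP", "DOWN"):
                expected_shared.add(g)
                if sa != sb:
                    expected_mirrored.add(g)
        assert result.shared_degs == expected_shared
        assert result.mirrored == expected_mirrored


class TestMirroredFraction:
    def test_published_arithmetic(self):
        # 172 mirrored of 1951 monosomy DEGs -> 8.8%
        statuses_a = ["DOWN"] * 1951 + ["NOT_DE"] * 49
        statuses_b = ["UP"] * 172 + ["DOWN"] * 1779 + ["NOT_DE"] * 49
        result = shared_and_mirrored(de_table(statuses_a), de_table(statuses_b))
        assert len(result.mirrored) == 172
        assert round(100 * mirrored_fraction(result), 1) == 8.8

    def test_empty_mirrored_gives_zero(self):
        a = de_table(["UP", "NOT_DE"])
        b = de_table(["UP", "NOT_DE"])
        assert mirrored_fraction(shared_and_mirrored(a, b)) == 0.0

    def test_zero_denominator_raises(self):
        a = de_table(["NOT_DE", "NOT_DE"])
        with pytest.raises(ZeroDivisionError):
            mirrored_fraction(shared_and_mirrored(a, a.copy()))

    def test_excluding_deleted_genes_removes_numerator_only(self):
        a = de_table(["DOWN"] * 10)
        b = de_table(["UP"] * 5 + ["NOT_DE"] * 5)
        result = shared_and_mirrored(a, b, deleted_genes={"g0", "g1"})
        assert mirrored_fraction(result) == pytest.approx(0.5)
        assert mirrored_fraction(result, exclude_deleted=True) == pytest.approx(0.3)


class TestPermutationTest:
    def test_extreme_observed_gives_minimal_p(self):
        # a DE subset with opposite signs: observed 1.0, virtually no shuffle
        # can reach it -> the add-one minimum 1/(n+1)
        a = de_table(["DOWN"] * 20 + ["NOT_DE"] * 30)
        b = de_table(["UP"] * 20 + ["NOT_DE"] * 30)
        summary = permutation_test(a, b, n=99, seed=0)
        assert summary.observed == 1.0
        assert summary.empirical_p == pytest.approx(1 / 100)

    def test_fully_opposite_universe_is_shuffle_invariant(self):
        # when every gene is DE with opposite signs, shuffling changes
        # nothing and the one-sided p is 1 by the >= convention
        a = de_table(["DOWN"] * 40)
        b = de_table(["UP"] * 40)
        summary = permutation_test(a, b, n=49, seed=0)
        assert summary.observed == 1.0
        assert (summary.null_fractions == 1.0).all()
        assert summary.empirical_p == 1.0

    def test_observed_below_all_null_gives_p_one(self):
        # concordant signs everywhere: observed 0, every shuffle >= 0
        a = de_table(["UP"] * 30 + ["NOT_DE"] * 30)
        b = de_table(["UP"] * 30 + ["NOT_DE"] * 30)
        summary = permutation_test(a, b, n=99, seed=1)
        assert summary.observed == 0.0
        assert summary.empirical_p == 1.0

    def test_empirical_p_never_zero_and_bounded(self):
        rng = np.random.default_rng(3)
        choices = ["UP", "DOWN", "NOT_DE"]
        a = de_table(list(rng.choice(choices, 100)))
        b = de_table(list(rng.choice(choices, 100)))
        summary = permutation_test(a, b, n=200, seed=4)
        assert 1 / 201 <= summary.empirical_p <= 1.0
        assert len(summary.null_fractions) == 200

    def test_fixed_seed_reproduces_summary(self):
        rng = np.random.default_rng(5)
        choices = ["UP", "DOWN", "NOT_DE"]
        a = de_table(list(rng.choice(choices, 100)))
        b = de_table(list(rng.choice(choices, 100)))
        s1 = permutation_test(a, b, n=100, seed=11)
        s2 = permutation_test(a, b, n=100, seed=11)
        assert np.array_equal(s1.null_fractions, s2.null_fractions)
        assert s1.empirical_p == s2.empirical_p

    def test_input_row_order_does_not_change_null_stream(self):
        rng = np.random.default_rng(6)
        choices = ["UP", "DOWN", "NOT_DE"]
        a = de_table(list(rng.choice(choices, 100)))
        b = de_table(list(rng.choice(choices, 100)))
        perm = rng.permutation(100)
        s1 = permutation_test(a, b, n=100, seed=12)
        s2 = permutation_test(a.iloc[perm], b.iloc[perm], n=100, seed=12)
        assert np.array_equal(s1.null_fractions, s2.null_fractions)

    def test_sign_flip_scheme_runs_and_differs(self):
        rng = np.random.default_rng(7)
        choices = ["UP", "DOWN", "NOT_DE"]
        a = de_table(list(rng.choice(choices, 100)))
        b = de_table(list(rng.choice(choices, 100)))
        flip = permutation_test(a, b, n=50, seed=13, scheme="sign_flip")
        assert flip.scheme == "sign_flip"
        assert 0 <= flip.empirical_p <= 1

    def test_invalid_arguments(self):
        a = de_table(["UP"])
        with pytest.raises(ValueError):
            permutation_test(a, a.copy(), n=0, seed=0)
        with pytest.raises(ValueError):
            permutation_test(a, a.copy(), n=10, seed=0, scheme="bootstrap")


def test_permutation_conservative_under_shared_control_heterogeneity():
    """With between-line variability and the two contrasts sharing one
    euploid control group, extra-NB noise correlates their calls with the
    same sign: the shuffle null then over-states the chance mirrored
    fraction and the test errs on the conservative side (p high, never
    anticonservative)."""
    from mirror21.simulate import SimConfig, simulate_experiment

    p_values = []
    for seed in range(12):
        config = SimConfig(
            n_genes=1500, chr21_fraction=0.0, n_deleted_genes=0,
            n_monosomy_lines=3, n_trisomy_lines=3, n_trans_degs=200,
            mirrored_fraction_true=0.0, seed=seed,  # sigma_line 0.2 default
        )
        counts, _, _ = simulate_experiment(config)
        merged = merge_trisomy(counts, ["DS1", "DS2", "DS3"])
        de_a = nb_wald(merged, ("monosomy", "control"))
        de_b = nb_wald(merged, ("trisomy", "control"))
        p_values.append(permutation_test(de_a, de_b, n=300, seed=seed).empirical_p)
    assert np.mean(p_values) > 0.5
    assert np.min(p_values) > 0.05


def test_venn_counts_strata(small_experiment, deletions):
    counts, truth, annotation = small_experiment
    merged = merge_trisomy(counts, ["DS1", "DS2"])
    de_a = nb_wald(merged, ("monosomy", "control"))
    de_b = nb_wald(merged, ("trisomy", "control"))
    result = shared_and_mirrored(de_a, de_b)
    venn = venn_counts(result, annotation, deletions)
    assert list(venn.index) == ["genome_wide", "chr21", "deletions"]
    # strata are nested: genome-wide >= chr21 >= deletions in every column
    for col in venn.columns:
        assert venn.loc["genome_wide", col] >= venn.loc["chr21", col]
        assert venn.loc["chr21", col] >= venn.loc["deletions", col]
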