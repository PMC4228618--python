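import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haplopop import (AlleleMatrix, StrataMap, allele_frequencies,
                      compare_group_diversity, effective_alleles,
                      gene_diversity, locus_summary, private_alleles,
                      unbiased_gene_diversity)
from conftest import random_matrix


def test_allele_frequencies_pairwise_deletion(tiny_matrix):
    freqs, n = allele_frequencies(tiny_matrix, "L3")
    assert n == 3                                  # one missing call excluded
    assert freqs == {9: 1.0}


def test_allele_frequencies_examples():
    m = AlleleMatrix(("a", "b", "c", "d"), ("L",),
                     np.array([[5], [5], [7], [0]]))
    freqs, n = allele_frequencies(m, "L")
    assert n == 3
    assert freqs[5] == pytest.approx(2 / 3)
    assert freqs[7] == pytest.approx(1 / 3)


def test_all_missing_locus_errors():
    m = AlleleMatrix(("a", "b"), ("L",), np.array([[0], [0]]))
    with pytest.raises(ValueError):
        allele_frequencies(m, "L")


def test_gene_diversity_hand_computed():
    h, he = gene_diversity({1: 0.5, 2: 0.25, 3: 0.25}, 4)
    assert h == pytest.approx(0.625)
    assert he == pytest.approx(0.625 * 4 / 3)


def test_gene_diversity_printed_marker_panel_consistency():
    # a locus whose effective allele number is 14.75 at n = 92 must give the
    # printed unbiased heterozygosity 0.942
    h = 1 - 1 / 14.75
    assert unbiased_gene_diversity(h, 92) == pytest.approx(0.942, abs=5e-4)
    assert effective_alleles(h) == pytest.approx(14.75)


def test_effective_alleles_limits():
    assert effective_alleles(0.0) == 1.0
    freqs = {a: 0.25 for a in range(4)}
    h, _ = gene_diversity(freqs, 100)
    assert effective_alleles(h) == pytest.approx(4.0)   # equifrequency identity
    with pytest.raises(ValueError):
        effective_alleles(1.0)


def test_private_alleles_enumeration():
    m = AlleleMatrix(("a", "b", "c", "d"), ("L",),
                     np.array([[5], [7], [5], [9]]))
    s = StrataMap.from_labels(["a", "b", "c", "d"],
                              age_class=["new", "new", "old", "old"])
    counts = private_alleles(m, s, "age_class")
    assert counts.loc["L", "new"] == 1              # allele 7
    assert counts.loc["L", "old"] == 1              # allele 9
    same = AlleleMatrix(("a", "b", "c", "d"), ("L",),
                        np.array([[5], [7], [5], [7]]))
    assert (private_alleles(same, s, "age_class") == 0).all().all()


def test_compare_group_diversity_closed_form():
    # group allele counts per locus: {1,2,3} vs {4,5,6}
    a_calls = np.array([[1, 1, 1], [1, 2, 2], [1, 1, 3],
                        [1, 2, 1], [1, 1, 2], [1, 2, 3]])
    b_calls = np.array([[1, 1, 1], [2, 2, 2], [3, 3, 3],
                        [4, 4, 4], [1, 5, 5], [2, 1, 6]])
    calls = np.vstack([a_calls, b_calls])
    ids = [f"i{k}" for k in range(12)]
    m = AlleleMatrix(tuple(ids), ("L1", "L2", "L3"), calls)
    s = StrataMap.from_labels(ids, age_class=["new"] * 6 + ["old"] * 6)
    res = compare_group_diversity(m, s, "age_class", index="N_a")
    assert list(res.per_locus["new"]) == [1, 2, 3]
    assert list(res.per_locus["old"]) == [4, 5, 6]
    assert res.t == pytest.approx(-3.674, abs=1e-3)
    assert res.df == 4
    assert res.p_value == pytest.approx(0.0213, abs=2e-3)


def test_compare_identical_groups_gives_t0_p1():
    calls = np.array([[1, 1], [2, 2], [1, 1], [2, 2]])
    ids = ["a", "b", "c", "d"]
    m = AlleleMatrix(tuple(ids), ("L1", "L2"), calls)
    s = StrataMap.from_labels(ids, age_class=["new", "new", "old", "old"])
    res = compare_group_diversity(m, s, "age_class", index="N_a")
    assert res.t == 0.0 and res.p_value == 1.0


def test_he_h_ratio_identity_and_ne_monotonicity(survey):
    matrix, _ = survey
    table = locus_summary(matrix)
    np.testing.assert_allclose(table["H_E"] / table["h"],
                               table["n"] / (table["n"] - 1))
    by_h = table.sort_values("h")
    assert (np.diff(by_h["N_e"]) >= -1e-12).all()


def test_pooling_strata_never_decreases_allele_count(survey):
    matrix, strata = survey
    labels = strata.labels(matrix, "age_class")
    pooled = locus_summary(matrix)["N_a"]
    for g in ("new", "old"):
        sub = matrix.subset_individuals(
            [i for i, l in zip(matrix.individuals, labels) if l == g])
        assert (locus_summary(sub)["N_a"] <= pooled).all()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(2, 6), st.integers(1, 3), st.integers(0, 10_000))
def test_small_matrix_statistics_match_enumeration(n, L, seed):
    """On tiny random matrices every per-locus statistic equals the value
    obtained by direct counting."""
    rng = np.random.default_rng(seed)
    m = random_matrix(rng, n, L, n_alleles=3)
    table = locus_summary(m)
    for j, locus in enumerate(m.loci):
        col = [c for c in m.calls[:, j] if c != 0]
        counts = {a: col.count(a) for a in set(col)}
        sum_p2 = sum((c / len(col)) ** 2 for c in counts.values())
        assert table.loc[locus, "N_a"] == len(counts)
        assert table.loc[locus, "h"] == pytest.approx(1 - sum_p2)
        assert table.loc[locus, "N_e"] == pytest.approx(1 / sum_p2)
        if len(col) >= 2:
            assert table.loc[locus, "H_E"] == pytest.approx(
                (1 - sum_p2) * len(col) / (len(col) - 1))
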