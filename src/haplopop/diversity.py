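"""Per-locus and per-stratum allele-frequency diversity statistics.

For a haploid locus with allele frequencies :math:`p_i` over the :math:`n`
non-missing calls:

* gene diversity  :math:`h = 1 - \\sum_i p_i^2` (Nei);
* unbiased expected heterozygosity  :math:`H_E = h \\, n/(n-1)` — the
  small-sample correction uses the haploid sample count *n* (number of
  individuals), not 2n;
* effective number of alleles  :math:`N_e = 1/(1-h) = 1/\\sum_i p_i^2`
  (Kimura & Crow), the count of equifrequent alleles that would give the
  observed gene diversity.

Missing calls are removed per locus (pairwise deletion), so each locus has
its own sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, AlleleMatrix, StrataMap

__all__ = [
    "allele_frequencies",
    "gene_diversity",
    "unbiased_gene_diversity",
    "effective_alleles",
    "locus_summary",
    "private_alleles",
    "compare_group_diversity",
    "GroupComparison",
]


def allele_frequencies(matrix: AlleleMatrix, locus: str) -> tuple[dict[int, float], int]:
    """Allele frequency spectrum and non-missing sample size at one locus."""
    calls = matrix.locus_calls(locus)
    calls = calls[calls != MISSING]
    n = calls.size
    if n == 0:
        raise ValueError(f"locus {locus!r} has no non-missing calls")
    alleles, counts = np.unique(calls, return_counts=True)
    return {int(a): c / n for a, c in zip(alleles, counts)}, n


def gene_diversity(freqs: dict[int, float] | np.ndarray, n: int
                   ) -> tuple[float, float]:
    """Gene diversity ``h`` and its unbiased estimate ``H_E``.

    ``H_E`` needs n >= 2; for n < 2 it is returned as NaN with ``h`` intact.
    """
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs,
                   dtype=float)
    if p.size == 0 or not np.isclose(p.sum(), 1.0):
        raise ValueError("frequencies must sum to 1")
    h = 1.0 - float(np.sum(p ** 2))
    return h, unbiased_gene_diversity(h, n)


def unbiased_gene_diversity(h: float, n: int) -> float:
    """Small-sample correction ``H_E = h * n/(n-1)`` (haploid sample count n)."""
    if n < 2:
        return float("nan")
    return h * n / (n - 1)


def effective_alleles(h: float) -> float:
    """Effective number of alleles ``N_e = 1/(1 - h)``."""
    if not 0 <= h < 1:
        raise ValueError("gene diversity h must be in [0, 1)")
    return 1.0 / (1.0 - h)


def locus_summary(matrix: AlleleMatrix,
                  strata: StrataMap | None = None,
                  partition: str | None = None) -> pd.DataFrame:
    """Per-locus summary table: n, N_a, null %, h, N_e, H_E (and N_p).

    Mirrors the conventional marker-panel report: one row per locus plus the
    cross-locus mean +/- SEM is available via :func:`summarize_with_sem`.
    If ``strata``/``partition`` are given, a private-allele count column is
    appended (total over strata).
    """
    rows = []
    for locus in matrix.loci:
        calls = matrix.locus_calls(locus)
        n_missing = int((calls == MISSING).sum())
        freqs, n = allele_frequencies(matrix, locus)
        h, he = gene_diversity(freqs, n)
        rows.append({
            "locus": locus,
            "n": n,
            "N_a": len(freqs),
            "null_pct": 100.0 * n_missing / matrix.n_individuals,
            "h": h,
            "N_e": effective_alleles(h),
            "H_E": he,
        })
    out = pd.DataFrame(rows).set_index("locus")
    if strata is not None and partition is not None:
        priv = private_alleles(matrix, strata, partition)
        out["N_p_total"] = priv.sum(axis=0)
    return out


def summarize_with_sem(table: pd.DataFrame,
                       columns: tuple[str, ...] = ("N_a", "null_pct", "N_e", "H_E")
                       ) -> pd.DataFrame:
    """Cross-locus mean and SEM (sample SD / sqrt(L)) for summary columns."""
    sub = table[list(columns)]
    return pd.DataFrame({"mean": sub.mean(axis=0),
                         "sem": sub.std(axis=0, ddof=1) / np.sqrt(len(sub))})


def private_alleles(matrix: AlleleMatrix, strata: StrataMap,
                    partition: str | list[str]) -> pd.DataFrame:
    """Count alleles observed in exactly one stratum, per locus x stratum."""
    labels = strata.labels(matrix, partition)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("private alleles need at least 2 strata")
    counts = pd.DataFrame(0, index=list(matrix.loci), columns=groups)
    for j, locus in enumerate(matrix.loci):
        col = matrix.calls[:, j]
        seen = {g: set(col[(labels == g) & (col != MISSING)].tolist())
                for g in groups}
        for g in groups:
            others = set().union(*(seen[o] for o in groups if o != g))
            counts.loc[locus, g] = len(seen[g] - others)
    return counts


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison of a per-locus diversity index between strata."""

    index: str
    groups: tuple[str, str]
    per_locus: pd.DataFrame    # loci x groups index values
    means: pd.Series
    sems: pd.Series
    t: float
    df: float
    p_value: float
    equal_var: bool


def compare_group_diversity(matrix: AlleleMatrix, strata: StrataMap,
                            partition: str | list[str] = "age_class",
                            index: str = "H_E",
                            equal_var: bool = True) -> GroupComparison:
    """Two-sample t-test on per-locus diversity indices between two strata.

    The index (``N_a``, ``N_e``, ``H_E`` or ``N_p``) is computed per locus
    within each of the two groups; the t-test treats loci as the sampling
    units. Student's equal-variance test is the default, with Welch behind
    ``equal_var=False``.
    """
    labels = strata.labels(matrix, partition)
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if matrix.n_loci < 2:
        raise ValueError("need at least 2 loci for the t-test")
    per_locus = {}
    if index == "N_p":
        priv = private_alleles(matrix, strata, partition)
        for g in groups:
            per_locus[g] = priv[g].astype(float).to_numpy()
    else:
        if index not in ("N_a", "N_e", "H_E", "h"):
            raise ValueError(f"unknown diversity index {index!r}")
        for g in groups:
            sub = matrix.subset_individuals(
                [i for i, l in zip(matrix.individuals, labels) if l == g])
            per_locus[g] = locus_summary(sub)[index].to_numpy()
    a, b = per_locus[groups[0]], per_locus[groups[1]]
    import warnings
    with warnings.catch_warnings():
        # zero-variance inputs are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    t_stat, p_val, df = float(res.statistic), float(res.pvalue), float(res.df)
    if np.isnan(t_stat) and np.isclose(np.mean(a), np.mean(b)):
        # zero pooled variance with equal means: no evidence of a difference
        t_stat, p_val = 0.0, 1.0
    table = pd.DataFrame(per_locus, index=list(matrix.loci))
    return GroupComparison(
        index=index,
        groups=(groups[0], groups[1]),
        per_locus=table,
        means=table.mean(axis=0),
        sems=table.std(axis=0, ddof=1) / np.sqrt(len(table)),
        t=t_stat,
        df=df,
        p_value=p_val,
        equal_var=equal_var,
    )
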