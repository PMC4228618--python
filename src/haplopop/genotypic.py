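"""Multilocus-genotype diversity: G, Ghat, evenness E5, accumulation curves.

Individuals are grouped into multilocus genotypes (MLGs) by exact equality of
their allele calls across all retained loci. With :math:`f_x` the number of
distinct genotypes occurring :math:`x` times in a sample of :math:`n`
individuals:

* Stoddart & Taylor's genotypic diversity
  :math:`G = 1 / \\sum_x f_x (x/n)^2` — the inverse Simpson index over
  genotype frequencies, i.e. the effective number of genotypes;
* the maximum percentage of genotypic diversity
  :math:`\\hat{G} = 100\\, G / N` (McDonald et al.), scaling G by the sample
  size so 100% means every isolate is genotypically unique;
* evenness :math:`E_5 = (G - 1)/(e^{H'} - 1)` (Grunwald et al.), the ratio of
  Simpson- to Shannon-based effective genotype numbers, with :math:`H'` the
  natural-log Shannon index; :math:`E_5 = 1` when all genotypes are
  equifrequent.

A genotype accumulation curve (mean distinct-genotype count against number of
subsampled loci) shows whether the marker panel saturates the resolvable
diversity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, AlleleMatrix

__all__ = [
    "GenotypeCensus",
    "census",
    "stoddart_taylor_G",
    "max_pct_genotypic_diversity",
    "shannon_H",
    "evenness_E5",
    "genotype_accumulation",
]


@dataclass(frozen=True)
class GenotypeCensus:
    """Counts of multilocus genotypes in a sample.

    ``counts`` maps a genotype key to its number of carriers; ``members``
    maps it to the individual IDs carrying it (empty when a census is built
    directly from counts). ``n_with_missing`` records how many individuals
    had a missing call at a retained locus and were therefore treated as
    unmatchable singletons.
    """

    counts: dict[tuple, int]
    members: dict[tuple, tuple[str, ...]] = field(default_factory=dict)
    n_with_missing: int = 0

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def n_genotypes(self) -> int:
        return len(self.counts)

    @property
    def f_x(self) -> dict[int, int]:
        """Number of distinct genotypes occurring exactly x times."""
        return dict(Counter(self.counts.values()))

    @classmethod
    def from_counts(cls, counts: list[int] | np.ndarray) -> "GenotypeCensus":
        """Build a census from abundance counts alone (anonymous genotypes)."""
        counts = [int(c) for c in counts]
        if any(c < 1 for c in counts):
            raise ValueError("genotype counts must be positive")
        return cls(counts={("g", i): c for i, c in enumerate(counts)})


def census(matrix: AlleleMatrix) -> GenotypeCensus:
    """Group individuals into multilocus genotypes by exact call equality.

    Missing matches nothing, including another missing call: an individual
    with any missing call at a retained locus can never be merged with
    another, so it forms its own genotype. This is conservative — spurious
    merges are impossible — and the count of such individuals is recorded.
    """
    counts: dict[tuple, int] = {}
    members: dict[tuple, list[str]] = {}
    n_with_missing = 0
    for ind, row in zip(matrix.individuals, matrix.calls):
        if (row == MISSING).any():
            n_with_missing += 1
            key = ("incomplete", ind)
        else:
            key = tuple(int(c) for c in row)
        counts[key] = counts.get(key, 0) + 1
        members.setdefault(key, []).append(ind)
    return GenotypeCensus(
        counts=counts,
        members={k: tuple(v) for k, v in members.items()},
        n_with_missing=n_with_missing,
    )


def stoddart_taylor_G(c: GenotypeCensus) -> float:
    """Stoddart & Taylor's G = 1 / sum_x f_x (x/n)^2."""
    n = c.n
    if n < 1:
        raise ValueError("empty census")
    denom = sum(fx * (x / n) ** 2 for x, fx in c.f_x.items())
    return 1.0 / denom


def max_pct_genotypic_diversity(G: float, N: int) -> float:
    """Ghat = 100 * G / N, the percentage of its sample-size maximum."""
    if G > N + 1e-9:
        raise ValueError("G cannot exceed the sample size")
    return 100.0 * G / N


def shannon_H(c: GenotypeCensus) -> float:
    """Shannon index H' (natural log) over genotype frequencies."""
    n = c.n
    p = np.array([x / n for x in c.counts.values()])
    return float(-(p * np.log(p)).sum())


def evenness_E5(c: GenotypeCensus) -> tuple[float, float]:
    """Evenness E5 = (G - 1)/(e^H' - 1); returns (E5, H').

    A single-genotype census is 0/0; by the equifrequency convention
    (k equifrequent genotypes give exactly (k-1)/(k-1) = 1) it returns 1.
    """
    G = stoddart_taylor_G(c)
    H = shannon_H(c)
    if c.n_genotypes == 1:
        return 1.0, H
    return (G - 1.0) / (np.expm1(H)), H


def genotype_accumulation(matrix: AlleleMatrix, reps: int = 100,
                          seed: int | None = None,
                          exhaustive: bool = False) -> pd.DataFrame:
    """Mean distinct-genotype count against number of subsampled loci.

    For each panel size L' = 1..L-1, averages the distinct multilocus
    genotype count over ``reps`` random locus subsets (or over all subsets
    when ``exhaustive``); at L' = L the exact count. Returns a DataFrame
    indexed by panel size with columns ``mean`` and ``sd``.
    """
    L = matrix.n_loci
    if L < 2:
        raise ValueError("accumulation curve needs >= 2 loci")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for size in range(1, L):
        if exhaustive:
            from itertools import combinations
            subsets = list(combinations(range(L), size))
        else:
            subsets = [rng.choice(L, size=size, replace=False) for _ in range(reps)]
        counts = []
        for idx in subsets:
            sub = matrix.subset_loci([matrix.loci[i] for i in idx])
            counts.append(census(sub).n_genotypes)
        rows.append({"n_loci": size, "mean": float(np.mean(counts)),
                     "sd": float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0})
    rows.append({"n_loci": L, "mean": float(census(matrix).n_genotypes), "sd": 0.0})
    return pd.DataFrame(rows).set_index("n_loci")
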