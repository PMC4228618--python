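"""Hierarchical analysis of molecular variance (AMOVA) for haploid genotypes.

Total molecular variance, measured through squared pairwise genetic
distances, is partitioned over a two-level nested hierarchy — groups of
subpopulations, subpopulations within groups, individuals within
subpopulations — following the Excoffier sums-of-squares construction: the
sum of squared deviations of a set of individuals equals the sum of their
squared pairwise distances divided by the set size.

The default distance is the multilocus mismatch count (number of loci at
which two haploids carry different alleles, both calls present), and the
mismatch count itself serves as the squared distance: each differing locus
contributes 1 to delta^2.

Variance components for unequal sample sizes come from the standard nested
expected-mean-square equations

.. math::

    MS_{WP} = \\sigma^2_c,\\quad
    MS_{AP} = \\sigma^2_c + n' \\sigma^2_b,\\quad
    MS_{AG} = \\sigma^2_c + n'' \\sigma^2_b + n''' \\sigma^2_a,

and the fixation indices are
:math:`\\Phi_{ST} = (\\sigma^2_a + \\sigma^2_b)/\\sigma^2`,
:math:`\\Phi_{SC} = \\sigma^2_b/(\\sigma^2_b + \\sigma^2_c)`,
:math:`\\Phi_{CT} = \\sigma^2_a/\\sigma^2`.

Significance uses the level-appropriate permutation schemes: individuals
among subpopulations regardless of groups (Phi_ST), individuals among
subpopulations within their group (Phi_SC), and whole subpopulations among
groups (Phi_CT), each with p = (1 + #{perm >= obs})/(R + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, AlleleMatrix

__all__ = ["AmovaResult", "distance_matrix", "amova"]


def distance_matrix(matrix: AlleleMatrix) -> np.ndarray:
    """Pairwise mismatch-count distances between haploid genotypes.

    Entry (i, j) is the number of loci at which individuals i and j carry
    different alleles, counted over loci where both calls are present. A
    pair sharing no co-typed locus is an error.
    """
    if matrix.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    calls = matrix.calls
    present = calls != MISSING
    diff = (calls[:, None, :] != calls[None, :, :])
    both = present[:, None, :] & present[None, :, :]
    dist = (diff & both).sum(axis=2).astype(float)
    co_typed = both.sum(axis=2)
    np.fill_diagonal(co_typed, 1)
    if (co_typed == 0).any():
        i, j = np.argwhere(co_typed == 0)[0]
        raise ValueError(
            f"individuals {matrix.individuals[i]!r} and {matrix.individuals[j]!r} "
            "share no co-typed locus")
    return dist


@dataclass(frozen=True)
class AmovaResult:
    """Variance components, Phi statistics and permutation p-values."""

    table: pd.DataFrame          # df, sum_sq, variance, pct_total (raw), p
    phi: dict[str, float]        # Phi_ST, Phi_SC, Phi_CT
    n: int
    n_groups: int
    n_subpops: int

    @property
    def components(self) -> pd.Series:
        return self.table["variance"]

    def pct_table(self) -> pd.DataFrame:
        """Rendered table with negative components floored at 0 in the % column."""
        out = self.table.copy()
        floored = out["variance"].clip(lower=0.0)
        total = floored.drop("Total").sum()
        pct = 100.0 * floored / total if total > 0 else floored * 0.0
        out["pct_total"] = pct
        out.loc["Total", "pct_total"] = pct.drop("Total").sum()
        return out


def _ss_within_sets(d2: np.ndarray, labels: np.ndarray) -> float:
    """Sum over sets of (sum of squared pairwise distances within set)/size."""
    total = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        total += sub.sum() / (2.0 * idx.size)
    return total


def _components(d2: np.ndarray, groups: np.ndarray, subpops: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(sigma2 [a,b,c], df [a,b,c], SS [a,b,c]) for one labeling."""
    N = d2.shape[0]
    ss_total = d2.sum() / (2.0 * N)
    ss_wp = _ss_within_sets(d2, subpops)
    ss_wg = _ss_within_sets(d2, groups)
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp
    uniq_sub, sub_inv = np.unique(subpops, return_inverse=True)
    uniq_grp = np.unique(groups)
    s, g = uniq_sub.size, uniq_grp.size
    df = np.array([g - 1, s - g, N - s], dtype=float)
    # size bookkeeping: n_p per subpop, group of each subpop, n_g per group
    n_p = np.bincount(sub_inv).astype(float)
    sub_group = np.empty(s, dtype=object)
    for k, lab in enumerate(uniq_sub):
        sub_group[k] = groups[subpops == lab][0]
    n_g = {lab: float(np.sum(groups == lab)) for lab in uniq_grp}
    sum_np2_by_g = {lab: float(np.sum(n_p[np.array([sg == lab for sg in sub_group])] ** 2))
                    for lab in uniq_grp}
    sum_np2 = float(np.sum(n_p ** 2))
    sum_ng2 = float(np.sum(np.array(list(n_g.values())) ** 2))
    n1 = (N - sum(sum_np2_by_g[lab] / n_g[lab] for lab in uniq_grp)) / df[1] if df[1] > 0 else np.nan
    n2 = ((sum(sum_np2_by_g[lab] / n_g[lab] for lab in uniq_grp) - sum_np2 / N) / df[0]
          if df[0] > 0 else np.nan)
    n3 = (N - sum_ng2 / N) / df[0] if df[0] > 0 else np.nan
    ms_wp = ss_wp / df[2] if df[2] > 0 else 0.0
    sigma_c = ms_wp
    sigma_b = (ss_ap / df[1] - sigma_c) / n1 if df[1] > 0 else 0.0
    sigma_a = ((ss_ag / df[0] - sigma_c - n2 * sigma_b) / n3) if df[0] > 0 else 0.0
    return (np.array([sigma_a, sigma_b, sigma_c]), df,
            np.array([ss_ag, ss_ap, ss_wp]))


def _phi(sig: np.ndarray) -> tuple[float, float, float]:
    a, b, c = sig
    tot = a + b + c
    phi_st = (a + b) / tot if tot != 0 else np.nan
    phi_sc = b / (b + c) if (b + c) != 0 else np.nan
    phi_ct = a / tot if tot != 0 else np.nan
    return phi_st, phi_sc, phi_ct


def amova(dist: np.ndarray, groups, subpops,
          permutations: int = 10_000, seed: int | None = None) -> AmovaResult:
    """Two-level nested AMOVA on a squared-distance matrix.

    Parameters
    ----------
    dist : (N, N) array
        Squared pairwise distances (for mismatch counts, the count itself).
    groups, subpops : length-N label sequences
        Group and subpopulation of each individual; every subpopulation must
        lie inside exactly one group.
    permutations : int
        Permutation replicates per testable level; 0 skips the tests.
    seed : int, optional
        Seed for the permutation RNG.
    """
    d2 = np.asarray(dist, dtype=float)
    groups = np.asarray([str(x) for x in groups])
    subpops = np.asarray([str(x) for x in subpops])
    N = d2.shape[0]
    if d2.shape != (N, N) or groups.shape != (N,) or subpops.shape != (N,):
        raise ValueError("distance matrix and label lengths disagree")
    for lab in np.unique(subpops):
        if np.unique(groups[subpops == lab]).size != 1:
            raise ValueError(f"subpopulation {lab!r} spans multiple groups")
    if np.unique(subpops).size < 2:
        raise ValueError("need >= 2 subpopulations")

    sig, df, ss = _components(d2, groups, subpops)
    phi_st, phi_sc, phi_ct = _phi(sig)

    p_st = p_sc = p_ct = np.nan
    if permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(3)
        count = np.zeros(3)
        g_of_sub = {lab: groups[subpops == lab][0] for lab in np.unique(subpops)}
        uniq_sub = np.unique(subpops)
        idx_all = np.arange(N)
        for _ in range(permutations):
            # Phi_ST: individuals among subpopulations, ignoring groups
            perm = rng.permutation(idx_all)
            s_p = subpops[perm]
            g_p = np.array([g_of_sub[x] for x in s_p])
            sp, _, _ = _components(d2, g_p, s_p)
            v = _phi(sp)[0]
            if np.isfinite(v):
                count[0] += 1
                exceed[0] += v >= phi_st - 1e-12
            # Phi_SC: individuals among subpopulations within their group
            s_q = subpops.copy()
            for glab in np.unique(groups):
                members = np.flatnonzero(groups == glab)
                s_q[members] = s_q[members][rng.permutation(members.size)]
            sq, _, _ = _components(d2, groups, s_q)
            v = _phi(sq)[1]
            if np.isfinite(v):
                count[1] += 1
                exceed[1] += v >= phi_sc - 1e-12
            # Phi_CT: whole subpopulations among groups
            perm_groups = rng.permutation([g_of_sub[x] for x in uniq_sub])
            remap = dict(zip(uniq_sub, perm_groups))
            g_r = np.array([remap[x] for x in subpops])
            sr, _, _ = _components(d2, g_r, subpops)
            v = _phi(sr)[2]
            if np.isfinite(v):
                count[2] += 1
                exceed[2] += v >= phi_ct - 1e-12
        p_st = (1 + exceed[0]) / (count[0] + 1) if count[0] else np.nan
        p_sc = (1 + exceed[1]) / (count[1] + 1) if count[1] else np.nan
        p_ct = (1 + exceed[2]) / (count[2] + 1) if count[2] else np.nan

    total_var = float(sig.sum())
    pct = 100.0 * sig / total_var if total_var != 0 else sig * 0.0
    table = pd.DataFrame(
        {
            "df": np.append(df, df.sum()),
            "sum_sq": np.append(ss, ss.sum()),
            "variance": np.append(sig, total_var),
            "pct_total": np.append(pct, pct.sum()),
            "p": [p_ct, p_sc, p_st, np.nan],
        },
        index=["Among groups", "Among subpopulations within groups",
               "Within subpopulations", "Total"],
    )
    return AmovaResult(
        table=table,
        phi={"Phi_ST": float(phi_st), "Phi_SC": float(phi_sc),
             "Phi_CT": float(phi_ct)},
        n=N, n_groups=int(np.unique(groups).size),
        n_subpops=int(np.unique(subpops).size),
    )
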