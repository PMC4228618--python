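"""Independent brute-force oracles, deliberately coded apart from the library.

Each oracle evaluates a statistic by direct enumeration (all pairs, all
spanning trees, explicit linear solves) so that a formula bug in the library
and in the check would have to coincide to go unnoticed.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

MISSING = 0


# --- genotypic diversity ----------------------------------------------------

def brute_G(genotype_of: list) -> float:
    """Inverse Simpson over genotypes, by enumerating all ordered pairs."""
    n = len(genotype_of)
    same = sum(1 for a in genotype_of for b in genotype_of if a == b)
    return 1.0 / (same / n ** 2)


def brute_E5(genotype_of: list) -> float:
    n = len(genotype_of)
    counts = {}
    for g in genotype_of:
        counts[g] = counts.get(g, 0) + 1
    G = brute_G(genotype_of)
    H = -sum((c / n) * math.log(c / n) for c in counts.values())
    if len(counts) == 1:
        return 1.0
    return (G - 1.0) / (math.exp(H) - 1.0)


# --- linkage ----------------------------------------------------------------

def brute_rbar_d(calls: np.ndarray) -> float:
    """rbar_d via explicit per-pair covariances: sum cov / sum sqrt(var var)."""
    n, L = calls.shape
    pairs = list(itertools.combinations(range(n), 2))
    m = np.zeros((len(pairs), L))
    for p, (i, j) in enumerate(pairs):
        for l in range(L):
            a, b = calls[i, l], calls[j, l]
            m[p, l] = 1.0 if (a != MISSING and b != MISSING and a != b) else 0.0
    P = len(pairs)
    means = m.mean(axis=0)
    var = ((m - means) ** 2).sum(axis=0) / P
    num = 0.0
    den = 0.0
    for j in range(L):
        for k in range(j + 1, L):
            cov = float(((m[:, j] - means[j]) * (m[:, k] - means[k])).sum() / P)
            num += cov
            den += math.sqrt(var[j] * var[k])
    if den == 0:
        return float("nan")
    return num / den


# --- differentiation --------------------------------------------------------

def brute_theta(calls: np.ndarray, labels: list) -> float:
    """theta = (Q - q)/(1 - q) by explicit enumeration of all allele pairs."""
    n, L = calls.shape
    same_w = tot_w = same_b = tot_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            for l in range(L):
                a, b = calls[i, l], calls[j, l]
                if a == MISSING or b == MISSING:
                    continue
                if labels[i] == labels[j]:
                    tot_w += 1
                    same_w += a == b
                else:
                    tot_b += 1
                    same_b += a == b
    Q, q = same_w / tot_w, same_b / tot_b
    return (Q - q) / (1 - q)


def direct_nei_chesser(freq_rows: list[dict], sizes: list[int]
                       ) -> tuple[float, float]:
    """(H_S_est, H_T_est) coded directly from the haploid formulas."""
    s = len(freq_rows)
    ntilde = s / sum(1.0 / n for n in sizes)
    sum_p2 = [sum(p ** 2 for p in row.values()) for row in freq_rows]
    hs = 1.0 - sum(sum_p2) / s
    HS = ntilde / (ntilde - 1.0) * hs
    alleles = sorted(set().union(*[set(r) for r in freq_rows]))
    pbar = {a: sum(r.get(a, 0.0) for r in freq_rows) / s for a in alleles}
    ht = 1.0 - sum(p ** 2 for p in pbar.values())
    HT = ht + HS / (ntilde * s)
    return HS, HT


# --- AMOVA --------------------------------------------------------------------

def brute_amova_components(d2: np.ndarray, groups: list, subpops: list
                           ) -> tuple[np.ndarray, np.ndarray]:
    """(sigma2 [a,b,c], df) via explicit SS loops and a linear EMS solve."""
    N = d2.shape[0]

    def ss_sets(labels):
        total = 0.0
        for lab in set(labels):
            idx = [i for i, x in enumerate(labels) if x == lab]
            acc = 0.0
            for i in idx:
                for j in idx:
                    if i < j:
                        acc += d2[i, j]
            total += acc / len(idx)
        return total

    ss_total = ss_sets(["all"] * N)
    ss_wg = ss_sets(list(groups))
    ss_wp = ss_sets(list(subpops))
    ss_ag, ss_ap = ss_total - ss_wg, ss_wg - ss_wp
    g = len(set(groups))
    s = len(set(subpops))
    df = np.array([g - 1, s - g, N - s], dtype=float)

    n_p = {lab: subpops.count(lab) for lab in set(subpops)}
    group_of = {lab: groups[subpops.index(lab)] for lab in set(subpops)}
    n_g = {lab: groups.count(lab) for lab in set(groups)}
    term_g = sum(sum(n_p[p] ** 2 for p in n_p if group_of[p] == glab) / n_g[glab]
                 for glab in n_g)
    n1 = (N - term_g) / df[1]
    n2 = (term_g - sum(v ** 2 for v in n_p.values()) / N) / df[0]
    n3 = (N - sum(v ** 2 for v in n_g.values()) / N) / df[0]
    # MS = A @ sigma, solved exactly
    A = np.array([[n3, n2, 1.0], [0.0, n1, 1.0], [0.0, 0.0, 1.0]])
    ms = np.array([ss_ag / df[0], ss_ap / df[1], ss_wp / df[2]])
    sigma = np.linalg.solve(A, ms)
    return sigma, df


# --- MSN ----------------------------------------------------------------------

def union_of_all_msts(d: np.ndarray) -> set[frozenset]:
    """Edge union over every minimum spanning tree, by full enumeration."""
    k = d.shape[0]
    G = nx.Graph()
    for i in range(k):
        for j in range(i + 1, k):
            G.add_edge(i, j, weight=float(d[i, j]))
    it = nx.SpanningTreeIterator(G, weight="weight", minimum=True)
    union: set[frozenset] = set()
    min_w = None
    for tree in it:
        w = sum(dd["weight"] for _, _, dd in tree.edges(data=True))
        if min_w is None:
            min_w = w
        if w > min_w + 1e-9:
            break
        union |= {frozenset(e) for e in tree.edges()}
    return union
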