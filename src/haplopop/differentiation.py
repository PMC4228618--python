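"""Haploid-adapted population differentiation and gene-flow statistics.

The Nei & Chesser small-sample estimators of within- and total-population
gene diversity, written for haploids (observed-heterozygosity terms vanish
and sample sizes count individuals, not allele pairs):

.. math::

    \\hat{H}_S = \\frac{\\tilde{n}}{\\tilde{n} - 1}
        \\Big(1 - \\overline{\\sum_i \\hat{p}_{ik}^2}\\Big), \\qquad
    \\hat{H}_T = 1 - \\sum_i \\bar{p}_i^2 + \\frac{\\hat{H}_S}{\\tilde{n} s},

with :math:`\\tilde{n}` the harmonic mean subpopulation sample size, *s* the
number of subpopulations, :math:`\\hat{p}_{ik}` the allele-*i* frequency in
subpopulation *k*, and :math:`\\bar{p}_i` the **unweighted** mean of the
subpopulation frequencies (so unequal samples do not distort the total).

Derived statistics:

* :math:`G_{ST} = (\\hat{H}_T - \\hat{H}_S)/\\hat{H}_T` from the multilocus
  means, and the island-model gene-flow estimate
  :math:`N_m = 0.5 (1 - G_{ST})/G_{ST}`;
* true diversities :math:`\\Delta_T = 1/(1-\\hat{H}_T)`,
  :math:`\\Delta_S = 1/(1-\\hat{H}_S)`, their ratio
  :math:`\\Delta_{ST} = \\Delta_T/\\Delta_S` (effective number of
  subpopulations) and its inverse (the share of total diversity already
  inside the average subpopulation);
* Jost's relative differentiation
  :math:`D = [(H_T - H_S)/(1 - H_S)]\\,[s/(s-1)]` from the uncorrected
  diversities, and :math:`D_{est(hap)}` from the estimators above;
* :math:`\\theta = (Q - q)/(1 - q)`, with *Q* the probability that two
  alleles drawn from the same subpopulation are identical and *q* the same
  probability for two alleles from different subpopulations, pooled over
  loci and pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, AlleleMatrix, StrataMap

__all__ = [
    "DifferentiationReport",
    "harmonic_mean_n",
    "nei_chesser_haploid",
    "gst_and_nm",
    "jost_d_haploid",
    "theta_Qq",
    "differentiation_report",
]


def harmonic_mean_n(sizes) -> float:
    """Harmonic mean of per-subpopulation sample sizes."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("no subpopulation sizes")
    if (sizes < 1).any():
        raise ValueError("every subpopulation size must be >= 1; drop empty "
                         "subpopulations upstream")
    return float(sizes.size / np.sum(1.0 / sizes))


def _per_locus_freqs(matrix: AlleleMatrix, labels: np.ndarray, j: int
                     ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Allele-frequency table (subpop x allele) and sizes at locus column j.

    Only subpopulations with >= 2 non-missing calls at the locus enter.
    """
    col = matrix.calls[:, j]
    groups = sorted(set(labels.tolist()))
    alleles = np.unique(col[col != MISSING])
    freq_rows, sizes, used = [], [], []
    for g in groups:
        vals = col[(labels == g) & (col != MISSING)]
        if vals.size < 2:
            continue
        counts = np.array([(vals == a).sum() for a in alleles], dtype=float)
        freq_rows.append(counts / vals.size)
        sizes.append(vals.size)
        used.append(g)
    return np.array(freq_rows), np.array(sizes, dtype=float), used


def nei_chesser_haploid(matrix: AlleleMatrix, strata: StrataMap,
                        partition: str | list[str]) -> pd.DataFrame:
    """Per-locus Nei-Chesser haploid diversity estimators.

    Returns a DataFrame indexed by locus with columns ``s`` (usable
    subpopulations), ``n_tilde``, the uncorrected within/total diversities
    ``h_S``/``h_T`` and the estimators ``H_S_est``/``H_T_est``. Loci with
    fewer than 2 usable subpopulations come back as NaN rows (excluded from
    multilocus means downstream).
    """
    labels = strata.labels(matrix, partition)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need >= 2 subpopulations")
    rows = []
    for j, locus in enumerate(matrix.loci):
        freqs, sizes, used = _per_locus_freqs(matrix, labels, j)
        if len(used) < 2:
            rows.append({"locus": locus, "s": len(used), "n_tilde": np.nan,
                         "h_S": np.nan, "h_T": np.nan,
                         "H_S_est": np.nan, "H_T_est": np.nan})
            continue
        s = len(used)
        ntilde = harmonic_mean_n(sizes)
        h_S = 1.0 - float(np.mean(np.sum(freqs ** 2, axis=1)))
        pbar = freqs.mean(axis=0)                 # unweighted over subpops
        h_T = 1.0 - float(np.sum(pbar ** 2))
        H_S = ntilde / (ntilde - 1.0) * h_S
        H_T = h_T + H_S / (ntilde * s)
        rows.append({"locus": locus, "s": s, "n_tilde": ntilde,
                     "h_S": h_S, "h_T": h_T, "H_S_est": H_S, "H_T_est": H_T})
    return pd.DataFrame(rows).set_index("locus")


def gst_and_nm(H_S: float, H_T: float) -> tuple[float, float]:
    """G_ST = (H_T - H_S)/H_T and island-model N_m = 0.5(1 - G_ST)/G_ST.

    For G_ST <= 0 (no differentiation signal) N_m is infinite.
    """
    if not H_T > 0:
        raise ValueError("H_T must be positive")
    gst = (H_T - H_S) / H_T
    nm = 0.5 * (1.0 - gst) / gst if gst > 0 else float("inf")
    return float(gst), float(nm)


def jost_d_haploid(H_S: float, H_T: float, s: int) -> dict[str, float]:
    """Jost-style diversity ratios and D from a (H_S, H_T, s) triple.

    Returns Delta_T, Delta_S, Delta_ST, Delta_S/Delta_T and
    D = [(H_T - H_S)/(1 - H_S)] * [s/(s - 1)]. The s/(s-1) factor uses the
    number of subpopulations.
    """
    if s < 2:
        raise ValueError("need s >= 2 subpopulations")
    if H_S >= 1:
        raise ValueError("H_S must be < 1")
    delta_T = 1.0 / (1.0 - H_T)
    delta_S = 1.0 / (1.0 - H_S)
    d = (H_T - H_S) / (1.0 - H_S) * s / (s - 1.0)
    return {
        "Delta_T": delta_T,
        "Delta_S": delta_S,
        "Delta_ST": delta_T / delta_S,
        "Delta_S_over_T": delta_S / delta_T,
        "D": float(d),
    }


def theta_Qq(matrix: AlleleMatrix, strata: StrataMap,
             partition: str | list[str]) -> tuple[float, float, float]:
    """theta = (Q - q)/(1 - q) from pooled pair identity frequencies.

    Q pools, over loci, all within-subpopulation pairs of non-missing calls;
    q pools all between-subpopulation pairs. Returns (theta, Q, q); theta is
    NaN when q = 1 (globally monomorphic).
    """
    labels = strata.labels(matrix, partition)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need >= 2 subpopulations")
    same_w = tot_w = same_b = tot_b = 0
    n = matrix.n_individuals
    iu, ju = np.triu_indices(n, k=1)
    within = labels[iu] == labels[ju]
    for j in range(matrix.n_loci):
        col = matrix.calls[:, j]
        a, b = col[iu], col[ju]
        ok = (a != MISSING) & (b != MISSING)
        eq = (a == b) & ok
        same_w += int(np.sum(eq & within))
        tot_w += int(np.sum(ok & within))
        same_b += int(np.sum(eq & ~within))
        tot_b += int(np.sum(ok & ~within))
    if tot_w == 0 or tot_b == 0:
        raise ValueError("partition yields no within- or between-subpopulation pairs")
    Q = same_w / tot_w
    q = same_b / tot_b
    theta = (Q - q) / (1.0 - q) if q < 1 else float("nan")
    return float(theta), float(Q), float(q)


@dataclass(frozen=True)
class DifferentiationReport:
    """Per-locus estimators plus the multilocus differentiation summary."""

    partition: str
    per_locus: pd.DataFrame
    summary: pd.Series         # multilocus statistics
    sem: pd.Series             # SEM across loci for the per-locus statistics

    def table(self, floor_D_est: bool = True) -> pd.Series:
        """Rendered summary; D_est(hap) floored at 0 like a report table."""
        out = self.summary.copy()
        if floor_D_est and out["D_est_hap"] < 0:
            out["D_est_hap"] = 0.0
        return out


def differentiation_report(matrix: AlleleMatrix, strata: StrataMap,
                           partition: str | list[str]) -> DifferentiationReport:
    """Full Table-2-style differentiation battery for one partition.

    Per-locus Nei-Chesser estimators feed per-locus Jost ratios and D; the
    multilocus G_ST/N_m and D/D_est(hap) use the unweighted locus means of
    the diversity estimates. theta comes from pooled pair frequencies.
    """
    nc = nei_chesser_haploid(matrix, strata, partition)
    usable = nc.dropna(subset=["H_S_est", "H_T_est"])
    if usable.empty:
        raise ValueError("no locus with >= 2 usable subpopulations")
    per_locus = usable.copy()
    jost_cols: dict[str, list[float]] = {}
    for locus, row in usable.iterrows():
        s = int(row["s"])
        est = jost_d_haploid(row["H_S_est"], row["H_T_est"], s)
        raw = jost_d_haploid(row["h_S"], row["h_T"], s)
        rec = {
            "N_e_total": 1.0 / (1.0 - row["h_T"]) if row["h_T"] < 1 else np.inf,
            "Delta_ST": est["Delta_ST"],
            "Delta_S_over_T": est["Delta_S_over_T"],
            "D": raw["D"],
            "D_est_hap": est["D"],
        }
        for k, v in rec.items():
            jost_cols.setdefault(k, []).append(v)
    for k, v in jost_cols.items():
        per_locus[k] = v

    H_S_bar = float(per_locus["H_S_est"].mean())
    H_T_bar = float(per_locus["H_T_est"].mean())
    s_mode = int(per_locus["s"].mode().iloc[0])
    gst, nm = gst_and_nm(H_S_bar, H_T_bar)
    est_bar = jost_d_haploid(H_S_bar, H_T_bar, s_mode)
    raw_bar = jost_d_haploid(float(per_locus["h_S"].mean()),
                             float(per_locus["h_T"].mean()), s_mode)
    theta, Q, q = theta_Qq(matrix, strata, partition)

    labels = strata.labels(matrix, partition)
    sizes = pd.Series(labels).value_counts()
    summary = pd.Series({
        "s": float(s_mode),
        "n_tilde": harmonic_mean_n(sizes.to_numpy()),
        "N_e": float(per_locus["N_e_total"].mean()),
        "Delta_ST": float(per_locus["Delta_ST"].mean()),
        "Delta_S_over_T": float(per_locus["Delta_S_over_T"].mean()),
        "D": float(per_locus["D"].mean()),
        "D_est_hap": est_bar["D"],
        "theta": theta,
        "Q": Q,
        "q": q,
        "G_ST": gst,
        "N_m": nm,
        "H_S_est": H_S_bar,
        "H_T_est": H_T_bar,
        "D_est_hap_raw": est_bar["D"],
    })
    L = len(per_locus)
    sem = per_locus[["N_e_total", "Delta_ST", "Delta_S_over_T", "D",
                     "D_est_hap", "H_S_est", "H_T_est"]].std(ddof=1) / np.sqrt(L)
    name = partition if isinstance(partition, str) else "+".join(partition)
    return DifferentiationReport(partition=name, per_locus=per_locus,
                                 summary=summary, sem=sem)
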