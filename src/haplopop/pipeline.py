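"""One-command analysis battery: QC, diversity, genotypic indices, linkage
disequilibrium, differentiation, AMOVA and the genotype network.

Every stage is a pure function of (input data, configuration, seed); the
bundle is written as tidy TSVs plus one machine-readable JSON summary whose
schema is versioned. All data-driven decisions (dropped loci, empty strata,
floored estimates) are logged into the summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amova import amova, distance_matrix
from .differentiation import differentiation_report
from .diversity import compare_group_diversity, locus_summary, summarize_with_sem
from .genotypic import (census, evenness_E5, genotype_accumulation,
                        max_pct_genotypic_diversity, stoddart_taylor_G)
from .io import (AlleleMatrix, StrataMap, null_allele_filter,
                 read_csv_genotypes, read_genepop)
from .linkage import index_of_association, ld_permutation_test
from .msn import export_network, network_from_census

SCHEMA_VERSION = 1

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``scenarios`` maps a scenario name to a (group_column, subpop_columns)
    pair: AMOVA groups subpopulations (the composite of ``subpop_columns``)
    by ``group_column``, and the differentiation battery partitions by
    ``group_column`` alone.
    """

    genotypes: str | Path | None = None
    out_dir: str | Path = "haplopop_out"
    null_threshold: float = 0.10
    ld_permutations: int = 1000
    amova_permutations: int = 10_000
    seed: int | None = None
    accumulation_reps: int = 100
    scenarios: dict[str, tuple[str, list[str]]] = field(default_factory=lambda: {
        "age_classes": ("age_class", ["tree", "age_class"]),
        "trees": ("tree", ["tree", "age_class"]),
    })

    def __post_init__(self) -> None:
        if (self.ld_permutations > 0 or self.amova_permutations > 0) \
                and self.seed is None:
            raise ValueError("seed is required when any permutation count > 0")


def _load(cfg: RunConfig) -> tuple[AlleleMatrix, StrataMap]:
    path = Path(cfg.genotypes)
    if path.suffix.lower() in (".gen", ".genepop"):
        return read_genepop(path)
    return read_csv_genotypes(path)


def run_pipeline(cfg: RunConfig,
                 data: tuple[AlleleMatrix, StrataMap] | None = None) -> dict:
    """Execute the full battery; returns the JSON-ready summary dict.

    ``data`` bypasses file input (e.g. a simulated dataset). Artifacts are
    written under ``cfg.out_dir``; the summary is also written there as
    ``summary.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    summary: dict = {"schema_version": SCHEMA_VERSION,
                     "haplopop_version": __version__,
                     "seed": cfg.seed, "log": log}

    matrix, strata = data if data is not None else _load(cfg)
    strata.check_complete(matrix)
    rng = np.random.default_rng(cfg.seed)

    # --- stage 1: locus QC -------------------------------------------------
    filtered, qc = null_allele_filter(matrix, cfg.null_threshold)
    qc.to_tsv(out / "locus_qc.tsv")
    if qc.dropped:
        log.append(f"dropped loci over null threshold {cfg.null_threshold}: "
                   f"{', '.join(qc.dropped)}")
    summary["qc"] = {
        "n_individuals": matrix.n_individuals,
        "n_loci_input": matrix.n_loci,
        "n_loci_retained": filtered.n_loci,
        "dropped": list(qc.dropped),
        "null_proportions": {l: float(p) for l, p in
                             qc.frame["null_proportion"].items()},
    }

    # --- stage 2: per-locus diversity (Table-1-style) ----------------------
    div = locus_summary(filtered)
    sem = summarize_with_sem(div)
    table1 = div.copy()
    table1.to_csv(out / "locus_summary.tsv", sep="\t")
    sem.to_csv(out / "locus_summary_mean_sem.tsv", sep="\t")
    summary["diversity"] = {
        "mean_H_E": float(div["H_E"].mean()),
        "sem_H_E": float(sem.loc["H_E", "sem"]),
        "mean_N_e": float(div["N_e"].mean()),
        "mean_N_a": float(div["N_a"].mean()),
        "total_alleles": int(div["N_a"].sum()),
    }

    # --- stage 3: genotypic indices ----------------------------------------
    cen = census(filtered)
    if cen.n_with_missing:
        log.append(f"{cen.n_with_missing} individuals with missing calls "
                   "treated as unmatchable singleton genotypes")
    G = stoddart_taylor_G(cen)
    ghat = max_pct_genotypic_diversity(G, cen.n)
    e5, H = evenness_E5(cen)
    acc = genotype_accumulation(filtered, reps=cfg.accumulation_reps,
                                seed=int(rng.integers(2 ** 31)))
    acc.to_csv(out / "genotype_accumulation.tsv", sep="\t")
    pd.DataFrame([{"N": cen.n, "genotypes": cen.n_genotypes, "G": G,
                   "G_hat_pct": ghat, "E5": e5, "H_prime": H}]
                 ).to_csv(out / "genotypic_indices.tsv", sep="\t", index=False)
    summary["genotypic"] = {"N": cen.n, "n_genotypes": cen.n_genotypes,
                            "G": G, "G_hat_pct": ghat, "E5": e5, "H_prime": H}

    # --- stage 4: group-diversity comparison --------------------------------
    if "age_class" in strata.columns:
        comparisons = {}
        for index in ("N_a", "N_e", "H_E", "N_p"):
            cmp_res = compare_group_diversity(filtered, strata, "age_class", index)
            comparisons[index] = {"t": cmp_res.t, "df": cmp_res.df,
                                  "p": cmp_res.p_value,
                                  "means": cmp_res.means.to_dict(),
                                  "sems": cmp_res.sems.to_dict()}
        summary["group_comparison"] = comparisons

    # --- stage 5: multilocus linkage disequilibrium -------------------------
    if cfg.ld_permutations > 0:
        ld = ld_permutation_test(filtered, cfg.ld_permutations,
                                 seed=int(rng.integers(2 ** 31)))
        np.savetxt(out / "ld_null_distribution.tsv", ld.null_rbar_d,
                   header="rbar_d_null", comments="")
    else:
        ld = index_of_association(filtered)
    summary["linkage"] = {"I_A": ld.I_A, "rbar_d": ld.rbar_d,
                          "V_O": ld.V_O, "V_E": ld.V_E}
    if ld.p_value is not None:
        summary["linkage"]["p"] = ld.p_value
        summary["linkage"]["replicates"] = ld.replicates

    # --- stage 6: differentiation (Table-2-style), both scenarios ----------
    diff_out = {}
    for name, (group_col, _) in cfg.scenarios.items():
        rep = differentiation_report(filtered, strata, group_col)
        rep.per_locus.to_csv(out / f"differentiation_{name}_per_locus.tsv", sep="\t")
        rendered = rep.table(floor_D_est=True)
        rendered.to_csv(out / f"differentiation_{name}.tsv", sep="\t",
                        header=["value"])
        if rep.summary["D_est_hap_raw"] < 0:
            log.append(f"differentiation[{name}]: negative raw D_est(hap) "
                       f"{rep.summary['D_est_hap_raw']:.4g} floored to 0 in table")
        diff_out[name] = {k: float(v) for k, v in rep.summary.items()}
        diff_out[name]["sem"] = {k: float(v) for k, v in rep.sem.items()}
    summary["differentiation"] = diff_out

    # --- stage 7: AMOVA (Table-3-style), both scenarios ---------------------
    dist = distance_matrix(filtered)
    amova_out = {}
    for name, (group_col, subpop_cols) in cfg.scenarios.items():
        groups = strata.labels(filtered, group_col)
        subpops = strata.labels(filtered, subpop_cols)
        res = amova(dist, groups, subpops,
                    permutations=cfg.amova_permutations,
                    seed=int(rng.integers(2 ** 31)))
        res.pct_table().to_csv(out / f"amova_{name}.tsv", sep="\t")
        amova_out[name] = {
            "df": res.table["df"].to_dict(),
            "variance": res.table["variance"].to_dict(),
            "pct_total_raw": res.table["pct_total"].to_dict(),
            "pct_total": res.pct_table()["pct_total"].to_dict(),
            "p": {k: (None if pd.isna(v) else float(v))
                  for k, v in res.table["p"].items()},
            "phi": res.phi,
        }
        if (res.table["variance"].drop("Total") < 0).any():
            log.append(f"amova[{name}]: negative variance component floored "
                       "to 0 in the % column only")
    summary["amova"] = amova_out

    # --- stage 8: minimum spanning network ----------------------------------
    complete = filtered.subset_individuals(
        [i for i, row in zip(filtered.individuals, filtered.missing_mask)
         if not row.any()])
    cen_c = census(complete)
    reps = [members[0] for members in cen_c.members.values()]
    rep_matrix = complete.subset_individuals(reps)
    net = network_from_census(cen_c, distance_matrix(rep_matrix),
                              strata_frame=strata.frame)
    export_network(net, out / "msn.graphml", "graphml")
    export_network(net, out / "msn_edges.tsv", "tsv")
    if complete.n_individuals < filtered.n_individuals:
        log.append(f"msn built on the {complete.n_individuals} individuals "
                   "with complete genotypes")
    summary["msn"] = {"n_nodes": net.n_nodes, "n_edges": net.n_edges,
                      "mst_weight": net.mst_weight,
                      "n_loops": net.n_edges - (net.n_nodes - 1)}

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
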