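"""Reading, validating, filtering and writing haploid multilocus genotype data.

The central container is :class:`AlleleMatrix`, an individuals x loci table of
integer allele codes (microsatellite fragment sizes or arbitrary positive
integers) with ``0`` reserved as the missing-data sentinel, fixed at ploidy 1.
Stratification metadata (which host tree and infructescence age class each
isolate came from) lives in a companion :class:`StrataMap`.

Two interchange formats are supported:

* GenePop (haploid single-allele dialect, 2- or 3-digit codes, ``POP`` blocks);
* a tidy CSV with header ``individual,tree,age_class,<locus...>``.

GenePop can carry only one stratification factor, so when both tree and age
class matter the CSV is canonical; the GenePop writer encodes the composite
``tree:age_class`` subpopulation key as the POP label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0

__all__ = [
    "MISSING",
    "AlleleMatrix",
    "StrataMap",
    "LocusQCReport",
    "GenotypeParseError",
    "read_genepop",
    "write_genepop",
    "read_csv_genotypes",
    "write_csv_genotypes",
    "null_allele_filter",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates its dialect."""


@dataclass(frozen=True)
class AlleleMatrix:
    """Haploid individuals x loci matrix of integer allele codes.

    Parameters
    ----------
    individuals : sequence of str
        Unique individual identifiers, one per row.
    loci : sequence of str
        Unique locus identifiers, one per column.
    calls : ndarray of int, shape (n_individuals, n_loci)
        Allele codes; every non-missing call is a positive integer and
        ``0`` marks a missing (null / failed amplification) call.
    """

    individuals: tuple[str, ...]
    loci: tuple[str, ...]
    calls: np.ndarray

    ploidy: int = 1

    def __post_init__(self) -> None:
        individuals = tuple(str(i) for i in self.individuals)
        loci = tuple(str(l) for l in self.loci)
        calls = np.asarray(self.calls, dtype=np.int64)
        object.__setattr__(self, "individuals", individuals)
        object.__setattr__(self, "loci", loci)
        object.__setattr__(self, "calls", calls)
        if len(individuals) < 1 or len(loci) < 1:
            raise ValueError("AlleleMatrix needs at least 1 individual and 1 locus")
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate individual IDs")
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus IDs")
        if calls.shape != (len(individuals), len(loci)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(individuals)} individuals x {len(loci)} loci"
            )
        if (calls < 0).any():
            raise ValueError("allele codes must be positive integers (0 = missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def locus_calls(self, locus: str) -> np.ndarray:
        """Calls at one locus, in individual order (includes missing)."""
        return self.calls[:, self.loci.index(str(locus))]

    def subset_loci(self, keep: Sequence[str]) -> "AlleleMatrix":
        idx = [self.loci.index(str(l)) for l in keep]
        return AlleleMatrix(self.individuals, tuple(self.loci[i] for i in idx),
                            self.calls[:, idx])

    def subset_individuals(self, keep: Sequence[str]) -> "AlleleMatrix":
        idx = [self.individuals.index(str(i)) for i in keep]
        return AlleleMatrix(tuple(self.individuals[i] for i in idx), self.loci,
                            self.calls[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=list(self.individuals),
                            columns=list(self.loci))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleMatrix):
            return NotImplemented
        return (self.individuals == other.individuals
                and self.loci == other.loci
                and np.array_equal(self.calls, other.calls))


@dataclass(frozen=True)
class StrataMap:
    """Per-individual stratification labels.

    Wraps a DataFrame indexed by individual ID whose columns are stratum
    factors (typically ``tree`` and ``age_class``). The composite
    ``tree:age_class`` key induces the finest subpopulation partition.
    """

    frame: pd.DataFrame

    COMPOSITE_SEP = ":"

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        frame.index = frame.index.astype(str)
        for c in frame.columns:
            frame[c] = frame[c].astype(str)
        if frame.index.has_duplicates:
            raise ValueError("duplicate individual IDs in strata")
        object.__setattr__(self, "frame", frame)

    @classmethod
    def from_labels(cls, individuals: Sequence[str],
                    tree: Sequence[str] | None = None,
                    age_class: Sequence[str] | None = None,
                    **extra: Sequence[str]) -> "StrataMap":
        data: dict[str, list[str]] = {}
        if tree is not None:
            data["tree"] = [str(x) for x in tree]
        if age_class is not None:
            data["age_class"] = [str(x) for x in age_class]
        for k, v in extra.items():
            data[k] = [str(x) for x in v]
        return cls(pd.DataFrame(data, index=[str(i) for i in individuals]))

    @property
    def individuals(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def labels(self, matrix: AlleleMatrix, columns: str | Sequence[str]) -> np.ndarray:
        """Stratum label per individual of ``matrix``, in matrix row order.

        ``columns`` may be a single factor name or several, in which case the
        composite key joins them with ``:``.
        """
        if isinstance(columns, str):
            columns = [columns]
        missing_cols = [c for c in columns if c not in self.frame.columns]
        if missing_cols:
            raise KeyError(f"unknown stratum column(s): {missing_cols}")
        missing_ind = [i for i in matrix.individuals if i not in self.frame.index]
        if missing_ind:
            raise KeyError(f"individuals without strata entry: {missing_ind[:5]}")
        sub = self.frame.loc[list(matrix.individuals), list(columns)]
        return sub.astype(str).agg(self.COMPOSITE_SEP.join, axis=1).to_numpy()

    def subpopulation_key(self, matrix: AlleleMatrix) -> np.ndarray:
        """Finest partition: composite of all stratum columns."""
        return self.labels(matrix, list(self.frame.columns))

    def check_complete(self, matrix: AlleleMatrix) -> None:
        missing = set(matrix.individuals) - set(self.frame.index)
        if missing:
            raise ValueError(f"strata missing for individuals: {sorted(missing)[:5]}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StrataMap):
            return NotImplemented
        return self.frame.equals(other.frame)


@dataclass(frozen=True)
class LocusQCReport:
    """Per-locus null-allele (missing-call) proportions and retention flags."""

    frame: pd.DataFrame  # index = locus, columns = null_proportion, retained
    threshold: float

    @property
    def retained(self) -> tuple[str, ...]:
        return tuple(self.frame.index[self.frame["retained"]])

    @property
    def dropped(self) -> tuple[str, ...]:
        return tuple(self.frame.index[~self.frame["retained"]])

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "locus", out.index)
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GenePop (haploid single-allele dialect)
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path: str | Path) -> tuple[AlleleMatrix, StrataMap]:
    """Read a haploid GenePop file.

    One allele per locus, 2- or 3-digit zero-padded codes; ``0``/``00``/``000``
    is missing. POP blocks become the ``pop`` stratum column; if the POP label
    (the ID of the block's last individual, per GenePop convention we use the
    first individual's label prefix) contains the composite separator ``:``,
    it is split back into ``tree`` and ``age_class``.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeParseError("empty GenePop file")
    # line 1: title; locus names until the first POP
    i = 1
    loci: list[str] = []
    while i < len(lines) and not _POP_RE.match(lines[i]):
        # locus names may be comma-separated on one line or one per line
        for name in lines[i].replace(",", " ").split():
            loci.append(name)
        i += 1
    if not loci:
        raise GenotypeParseError("no locus names before first POP")
    individuals: list[str] = []
    pops: list[str] = []
    rows: list[list[int]] = []
    pop_idx = 0
    pop_start_count = 0
    while i < len(lines):
        if _POP_RE.match(lines[i]):
            if pop_idx > 0 and len(individuals) == pop_start_count:
                raise GenotypeParseError(f"empty POP block before line {i + 1}")
            pop_idx += 1
            pop_start_count = len(individuals)
            i += 1
            continue
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if pop_idx == 0:
            raise GenotypeParseError(f"genotype record before first POP at line {i + 1}")
        if "," not in line:
            raise GenotypeParseError(f"missing ',' separator at line {i + 1}")
        ident, geno = line.split(",", 1)
        codes = geno.split()
        if len(codes) != len(loci):
            raise GenotypeParseError(
                f"line {i + 1}: {len(codes)} allele codes but header declares "
                f"{len(loci)} loci")
        try:
            row = [int(c) for c in codes]
        except ValueError as exc:
            raise GenotypeParseError(f"line {i + 1}: non-integer allele code") from exc
        individuals.append(ident.strip())
        pops.append(f"pop{pop_idx}")
        rows.append(row)
        i += 1
    if pop_idx == 0:
        raise GenotypeParseError("no POP block found")
    if len(individuals) == pop_start_count:
        raise GenotypeParseError("empty final POP block")
    matrix = AlleleMatrix(tuple(individuals), tuple(loci), np.array(rows))
    # individual IDs written by write_genepop carry the composite key as a
    # "key|id" prefix; recover tree/age_class when present
    if all(StrataMap.COMPOSITE_SEP in ind and "|" in ind for ind in individuals):
        keys = [ind.split("|", 1)[0] for ind in individuals]
        ids = [ind.split("|", 1)[1] for ind in individuals]
        trees = [k.split(StrataMap.COMPOSITE_SEP)[0] for k in keys]
        ages = [k.split(StrataMap.COMPOSITE_SEP)[1] for k in keys]
        matrix = AlleleMatrix(tuple(ids), tuple(loci), np.array(rows))
        strata = StrataMap.from_labels(ids, tree=trees, age_class=ages)
    else:
        strata = StrataMap.from_labels(individuals, pop=pops)
    return matrix, strata


def write_genepop(matrix: AlleleMatrix, strata: StrataMap, path: str | Path,
                  title: str = "haplopop export", digits: int = 3) -> None:
    """Write the haploid single-allele GenePop dialect.

    The finest subpopulation partition (composite of all stratum columns)
    defines POP blocks; the composite key is prefixed to each individual ID as
    ``key|id`` so a round trip recovers both stratification factors.
    """
    if digits not in (2, 3):
        raise ValueError("GenePop allele codes are 2- or 3-digit")
    if int(matrix.calls.max()) >= 10 ** digits:
        raise ValueError(f"allele code too large for {digits}-digit GenePop")
    strata.check_complete(matrix)
    keys = strata.subpopulation_key(matrix)
    two_factor = len(strata.columns) > 1
    lines = [title]
    lines.extend(matrix.loci)
    for key in dict.fromkeys(keys):  # preserve first-appearance order
        lines.append("POP")
        for i, (ind, row) in enumerate(zip(matrix.individuals, matrix.calls)):
            if keys[i] != key:
                continue
            label = f"{key}|{ind}" if two_factor else ind
            codes = " ".join(f"{c:0{digits}d}" for c in row)
            lines.append(f"{label}, {codes}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tidy CSV
# ---------------------------------------------------------------------------

def read_csv_genotypes(path: str | Path) -> tuple[AlleleMatrix, StrataMap]:
    """Read the tidy CSV dialect ``individual,tree,age_class,<locus...>``.

    Blank cells and NA are missing calls. Age-class values must be ``new`` or
    ``old``; duplicate individual IDs are an error.
    """
    df = pd.read_csv(path, dtype={"individual": str, "tree": str, "age_class": str})
    required = ["individual", "tree", "age_class"]
    for col in required:
        if col not in df.columns:
            raise GenotypeParseError(f"CSV missing required column {col!r}")
    loci = [c for c in df.columns if c not in required]
    if not loci:
        raise GenotypeParseError("CSV has no locus columns")
    if df["individual"].duplicated().any():
        dup = df["individual"][df["individual"].duplicated()].iloc[0]
        raise GenotypeParseError(f"duplicate individual ID {dup!r}")
    bad_age = set(df["age_class"].dropna()) - {"new", "old"}
    if bad_age:
        raise GenotypeParseError(f"unknown age_class value(s): {sorted(bad_age)}")
    calls = df[loci].fillna(MISSING).to_numpy(dtype=np.int64)
    matrix = AlleleMatrix(tuple(df["individual"]), tuple(loci), calls)
    strata = StrataMap.from_labels(df["individual"], tree=df["tree"],
                                   age_class=df["age_class"])
    return matrix, strata


def write_csv_genotypes(matrix: AlleleMatrix, strata: StrataMap,
                        path: str | Path) -> None:
    strata.check_complete(matrix)
    sub = strata.frame.loc[list(matrix.individuals)]
    df = pd.DataFrame({"individual": list(matrix.individuals)})
    df["tree"] = sub.get("tree", sub.get("pop", "1")).to_numpy()
    df["age_class"] = sub.get("age_class", pd.Series("new", index=sub.index)).to_numpy()
    for j, locus in enumerate(matrix.loci):
        col = matrix.calls[:, j].astype(object)
        col[matrix.calls[:, j] == MISSING] = ""
        df[locus] = col
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Null-allele QC
# ---------------------------------------------------------------------------

def null_allele_filter(matrix: AlleleMatrix, threshold: float = 0.10
                       ) -> tuple[AlleleMatrix, LocusQCReport]:
    """Drop loci whose missing-call proportion exceeds ``threshold``.

    Null alleles are operationally defined as amplification failures, i.e.
    missing calls; loci retained keep their remaining missing calls as
    missing. Default threshold 0.10 is a conventional cutoff separating
    low-level dropout (a few percent) from systematic null loci.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    prop = (matrix.calls == MISSING).mean(axis=0)
    retained = prop <= threshold
    report = LocusQCReport(
        pd.DataFrame({"null_proportion": prop, "retained": retained},
                     index=list(matrix.loci)),
        threshold=threshold,
    )
    if not retained.any():
        raise ValueError(
            f"all loci exceed the null-allele threshold {threshold}; "
            "raise the threshold or inspect the data")
    keep = [l for l, r in zip(matrix.loci, retained) if r]
    return matrix.subset_loci(keep), report
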