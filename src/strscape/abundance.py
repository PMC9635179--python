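"""Chromosome-by-species STR abundance matrices.

The cross-species analysis works on integer count tables: one row per
chromosome label, one column per species.  Karyotypes differ across the
nine study species — great apes carry the split chromosomes 2A/2B, the
tables carry split 7A/7B rows, rodents lack chromosomes 21/22, mouse lacks
20 — so some cells are *structural zeros*: the chromosome simply does not
exist in that species.  Structural zeros are retained as 0 in clustering
feature vectors but excluded from ANOVA observations, since they are
karyotype artifacts rather than measurements.

Packaged fixtures transcribe the published per-chromosome abundance tables
for the nine species (rat, mouse, gelada, olive baboon, macaque, gorilla,
chimpanzee, bonobo, human) in the mono-, di- and trinucleotide categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

SPECIES_ORDER = (
    "rat",
    "mouse",
    "gelada",
    "baboon",
    "macaque",
    "gorilla",
    "chimpanzee",
    "bonobo",
    "human",
)

#: Row-label universe: autosomes 1-22 with the great-ape 2A/2B split and the
#: table's 7A/7B split, plus X.  Order is fixed for deterministic output.
CHROM_ORDER = (
    ["1", "2", "2A", "2B"]
    + [str(i) for i in range(3, 7)]
    + ["7", "7A", "7B"]
    + [str(i) for i in range(8, 23)]
    + ["X"]
)

_SPLIT_ROWS = {"2": ("2A", "2B"), "7": ("7A", "7B")}

_FIXTURE_FILES = {
    "mono": "abundance_mono.tsv",
    "di": "abundance_di.tsv",
    "tri": "abundance_tri.tsv",
}


@dataclass(frozen=True)
class SpeciesMeta:
    """One study species: phylogenetic group, assembly size, karyotype."""

    name: str
    group: str  # rodent | Old World monkey | great ape
    genome_size: int
    absent_chromosomes: frozenset[str]


def load_species_meta() -> dict[str, SpeciesMeta]:
    """The nine packaged species with genome sizes and absent chromosomes."""
    with resources.files("strscape.data").joinpath("species.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    meta = {}
    for row in df.itertuples(index=False):
        absent = frozenset(str(row.absent_chromosomes).split(","))
        meta[row.name] = SpeciesMeta(
            row.name, row.group, int(row.genome_size), absent
        )
    return meta


def default_karyotype() -> dict[str, frozenset[str]]:
    """species -> chromosomes absent from its karyotype (packaged metadata)."""
    return {name: m.absent_chromosomes for name, m in load_species_meta().items()}


def _chrom_sort_key(label: str):
    order = {c: i for i, c in enumerate(CHROM_ORDER)}
    return (0, order[label]) if label in order else (1, label)


class AbundanceMatrix:
    """Integer count table: chromosomes x species, with a structural-zero mask.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative integer counts; index = chromosome labels, columns =
        species names, both unique.
    structural_zeros : pandas.DataFrame of bool, optional
        True where the chromosome does not exist in the species.  Such
        cells must hold value 0.  Default: no structural zeros.
    category : str or tuple, optional
        "mono" | "di" | "tri", or a ``(unit, repeats)`` stratum key.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        structural_zeros: pd.DataFrame | None = None,
        category=None,
    ):
        values = values.copy()
        if values.index.has_duplicates:
            raise ValueError("duplicate chromosome labels")
        if values.columns.has_duplicates:
            raise ValueError("duplicate species labels")
        if values.size == 0:
            raise ValueError("empty abundance matrix")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("non-numeric counts in abundance table")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite counts in abundance table")
        if np.any(arr < 0):
            raise ValueError("negative counts in abundance table")
        if np.any(arr != np.round(arr)):
            raise ValueError("non-integer counts in abundance table")
        self.values = values.astype(np.int64)
        if structural_zeros is None:
            structural_zeros = pd.DataFrame(
                False, index=values.index, columns=values.columns
            )
        structural_zeros = structural_zeros.reindex_like(self.values).fillna(False)
        if np.any(self.values.to_numpy()[structural_zeros.to_numpy()] != 0):
            raise ValueError("structural-zero cell carries a nonzero count")
        self.structural_zeros = structural_zeros.astype(bool)
        self.category = category

    # -- basic accessors -------------------------------------------------
    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.values.index)

    def column_totals(self) -> pd.Series:
        """Per-species genome total over all chromosome rows."""
        return self.values.sum(axis=0)

    def observations(self) -> pd.DataFrame:
        """Tidy (chromosome, species, count) triples, structural zeros excluded."""
        long = self.values.stack().rename("count").reset_index()
        long.columns = ["chromosome", "species", "count"]
        mask = self.structural_zeros.stack().reset_index(drop=True)
        return long[~mask.to_numpy()].reset_index(drop=True)

    # -- transforms ------------------------------------------------------
    def harmonize(self, merge_split: bool = True) -> "AbundanceMatrix":
        """Merge split chromosome rows (2A+2B -> 2, 7A+7B -> 7).

        Split rows exist because great apes carry two chromosomes homologous
        to the single chromosome 2 of the other species; summing the split
        rows restores comparability of the row vectors across karyotypes.
        A merged cell is structural only where every contributing cell was
        structural.  Idempotent; with ``merge_split=False`` a copy of the
        matrix passes through unchanged.
        """
        if not merge_split:
            return AbundanceMatrix(self.values, self.structural_zeros, self.category)
        values = self.values.copy()
        mask = self.structural_zeros.copy()
        for merged, parts in _SPLIT_ROWS.items():
            present = [p for p in parts if p in values.index]
            if not present:
                continue
            summed = values.loc[present].sum(axis=0)
            merged_mask = mask.loc[present].all(axis=0)
            if merged in values.index:
                summed = summed + values.loc[merged]
                merged_mask = merged_mask & mask.loc[merged]
                values = values.drop(index=merged)
                mask = mask.drop(index=merged)
            values = values.drop(index=present)
            mask = mask.drop(index=present)
            values.loc[merged] = summed
            mask.loc[merged] = merged_mask
        order = sorted(values.index, key=_chrom_sort_key)
        return AbundanceMatrix(
            values.loc[order], mask.loc[order], self.category
        )

    # -- I/O -------------------------------------------------------------
    def write_table(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "chromosome"
        out.to_csv(path, sep="\t")

    def __repr__(self) -> str:
        cat = f", category={self.category!r}" if self.category else ""
        return (
            f"AbundanceMatrix({len(self.chromosomes)} chromosomes x "
            f"{len(self.species)} species{cat})"
        )


def load_table(
    path: str | Path,
    karyotype: Mapping[str, frozenset[str]] | None = None,
    category=None,
) -> AbundanceMatrix:
    """Read a chromosome-by-species TSV into a validated matrix.

    ``karyotype`` maps species to chromosome labels absent from that
    species; matching cells (which must read 0 or blank) become structural
    zeros.  Blank/NA cells are accepted only on absent chromosomes.
    """
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    mask = pd.DataFrame(False, index=df.index, columns=df.columns)
    if karyotype:
        for sp in df.columns:
            absent = karyotype.get(sp, frozenset())
            mask.loc[df.index.isin(absent), sp] = True
    if df.isna().any().any():
        na_outside = df.isna() & ~mask
        if na_outside.any().any():
            bad = list(df.index[na_outside.any(axis=1)])
            raise ValueError(f"blank cells outside absent chromosomes: rows {bad}")
        df = df.fillna(0)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"unparseable numeric column {col!r} in {path}")
    return AbundanceMatrix(df, mask, category=category)


def write_table(m: AbundanceMatrix, path: str | Path) -> None:
    m.write_table(path)


def column_totals(m: AbundanceMatrix) -> dict[str, int]:
    """Per-species genome totals (the published tables' Sum row)."""
    return {sp: int(v) for sp, v in m.column_totals().items()}


def harmonize(m: AbundanceMatrix, merge_split: bool = True) -> AbundanceMatrix:
    return m.harmonize(merge_split=merge_split)


def _normalize_chrom(label: str) -> str:
    c = str(label)
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper()
    return c


def build_matrix(
    per_species_counts: Mapping[str, Mapping[str, int]],
    karyotype: Mapping[str, frozenset[str]] | None = None,
    category=None,
) -> AbundanceMatrix:
    """Assemble a matrix from per-species ``chromosome -> count`` mappings.

    Rows are the union of chromosomes across species, in canonical order.
    A chromosome missing from one species' mapping is a structural zero for
    that species (or, when a karyotype is supplied, exactly the karyotype's
    absent chromosomes are structural).  Labels must resolve to the shared
    row-label universe; a ``chr`` prefix is stripped.
    """
    if not per_species_counts:
        raise ValueError("no species supplied")
    normed: dict[str, dict[str, int]] = {}
    bad: list[str] = []
    for sp, counts in per_species_counts.items():
        normed[sp] = {}
        for chrom, v in counts.items():
            c = _normalize_chrom(chrom)
            if c not in CHROM_ORDER:
                bad.append(str(chrom))
            normed[sp][c] = normed[sp].get(c, 0) + int(v)
    if bad:
        raise ValueError(f"unmappable chromosome labels: {sorted(set(bad))}")
    rows = sorted({c for counts in normed.values() for c in counts}, key=_chrom_sort_key)
    if not rows:
        raise ValueError("no chromosomes supplied")
    species = list(per_species_counts)
    values = pd.DataFrame(0, index=rows, columns=species, dtype=np.int64)
    mask = pd.DataFrame(False, index=rows, columns=species)
    for sp in species:
        for c in rows:
            if c in normed[sp]:
                values.loc[c, sp] = normed[sp][c]
            elif karyotype is None or c in karyotype.get(sp, frozenset()):
                mask.loc[c, sp] = True
    values.index.name = "chromosome"
    return AbundanceMatrix(values, mask, category=category)


def load_fixture(category: str) -> AbundanceMatrix:
    """One of the packaged nine-species abundance tables: mono, di or tri."""
    if category not in _FIXTURE_FILES:
        raise ValueError(f"category must be one of {sorted(_FIXTURE_FILES)}")
    ref = resources.files("strscape.data").joinpath(_FIXTURE_FILES[category])
    with resources.as_file(ref) as path:
        return load_table(path, karyotype=default_karyotype(), category=category)
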