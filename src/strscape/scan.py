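"""Perfect STR detection over nucleotide sequences and FASTA files.

The scanner walks a sequence left to right.  At position ``i`` it compares
the window ``seq[i:i+n]`` with ``seq[i+n:i+2n]``; when the two halves are
equal (and pure ACGT) it has found two tandem copies of a candidate unit,
extends by whole units for as long as the next n-mer equals the seed unit,
and — if the completed-copy count M reaches the category threshold and the
unit is in the catalog — emits a locus and resumes at the end of the run.
Otherwise it advances.  Only complete copies count: trailing partial units
never contribute to M.

Default thresholds are M >= 10 for mononucleotide, M >= 6 for dinucleotide
and M >= 4 for trinucleotide repeats.  Each unit length is scanned in an
independent pass, so a poly-A tract of 12 is one mononucleotide locus and
is never re-reported as an ``AA`` dinucleotide (``AA`` is not a catalog
unit).

Coordinates are 0-based, half-open.  Phase matters and the leftmost
qualifying window wins: ``ACACACACACAC...`` is attributed to unit AC while
``CACACACACACA...`` is attributed to CA, so per-motif strata are
phase-sensitive.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .motifs import BASES, Motif, catalog

DEFAULT_MIN_REPEATS = {1: 10, 2: 6, 3: 4}

_PURE = frozenset(BASES)


class FastaFormatError(ValueError):
    """Raised for unparseable FASTA input or duplicate record names."""


@dataclass(frozen=True, order=True)
class STRLocus:
    """One perfect tandem-repeat run.

    ``start`` is a 0-based offset; ``end = start + repeats * len(unit)`` is
    exclusive.  The slice ``seq[start:end]`` equals ``unit`` concatenated
    ``repeats`` times and no further complete copy follows.
    """

    chrom: str
    start: int
    unit: str
    repeats: int

    @property
    def n(self) -> int:
        return len(self.unit)

    @property
    def end(self) -> int:
        return self.start + self.repeats * len(self.unit)

    @property
    def motif(self) -> Motif:
        return Motif(self.unit)


@dataclass
class ScanConfig:
    """Scan parameters: unit lengths, per-length thresholds, case handling."""

    min_repeats: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    unit_lengths: tuple[int, ...] = (1, 2, 3)
    case_fold: bool = True
    chromosome_allowlist: list[str] | None = None

    def __post_init__(self) -> None:
        for n in self.unit_lengths:
            if n not in (1, 2, 3):
                raise ValueError(f"unit length must be 1, 2 or 3, got {n}")
            if self.min_repeats.get(n, 0) < 2:
                raise ValueError(f"min_repeats for n={n} must be >= 2")


def scan_sequence(
    seq: str, n: int, min_repeats: int, chrom: str = ""
) -> list[STRLocus]:
    """Scan one sequence for perfect repeats of unit length ``n``.

    Non-ACGT characters (N runs, IUPAC codes, masking symbols) never begin
    or extend a match.  The caller is responsible for case folding;
    :func:`scan_fasta` folds soft-masked lowercase by default.
    """
    if n not in (1, 2, 3):
        raise ValueError(f"unit length must be 1, 2 or 3, got {n}")
    if min_repeats < 2:
        raise ValueError(f"min_repeats must be >= 2, got {min_repeats}")

    units = catalog(n)
    loci: list[STRLocus] = []
    L = len(seq)
    i = 0
    limit = L - 2 * n
    while i <= limit:
        unit = seq[i : i + n]
        if seq[i + n : i + 2 * n] != unit or not _PURE.issuperset(unit):
            i += 1
            continue
        # two tandem copies found; extend by whole units
        j = i + 2 * n
        while seq[j : j + n] == unit:
            j += n
        m = (j - i) // n
        if m >= min_repeats and unit in units:
            loci.append(STRLocus(chrom, i, unit, m))
        # resume at run end either way: no qualifying run can start inside
        # a shorter pure run of the same unit
        i = j
    return loci


def _iter_fasta(path: str | Path):
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        yield from SeqIO.parse(handle, "fasta")


def scan_fasta(
    path: str | Path, config: ScanConfig | None = None
) -> dict[str, list[STRLocus]]:
    """Scan every record of a FASTA file (plain or gzipped).

    Returns a mapping ``record name -> loci`` covering all configured unit
    lengths, loci sorted by (unit length, start).  Records outside the
    allowlist, when one is set, are skipped.
    """
    config = config or ScanConfig()
    allow = (
        set(config.chromosome_allowlist)
        if config.chromosome_allowlist is not None
        else None
    )
    result: dict[str, list[STRLocus]] = {}
    try:
        records = list(_iter_fasta(path))
    except (ValueError, OSError) as exc:
        raise FastaFormatError(f"cannot parse FASTA {path}: {exc}") from exc
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record name: {rec.id!r}")
        seen.add(rec.id)
        if allow is not None and rec.id not in allow:
            continue
        seq = str(rec.seq)
        if config.case_fold:
            seq = seq.upper()
        loci: list[STRLocus] = []
        for n in sorted(config.unit_lengths):
            loci.extend(scan_sequence(seq, n, config.min_repeats[n], rec.id))
        result[rec.id] = sorted(loci, key=lambda l: (l.n, l.start))
    return result


def tabulate_counts(
    loci: Mapping[str, Iterable[STRLocus]], mode: str = "category"
) -> dict[str, dict]:
    """Per-chromosome locus counts.

    mode="category": counts keyed by unit length n (the per-chromosome
    abundance of mono/di/trinucleotide STRs).  mode="motif_length": counts
    keyed by ``(unit, repeats)`` so strata such as (T, 10) or (CT, 6) can
    be extracted; category totals are the sums of these strata.
    """
    if mode not in ("category", "motif_length"):
        raise ValueError(f"mode must be 'category' or 'motif_length', got {mode!r}")
    table: dict[str, dict] = {}
    for chrom, lst in loci.items():
        counts: dict = {}
        for locus in lst:
            key = locus.n if mode == "category" else (locus.unit, locus.repeats)
            counts[key] = counts.get(key, 0) + 1
        table[chrom] = counts
    return table


def write_loci(loci: Mapping[str, Iterable[STRLocus]], path: str | Path) -> None:
    """BED-like TSV: chrom, start, end, unit, repeats (0-based, end exclusive)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tunit\trepeats\n")
        for chrom in sorted(loci):
            for l in sorted(loci[chrom], key=lambda l: (l.start, l.n)):
                fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.unit}\t{l.repeats}\n")


def read_loci(path: str | Path) -> dict[str, list[STRLocus]]:
    """Inverse of :func:`write_loci`."""
    result: dict[str, list[STRLocus]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["chrom", "start", "end", "unit", "repeats"]:
            raise FastaFormatError(f"unexpected loci header in {path}: {header}")
        for line in fh:
            chrom, start, _end, unit, repeats = line.rstrip("\n").split("\t")
            result.setdefault(chrom, []).append(
                STRLocus(chrom, int(start), unit, int(repeats))
            )
    return result


def write_counts(table: Mapping[str, dict], mode: str, path: str | Path) -> None:
    """Count table TSV: category mode -> chrom, unit_length, count;
    stratified mode -> chrom, unit, repeats, count."""
    with open(path, "w") as fh:
        if mode == "category":
            fh.write("chrom\tunit_length\tcount\n")
            for chrom in sorted(table):
                for n in sorted(table[chrom]):
                    fh.write(f"{chrom}\t{n}\t{table[chrom][n]}\n")
        elif mode == "motif_length":
            fh.write("chrom\tunit\trepeats\tcount\n")
            for chrom in sorted(table):
                for unit, reps in sorted(table[chrom]):
                    fh.write(f"{chrom}\t{unit}\t{reps}\t{table[chrom][(unit, reps)]}\n")
        else:
            raise ValueError(f"unknown mode {mode!r}")
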