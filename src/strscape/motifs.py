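"""Repeat-unit (motif) catalogs for perfect STR scanning.

The scanner recognises every mononucleotide unit, every primitive
dinucleotide unit, and every primitive trinucleotide unit.  A unit is
*primitive* when it is not a whole-number repetition of a shorter string,
so ``AA`` is excluded from the dinucleotide catalog (a run of ``AA`` is a
poly-A tract and belongs to the mononucleotide category) and ``CCC`` from
the trinucleotide catalog.  That leaves 4 mono-, 12 di- and 60
trinucleotide units.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

BASES = "ACGT"

#: Catalog order is fixed: the published unit lists for n = 1 and 2, and
#: A/C/T/G-major enumeration for n = 3.
_MONO = ("A", "C", "T", "G")
_DI = ("AC", "AG", "AT", "CA", "CG", "CT", "GA", "GC", "GT", "TA", "TC", "TG")
_TRI = (
    "AAC", "AAT", "AAG", "ACA", "ACC", "ACT", "ACG", "ATA", "ATC", "ATT",
    "ATG", "AGA", "AGC", "AGT", "AGG", "CAA", "CAC", "CAT", "CAG", "CCA",
    "CCT", "CCG", "CTA", "CTC", "CTT", "CTG", "CGA", "CGC", "CGT", "CGG",
    "TAA", "TAC", "TAT", "TAG", "TCA", "TCC", "TCT", "TCG", "TTA", "TTC",
    "TTG", "TGA", "TGC", "TGT", "TGG", "GAA", "GAC", "GAT", "GAG", "GCA",
    "GCC", "GCT", "GCG", "GTA", "GTC", "GTT", "GTG", "GGA", "GGC", "GGT",
)

_CATALOGS = {1: _MONO, 2: _DI, 3: _TRI}
_CATALOG_SETS = {n: frozenset(units) for n, units in _CATALOGS.items()}


def is_primitive(unit: str) -> bool:
    """True if *unit* is not a whole-number repetition of a shorter string."""
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return False
    return True


@dataclass(frozen=True)
class Motif:
    """A primitive repeat unit of length 1-3 over {A, C, G, T}."""

    unit: str

    def __post_init__(self) -> None:
        n = len(self.unit)
        if n not in _CATALOGS:
            raise ValueError(f"unit length must be 1-3, got {n}: {self.unit!r}")
        if any(b not in BASES for b in self.unit):
            raise ValueError(f"unit must be over ACGT: {self.unit!r}")
        if self.unit not in _CATALOG_SETS[n]:
            raise ValueError(f"unit is not primitive: {self.unit!r}")

    @property
    def n(self) -> int:
        return len(self.unit)

    def __str__(self) -> str:
        return self.unit


def enumerate_motifs(n: int) -> list[Motif]:
    """All catalog units of length ``n`` in fixed order.

    Parameters
    ----------
    n : int
        Unit length, one of 1 (4 units), 2 (12 units) or 3 (60 units).
    """
    if n not in _CATALOGS:
        raise ValueError(f"unit length must be 1, 2 or 3, got {n}")
    return [Motif(u) for u in _CATALOGS[n]]


def catalog(n: int) -> frozenset[str]:
    """The unit strings of length ``n`` as a set, for membership tests."""
    if n not in _CATALOG_SETS:
        raise ValueError(f"unit length must be 1, 2 or 3, got {n}")
    return _CATALOG_SETS[n]


def _check_catalog_completeness() -> None:
    # the tri catalog is exactly the primitive 3-mers; guard against typos
    expect = {"".join(p) for p in product(BASES, repeat=3) if is_primitive("".join(p))}
    assert set(_TRI) == expect and len(_TRI) == 60


_check_catalog_completeness()
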