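"""Synthetic inputs with exact ground truth, for end-to-end testing.

Two generators:

* :func:`plant_genome` writes genomes of i.i.d. uniform ACGT background
  with perfect STR loci planted at known positions.  The background is
  screened with the independent reference detector so that scanning the
  genome at default thresholds returns exactly the planted locus list —
  exact truth tables trump sequence realism here.

* :func:`simulate_profiles` draws nine-species chromosome-by-species count
  matrices as three planted group-mean profiles plus truncated, rounded
  Gaussian noise, emulating the three-cluster structure of the real
  tables; the planted partition is returned for recovery scoring.

Both are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix, load_fixture
from .cluster_stats import REFERENCE_GROUPS, Partition
from .motifs import BASES, Motif
from .oracle import reference_scan_all
from .scan import DEFAULT_MIN_REPEATS, STRLocus

_MIN_GAP = 8  # spacer between planted tracts and sequence edges (>= 2n+1)


@dataclass
class GenomePlantSpec:
    """What to plant: chromosome lengths and (chrom, unit, repeats) loci."""

    chromosome_lengths: dict[str, int]
    loci: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self):
        for chrom, unit, repeats in self.loci:
            if chrom not in self.chromosome_lengths:
                raise ValueError(f"locus on unknown chromosome {chrom!r}")
            motif = Motif(unit)  # validates catalog membership
            if repeats < DEFAULT_MIN_REPEATS[motif.n]:
                raise ValueError(
                    f"planted ({unit},{repeats}) is below the default "
                    f"threshold {DEFAULT_MIN_REPEATS[motif.n]} and would not "
                    "be recoverable"
                )


@dataclass
class GenomeTruthSet:
    """A generated genome plus the exact locus list planted in it."""

    sequences: dict[str, str]
    truth: list[STRLocus]
    seed: int
    fasta: Path | None = None

    def to_fasta(self, path: str | Path, width: int = 70) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        self.fasta = path
        return path

    def truth_by_chrom(self) -> dict[str, list[STRLocus]]:
        out: dict[str, list[STRLocus]] = {c: [] for c in self.sequences}
        for locus in self.truth:
            out[locus.chrom].append(locus)
        for lst in out.values():
            lst.sort(key=lambda l: (l.n, l.start))
        return out


def _background(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(BASES), size=length))


def _place_loci(
    rng: np.random.Generator, length: int, tracts: list[str]
) -> list[int]:
    """Random non-overlapping start offsets with >= _MIN_GAP spacing."""
    need = sum(len(t) for t in tracts) + _MIN_GAP * (len(tracts) + 1)
    if need > length:
        raise ValueError(
            f"cannot pack {len(tracts)} tracts into {length} bases "
            f"(need >= {need})"
        )
    slack = length - need
    cuts = np.sort(rng.integers(0, slack + 1, size=len(tracts)))
    starts = []
    consumed = _MIN_GAP
    for cut, tract in zip(cuts, tracts):
        starts.append(int(cut) + consumed)
        consumed += len(tract) + _MIN_GAP
    return starts


def plant_genome(
    spec: GenomePlantSpec, seed: int, max_retries: int = 100
) -> GenomeTruthSet:
    """Generate a genome whose default-threshold scan is exactly the truth.

    Each chromosome is uniform random ACGT with the requested repeat
    tracts inserted at random positions, flanked by bases drawn outside
    the unit's character set so a planted run can neither extend nor
    phase-shift across its boundary.  The assembled chromosome is screened
    with the reference detector; on any discrepancy (an accidental
    background STR, or interference at a junction) the chromosome is
    redrawn, up to ``max_retries`` times.
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    truth: list[STRLocus] = []
    for chrom in sorted(spec.chromosome_lengths):
        length = spec.chromosome_lengths[chrom]
        planted = [(u, m) for c, u, m in spec.loci if c == chrom]
        tracts = [u * m for u, m in planted]
        expected: list[STRLocus] | None = None
        for _ in range(max_retries):
            starts = _place_loci(rng, length, tracts) if tracts else []
            seq = _background(rng, length)
            for start, (unit, m) in zip(starts, planted):
                tract = unit * m
                seq[start : start + len(tract)] = tract
                breakers = [b for b in BASES if b not in set(unit)]
                seq[start - 1] = str(rng.choice(breakers))
                seq[start + len(tract)] = str(rng.choice(breakers))
            s = "".join(seq)
            candidate = sorted(
                (
                    STRLocus(chrom, st, u, m)
                    for st, (u, m) in zip(starts, planted)
                ),
                key=lambda l: (l.n, l.start),
            )
            found = sorted(
                reference_scan_all(s, chrom), key=lambda l: (l.n, l.start)
            )
            if found == candidate:
                sequences[chrom] = s
                expected = candidate
                break
        if expected is None:
            raise RuntimeError(
                f"could not realise chromosome {chrom!r} free of accidental "
                f"STRs after {max_retries} attempts"
            )
        truth.extend(expected)
    return GenomeTruthSet(sequences, truth, seed)


def random_plant_spec(
    rng: np.random.Generator,
    n_chromosomes: int = 2,
    chrom_length: int = 3000,
    max_loci_per_chrom: int = 4,
) -> GenomePlantSpec:
    """A random feasible planting spec (used by the end-to-end identity
    checks: plant -> scan -> tabulate -> build_matrix)."""
    from .motifs import enumerate_motifs

    lengths = {f"chr{i + 1}": chrom_length for i in range(n_chromosomes)}
    loci = []
    for chrom in lengths:
        for _ in range(int(rng.integers(0, max_loci_per_chrom + 1))):
            n = int(rng.integers(1, 4))
            unit = str(rng.choice([m.unit for m in enumerate_motifs(n)]))
            repeats = int(
                DEFAULT_MIN_REPEATS[n] + rng.integers(0, 6)
            )
            loci.append((chrom, unit, repeats))
    return GenomePlantSpec(lengths, loci)


@dataclass
class ProfileSimSpec:
    """Three planted group-mean profiles + noise over nine species.

    ``group_means`` has one row per cluster (rodent, Old World monkey,
    great ape order) and one column per chromosome.  Species counts are
    drawn as mean + N(0, noise_sd), truncated at 0 and rounded.
    """

    group_means: pd.DataFrame  # 3 x n_chromosomes
    noise_sd: float = 1000.0
    species_per_group: tuple[int, int, int] = (2, 3, 4)
    species_names: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.group_means.shape[0] != 3:
            raise ValueError("group_means must have exactly 3 rows")
        if (self.group_means.to_numpy() < 0).any():
            raise ValueError("group means must be non-negative")
        if self.species_names is None:
            order = ["rodent", "Old World monkey", "great ape"]
            names = []
            for g, size in zip(order, self.species_per_group):
                members = [sp for sp, gg in REFERENCE_GROUPS.items() if gg == g]
                names.extend(members[:size])
            self.species_names = tuple(names)
        if len(self.species_names) != sum(self.species_per_group):
            raise ValueError("species_names length must match species_per_group")


def default_profile_spec(noise_sd: float = 1000.0) -> ProfileSimSpec:
    """Study conditions: group means are the per-cluster means of the
    harmonized mononucleotide fixture; noise sd 1000 counts."""
    h = load_fixture("mono").harmonize()
    groups = pd.Series({sp: REFERENCE_GROUPS[sp] for sp in h.species})
    means = h.values.astype(float).T.groupby(groups).mean()
    means = means.loc[["rodent", "Old World monkey", "great ape"]]
    return ProfileSimSpec(group_means=means, noise_sd=noise_sd)


def simulate_profiles(
    spec: ProfileSimSpec, seed: int
) -> tuple[AbundanceMatrix, Partition]:
    """Draw a nine-species matrix from the spec; returns (matrix, truth)."""
    rng = np.random.default_rng(seed)
    chroms = list(spec.group_means.columns)
    cols = {}
    assignment = {}
    idx = 0
    for g, size in enumerate(spec.species_per_group):
        mean = spec.group_means.iloc[g].to_numpy(dtype=float)
        for _ in range(size):
            name = spec.species_names[idx]
            noise = rng.normal(0.0, spec.noise_sd, size=len(chroms)) if spec.noise_sd else 0.0
            counts = np.round(np.maximum(mean + noise, 0.0)).astype(np.int64)
            cols[name] = counts
            assignment[name] = g + 1
            idx += 1
    values = pd.DataFrame(cols, index=chroms)
    values.index.name = "chromosome"
    return AbundanceMatrix(values, category="simulated"), Partition(assignment)
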