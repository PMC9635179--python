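# Methods

## Perfect-STR detection

The scanner detects *perfect* (pure, uninterrupted) tandem repeats of unit
length n ∈ {1, 2, 3}. At position i it tests whether `seq[i:i+n]` equals
`seq[i+n:i+2n]` with all 2n bases in {A, C, G, T}; two adjacent identical
copies define a candidate run, which is extended one whole unit at a time
while the next n-mer equals the seed unit. The number of complete copies M is
the repeat count; trailing partial copies are ignored. A locus is emitted when
M reaches the category threshold — 10 (mono), 6 (di), 4 (tri) complete
copies — and the seed unit belongs to the catalog of primitive units (4 / 12 /
60 for n = 1 / 2 / 3). Units that are repetitions of a shorter unit (AA, CCC,
…) are excluded from the di/tri catalogs so a poly-A tract is counted once, in
the mononucleotide pass, and never re-counted as AA or AAA.

Numerical/algorithmic choices:

* **Coordinates** are 0-based, half-open; only counts feed the downstream
  statistics, so the convention is internal but fixed.
* **Consumption rule.** After any detected run — emitted, sub-threshold, or
  non-catalog (homopolymer seed in the di/tri pass) — the walk resumes at the
  end of the run; after a window mismatch it advances one base. For
  sub-threshold catalog runs this is provably equivalent to advancing one base
  (no qualifying run can start inside a shorter pure run of the same unit).
  For skipped homopolymer-seeded runs the two conventions can differ at rare
  junctions (e.g. `AAAA·CACACACACACA` in the n = 2 pass: run-end resumption
  attributes the locus to CA at the first position after the poly-A run); the
  package fixes run-end resumption as its convention, applies it identically
  in the scanner and in the reference detector, and documents that per-motif
  strata are phase-sensitive (leftmost qualifying window wins: `ACACAC…` is an
  AC locus, `CACACA…` a CA locus).
* **Ambiguity and masking.** Any character outside ACGT (N, IUPAC codes)
  neither begins nor extends a match. Soft-masked lowercase is folded to
  uppercase by default (`case_fold=False` disables), since genome-wide counts
  should not depend on repeat-masking annotation.
* **Maximum M** is unbounded; thresholds are configurable per unit length with
  a floor of 2 (the definition of "tandem").

The reference detector in `strscape.oracle` recomputes the same semantics from
a different algorithmic idea — a vectorised array marking tandem positions and
a reverse recursion giving complete-copy counts at every offset — and is used
both as the test oracle for the scanner and as the screen inside the
synthetic-genome generator. It is a check on the scanner, not a substitute.

## Abundance matrices and karyotype handling

Counts are organised as integer chromosome × species tables. Two karyotype
mechanisms matter:

* **Structural zeros.** A cell whose chromosome does not exist in a species
  (human 2B, rodent 21/22, mouse 20, …) is flagged structurally zero: retained
  as 0 in clustering feature vectors (the profile genuinely has nothing
  there) but excluded from ANOVA/Friedman observations (it is a karyotype
  artifact, not a measurement). Packaged species metadata records each
  species' absent chromosomes; the gelada column keeps its split 7A/7B rows
  as published.
* **Harmonization.** Split rows are summed (2A+2B → 2, 7A+7B → 7) before
  cross-species comparison, so the great-ape chromosome-2 pair is compared
  with the single chromosome 2 of the other species. Without this merge the
  human column (all of chromosome 2 printed in the 2A row) resembles an Old
  World monkey rather than the other great apes. Harmonization preserves
  column totals exactly and is idempotent; `merge_split=False` disables it.

## Clustering

Species columns are clustered agglomeratively on their harmonized
per-chromosome profiles with Euclidean distance and complete linkage (the
defaults of R's `hclust` on a `dist` matrix); ties are broken by input column
order, output is deterministic, and the k-cut undoes the k−1 highest merges.

**Feature scaling** was a genuinely open design choice, and the package's
default is to replace each chromosome's counts by the ranks of the species on
that chromosome (average ranks on ties) before computing distances
(`scale="rank"`; `scale="none"` gives raw counts). The reason is structural:
on raw counts the rodent-versus-primate count gap dominates every distance, so
the rat–mouse distance (~44,000 in the dinucleotide table) exceeds the entire
Old World monkey / great ape separation (~13,000) and no horizontal three-group
cut can isolate the primate subgroups — the dinucleotide tree cuts into
{rat}, {mouse}, {all primates} under raw counts and under every common variance
transform (log, square root, z-score, proportions). Rank features measure what
the cross-species comparison is actually about — the consistency of the
species ordering chromosome by chromosome — and recover the phylogenetic
three-group structure in all three categories. The descriptive great-ape
outlier statistic deliberately stays on raw counts: it reports mean Euclidean
profile distances within the great apes, where human's trinucleotide profile
sits ~2.5× further from the other three than they sit from each other.

## Statistics

* **Headline test:** two-way fixed-effects ANOVA, `count ~ cluster +
  chromosome`, on non-structural-zero observations of the harmonized table,
  with the three-group phylogenetic labels as the cluster factor. The
  chromosome factor absorbs the large shared chromosome-size component.
* **Alternative design:** one-way repeated-measures ANOVA with chromosome as
  the block, on chromosomes observed in every column (per-cluster means when
  the factor is the cluster grouping).
* **Nonparametric confirmation:** Friedman test across factor levels blocking
  on chromosome; Kruskal–Wallis on pooled observations when blocking is
  impossible (fewer than 2 complete blocks or fewer than 3 levels).
* **Degenerate inputs** raise an explicit error (single-level factor, zero
  residual degrees of freedom, zero variance) rather than returning NaN; a
  saturated fit with a null factor (identical species columns) reports
  F = 0, p = 1.

No multiple-testing correction is applied to per-stratum concordance flags;
stratum-level p-values, where requested, are reported raw (a
Benjamini–Hochberg column can be added by the caller from the raw values).

## Synthetic data

`plant_genome` builds chromosomes of i.i.d. uniform ACGT with requested
perfect-repeat tracts inserted at seeded random positions, each tract flanked
by bases drawn outside the unit's character set and separated from neighbours
and sequence edges by ≥ 8 background bases. Every assembled chromosome is
screened with the reference detector; if the default-threshold scan differs
from the planted list in any way (an accidental background STR, or junction
interference) the chromosome is redrawn, up to a bounded retry count. The
generator therefore guarantees exact truth tables at the cost of sequence
realism: background composition, GC structure, masking and interrupted or
compound repeats of real genomes are not emulated, so passing tests establish
correctness of the detection/aggregation machinery, not performance on real
genomic sequence. Chromosomes default to a few kilobases — ample for exact
truth-table checks, since scanner behaviour has no length-dependent logic.

`simulate_profiles` draws nine-species matrices as three planted group-mean
profiles (sizes 2/3/4, mirroring rodents / Old World monkeys / great apes)
plus Gaussian noise truncated at zero and rounded to integer counts. The
default study conditions take the group means from the per-cluster means of
the harmonized mononucleotide fixture and noise sd = 1,000 counts — roughly
the within-group spread of that table and well under the between-group
separation. The planted partition is returned for recovery scoring; at the
default conditions the k = 3 cut recovers it in ≥ 95% of seeded replicates,
while matrices with identical group means match the fixed reference partition
only rarely. The Gaussian noise model is a test harness, not a claim about
count-generating processes in genomes.

## Known limitations

* The scanner targets perfect repeats of units 1–3 only; interrupted,
  compound, or longer-unit STRs are out of scope, as is polymorphism calling.
* The three-cluster concordance is a descriptive agreement check against a
  fixed reference partition, not phylogenetic inference; no bootstrap or
  cophenetic support is computed.
* Per-motif (unit, length) concordance is exercised on synthetic strata;
  genome-scale per-motif matrices for the nine species are external data.
* The packaged tables are transcriptions of printed per-chromosome counts;
  one printed value (human trinucleotide chromosome 6) is unusually large but
  is consistent with its printed column sum and is kept as published.
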