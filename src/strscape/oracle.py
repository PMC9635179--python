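"""Reference perfect-STR detector, implemented independently of the scanner.

Where :mod:`strscape.scan` walks the sequence with string-slice window
comparisons, this module vectorises: it builds a boolean array marking
positions where the n-mer equals the following n-mer (both pure ACGT),
derives the number of complete unit copies at every position with a single
reverse dynamic-programming pass, and then replays the consumption rule
(emit catalog runs at threshold, resume after any detected run).  It exists
so that the scanner can be checked against a second, structurally different
implementation, and so that the synthetic-genome generator can screen its
output without trusting the code under test.
"""

from __future__ import annotations

import numpy as np

from .motifs import BASES, catalog
from .scan import DEFAULT_MIN_REPEATS, STRLocus


def _copies_array(seq: str, n: int) -> np.ndarray:
    """copies[i] = number of complete copies of seq[i:i+n] starting at i
    (0 where the window test fails, i.e. fewer than two pure copies)."""
    L = len(seq)
    copies = np.zeros(L, dtype=np.int64)
    if L < 2 * n:
        return copies
    s = np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)
    pure = np.isin(s, np.frombuffer(BASES.encode(), dtype=np.uint8))
    # tandem[i]: seq[i:i+n] == seq[i+n:i+2n], all 2n bases pure
    eq = s[:-n] == s[n:]
    ok = pure[:-n] & pure[n:]
    tandem = np.ones(L - 2 * n + 1, dtype=bool)
    for k in range(n):
        tandem &= eq[k : L - 2 * n + 1 + k] & ok[k : L - 2 * n + 1 + k]
    # chain[i] = 1 + chain[i+n] while tandem holds: one pass per phase
    chain = np.zeros(L, dtype=np.int64)
    for i in range(L - 2 * n, -1, -1):
        if tandem[i]:
            chain[i] = chain[i + n] + 1
    copies[chain > 0] = chain[chain > 0] + 1
    return copies


def reference_scan(
    seq: str, n: int, min_repeats: int, chrom: str = ""
) -> list[STRLocus]:
    """Reference implementation of the scan over one sequence."""
    if n not in (1, 2, 3):
        raise ValueError(f"unit length must be 1, 2 or 3, got {n}")
    units = catalog(n)
    copies = _copies_array(seq, n)
    loci: list[STRLocus] = []
    i = 0
    L = len(seq)
    while i <= L - 2 * n:
        m = int(copies[i])
        if m < 2:
            i += 1
            continue
        unit = seq[i : i + n]
        if m >= min_repeats and unit in units:
            loci.append(STRLocus(chrom, i, unit, m))
        i += m * n
    return loci


def reference_scan_all(
    seq: str,
    chrom: str = "",
    min_repeats: dict[int, int] | None = None,
) -> list[STRLocus]:
    """Reference scan at all three unit lengths, default thresholds."""
    thresholds = min_repeats or DEFAULT_MIN_REPEATS
    out: list[STRLocus] = []
    for n in sorted(thresholds):
        out.extend(reference_scan(seq, n, thresholds[n], chrom))
    return out
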