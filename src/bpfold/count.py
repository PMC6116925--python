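"""Counting the nested-structure space by dynamic programming.

The number of nested structures of a subsequence S_i..S_j satisfies the
Waterman-Smith decomposition over the pairing state of the last position:

    C[i,j] = C[i,j-1] + sum_{i <= k < j-l, S_k~S_j} C[i,k-1] * C[k+1,j-1]

with C over any empty or single-position interval equal to 1.  Counts are
exact Python integers: they overflow 64-bit arithmetic near n ~ 60 for
pairable sequences, and oracle comparisons require exactness.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import FoldConfig, PairRule, RnaSequence


@dataclass(frozen=True)
class CountMatrix:
    """Upper-triangular table of exact structure counts, 1-based."""

    n: int
    entries: dict[tuple[int, int], int]

    def value(self, i: int, j: int) -> int:
        """C[i,j]; empty intervals (j < i) count the empty structure once."""
        if j < i:
            return 1
        return self.entries[(i, j)]

    @property
    def total(self) -> int:
        return self.value(1, self.n)


def count_matrix(
    seq: RnaSequence | str,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
) -> CountMatrix:
    """Fill the structure-count table for *seq*."""
    if isinstance(seq, str):
        seq = RnaSequence.from_raw(seq)
    cfg = cfg or FoldConfig()
    rule = rule or PairRule()
    n = seq.n
    c: dict[tuple[int, int], int] = {}

    def get(i: int, j: int) -> int:
        return 1 if j < i else c[(i, j)]

    for i in range(1, n + 1):
        c[(i, i)] = 1
    for span in range(1, n):
        for i in range(1, n - span + 1):
            j = i + span
            total = get(i, j - 1)
            for k in range(i, j - cfg.min_loop):
                if cfg.admissible(seq, k, j, rule):
                    total += get(i, k - 1) * get(k + 1, j - 1)
            c[(i, j)] = total
    return CountMatrix(n=n, entries=c)


def count_structures(
    seq: RnaSequence | str,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
) -> int:
    """|P|: number of valid nested structures (1 for the empty sequence)."""
    if isinstance(seq, str):
        seq = RnaSequence.from_raw(seq)
    if seq.n == 0:
        return 1
    return count_matrix(seq, cfg, rule).total


def _length_counts(max_len: int, min_loop: int) -> list[int]:
    """f(m): structure counts when every position pair may pair.

    When complementarity never constrains pairing, C[i,j] depends only on
    the interval length m = j - i + 1, collapsing the counting recursion to

        f(m) = f(m-1) + sum_{k=1..m-l-1} f(k-1) * f(m-k-1)

    with f(0) = ... = f(l+1) = 1.  Exact integers; O(n^2) time.
    """
    f = [1] * (min(min_loop + 2, max_len + 1))
    for m in range(len(f), max_len + 1):
        total = f[m - 1]
        for k in range(1, m - min_loop):
            total += f[k - 1] * f[m - k - 1]
        f.append(total)
    return f


def growth_factor(n: int, min_loop: int = 3) -> float:
    """Per-nucleotide growth factor f(n+1)/f(n) of the structure space.

    Uses the sequence-agnostic (every pair admissible) count; for
    min_loop = 3 the ratio approaches roughly 2.3 for large n.
    """
    if n < 1:
        raise ValueError("n must be positive")
    f = _length_counts(n + 1, min_loop)
    return f[n + 1] / f[n]
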