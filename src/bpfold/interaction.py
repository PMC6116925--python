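"""RNA-RNA interaction prediction: three paradigms under the base-pair model.

1. *Hybridization-only* — maximize intermolecular pairs between S1 and the
   reversed S2 with a Needleman-Wunsch-shaped prefix DP (no gap cost, no
   intramolecular structure).  Fast, but blind to structure within either
   molecule.
2. *Cofold / concatenation* — join the molecules with a non-pairable
   linker ``X`` of length min_loop+1 and run single-sequence base-pair
   maximization; intra- and intermolecular competition is captured, but
   the hybrid structure must stay nested, so kissing interactions are out
   of reach.
3. *Accessibility-based* — score a candidate duplex between sites of the
   two molecules by its pair energy D plus the opening penalties
   dE = -RT*log(Pr_ss) each molecule pays to leave its site unpaired:
   I = D + dE1 + dE2.  Captures kissing stem-loop patterns.

Molecules interact antiparallel: S2 is handled through its reversed view
(position j of the view is position m-j+1 of the original), and every
user-facing result is mapped back to original 5'->3' coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import fold
from .ensemble import basepair_probabilities, partition_matrices, unpaired_probability
from .model import (
    EnergyModel,
    FoldConfig,
    LINKER_CHAR,
    PairRule,
    RnaSequence,
    SecondaryStructure,
)


@dataclass(frozen=True)
class DuplexPair:
    """Two interacting RNAs; S2 is exposed both as-is and reversed."""

    seq1: RnaSequence
    seq2: RnaSequence

    @classmethod
    def from_raw(cls, s1: str, s2: str) -> "DuplexPair":
        return cls(RnaSequence.from_raw(s1), RnaSequence.from_raw(s2))

    @property
    def n(self) -> int:
        return self.seq1.n

    @property
    def m(self) -> int:
        return self.seq2.n

    @property
    def seq2_reversed(self) -> RnaSequence:
        return RnaSequence(self.seq2.residues[::-1])

    def to_original2(self, j_rev: int) -> int:
        """Reversed-view position -> original S2 position."""
        return self.m - j_rev + 1


@dataclass(frozen=True)
class HybridMatrix:
    """Prefix table H, (n+1) x (m+1), row/column 0 all zero."""

    n: int
    m: int
    h: tuple[tuple[int, ...], ...]

    def value(self, i: int, j: int) -> int:
        return self.h[i][j]

    @property
    def optimum(self) -> int:
        return self.h[self.n][self.m]


@dataclass(frozen=True)
class InteractionResult:
    """One predicted interaction in original coordinates of both RNAs."""

    site1: tuple[int, int]
    site2: tuple[int, int]
    inter_pairs: tuple[tuple[int, int], ...]
    energy: float
    duplex_energy: float = 0.0
    delta_e1: float = 0.0
    delta_e2: float = 0.0

    @property
    def favorable(self) -> bool:
        return self.energy < 0


def hybrid_only(
    pair: DuplexPair,
    rule: PairRule | None = None,
    max_results: int | None = 1000,
) -> tuple[HybridMatrix, list[InteractionResult]]:
    """Maximize intermolecular pairs ignoring intramolecular structure.

        H[i,j] = max( H[i-1,j-1] + 1 if S1_i ~ S2rev_j,
                      H[i-1,j], H[i,j-1] )

    Returns the filled prefix matrix and every optimal intermolecular
    pair set (deduplicated, original coordinates).
    """
    rule = rule or PairRule()
    s1, s2r = pair.seq1, pair.seq2_reversed
    n, m = pair.n, pair.m
    if n == 0 or m == 0:
        raise ValueError("both sequences must be non-empty")
    h = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = max(h[i - 1][j], h[i][j - 1])
            if rule.complementary(s1.base(i), s2r.base(j)):
                best = max(best, h[i - 1][j - 1] + 1)
            h[i][j] = best

    # enumerate optimal pair sets by walking back through every case that
    # reproduces the cell value; deduplicate since distinct paths can
    # carry identical pair sets (pure shifts contribute no pairs)
    seen: set[frozenset[tuple[int, int]]] = set()
    stack: list[tuple[int, int, tuple[tuple[int, int], ...]]] = [(n, m, ())]
    while stack and (max_results is None or len(seen) < max_results):
        i, j, acc = stack.pop()
        if i == 0 or j == 0:
            seen.add(frozenset(acc))
            continue
        if (
            rule.complementary(s1.base(i), s2r.base(j))
            and h[i][j] == h[i - 1][j - 1] + 1
        ):
            stack.append((i - 1, j - 1, acc + ((i, j),)))
        if h[i][j] == h[i - 1][j]:
            stack.append((i - 1, j, acc))
        if h[i][j] == h[i][j - 1]:
            stack.append((i, j - 1, acc))

    results = []
    for pairs_rev in seen:
        inter = tuple(
            sorted((i, pair.to_original2(j)) for i, j in pairs_rev)
        )
        if not inter:
            continue
        site1 = (min(i for i, _ in inter), max(i for i, _ in inter))
        site2 = (min(j for _, j in inter), max(j for _, j in inter))
        results.append(
            InteractionResult(
                site1=site1,
                site2=site2,
                inter_pairs=inter,
                energy=-float(len(inter)),
            )
        )
    results.sort(key=lambda r: (r.site1[0], r.site2[0], r.inter_pairs))
    matrix = HybridMatrix(n=n, m=m, h=tuple(tuple(row) for row in h))
    return matrix, results


# ---------------------------------------------------------------------------
# cofold
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CofoldResult:
    """One (sub)optimal hybrid structure of the concatenated sequence."""

    dotbracket: str
    score: float
    intra_pairs1: tuple[tuple[int, int], ...]
    intra_pairs2: tuple[tuple[int, int], ...]
    inter_pairs: tuple[tuple[int, int], ...]
    structure: SecondaryStructure


def concatenate(pair: DuplexPair, cfg: FoldConfig) -> RnaSequence:
    """S1 + X-linker + S2 with the concatenated flag set."""
    linker = LINKER_CHAR * cfg.effective_linker_length
    return RnaSequence(
        pair.seq1.residues + linker + pair.seq2.residues, concatenated=True
    )


def cofold(
    pair: DuplexPair,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
    model: EnergyModel | None = None,
    delta: float = 0.0,
    max_results: int | None = None,
) -> list[CofoldResult]:
    """Concatenation-based prediction via single-sequence folding.

    Pairs touching a linker position are inadmissible (``X`` never
    pairs); there is no special energy for linker-containing loops in
    this model.  Dot-bracket output uses '()' for intramolecular pairs,
    '[]' for linker-spanning (intermolecular) pairs and 'X' for the
    linker itself.
    """
    cfg = cfg or FoldConfig()
    hybrid = concatenate(pair, cfg)
    entries = fold.enumerate_suboptimal(hybrid, cfg, rule, delta=delta, max_results=max_results)
    n1 = pair.n
    lk = cfg.effective_linker_length
    off = n1 + lk  # concatenated index of S2 position p is off + p

    results = []
    for entry in entries:
        intra1, intra2, inter = [], [], []
        chars = ["."] * hybrid.n
        for p in range(n1 + 1, n1 + lk + 1):
            chars[p - 1] = LINKER_CHAR
        for a, b in entry.structure.sorted_pairs():
            if b <= n1:
                intra1.append((a, b))
                chars[a - 1], chars[b - 1] = "(", ")"
            elif a > off:
                intra2.append((a - off, b - off))
                chars[a - 1], chars[b - 1] = "(", ")"
            else:
                inter.append((a, b - off))
                chars[a - 1], chars[b - 1] = "[", "]"
        results.append(
            CofoldResult(
                dotbracket="".join(chars),
                score=entry.score,
                intra_pairs1=tuple(intra1),
                intra_pairs2=tuple(intra2),
                inter_pairs=tuple(inter),
                structure=entry.structure,
            )
        )
    return results


# ---------------------------------------------------------------------------
# accessibility-based prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccessibilityPenalties:
    """Opening penalties dE[i..j] = -RT * log(Pr_ss(i,j)), all >= 0."""

    n: int
    entries: dict[tuple[int, int], float]

    def value(self, i: int, j: int) -> float:
        return self.entries[(i, j)]


def accessibility_penalties(
    seq: RnaSequence | str,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
    model: EnergyModel | None = None,
) -> AccessibilityPenalties:
    """dE for every subsequence of one molecule folded in isolation."""
    if isinstance(seq, str):
        seq = RnaSequence.from_raw(seq)
    cfg = cfg or FoldConfig()
    rule = rule or PairRule()
    model = model or EnergyModel()
    pm = partition_matrices(seq, cfg, rule, model)
    stats = basepair_probabilities(seq, cfg, rule, model, matrices=pm)
    entries: dict[tuple[int, int], float] = {}
    for i in range(1, seq.n + 1):
        for j in range(i, seq.n + 1):
            pr = unpaired_probability(
                seq, i, j, cfg, rule, model, matrices=pm, stats=stats
            )
            if pr <= 0.0:
                raise ArithmeticError(
                    f"Pr_ss({i},{j}) = {pr}; the empty structure always "
                    "contributes, so this indicates a numeric fault"
                )
            # clamp tiny negative penalties from roundoff of Pr_ss ~ 1
            entries[(i, j)] = max(0.0, -model.rt * math.log(pr))
    return AccessibilityPenalties(n=seq.n, entries=entries)


DuplexKey = tuple[int, int, int, int]  # (i, k, j, l): S1 i..k, S2rev j..l


@dataclass(frozen=True)
class InterTables:
    """Sparse duplex-energy table D (and optionally I) keyed (i,k,j,l)."""

    d: dict[DuplexKey, float]
    back: dict[DuplexKey, tuple[int, int] | None]

    def min_energy(self) -> float:
        return min(self.d.values()) if self.d else math.inf


def duplex_matrix(
    pair: DuplexPair,
    rule: PairRule | None = None,
    model: EnergyModel | None = None,
    max_gap: int | None = 15,
) -> InterTables:
    """Duplex energies for every boundary combination.

    D over (i..k | j..l) assumes the boundaries pair intermolecularly:
    the base case i=k, j=l contributes one pair (e_bp); extension adds a
    pair (i,j) in front of an interaction starting at (p,q) with
    i < p <= k, j < q <= l and p-i, q-j bounded by *max_gap*.  Entries
    are stored sparsely; inadmissible boundaries are simply absent
    (conceptually +inf).
    """
    rule = rule or PairRule()
    model = model or EnergyModel()
    s1, s2r = pair.seq1, pair.seq2_reversed
    n, m = pair.n, pair.m
    if n == 0 or m == 0:
        raise ValueError("both sequences must be non-empty")
    e_bp = model.e_bp
    d: dict[DuplexKey, float] = {}
    back: dict[DuplexKey, tuple[int, int] | None] = {}
    pairable = [
        (i, j)
        for i in range(1, n + 1)
        for j in range(1, m + 1)
        if rule.complementary(s1.base(i), s2r.base(j))
    ]
    # fill right-to-left so extensions look up already-computed entries
    for i, j in sorted(pairable, reverse=True):
        for k in range(i, n + 1):
            for l in range(j, m + 1):
                if k == i and l == j:
                    d[(i, k, j, l)] = e_bp
                    back[(i, k, j, l)] = None
                    continue
                if k == i or l == j:
                    continue
                best, best_ext = math.inf, None
                p_hi = min(k, i + max_gap) if max_gap is not None else k
                q_hi = min(l, j + max_gap) if max_gap is not None else l
                for p in range(i + 1, p_hi + 1):
                    for q in range(j + 1, q_hi + 1):
                        sub = d.get((p, k, q, l))
                        if sub is not None and e_bp + sub < best:
                            best, best_ext = e_bp + sub, (p, q)
                if best_ext is not None:
                    d[(i, k, j, l)] = best
                    back[(i, k, j, l)] = best_ext
    return InterTables(d=d, back=back)


def _traceback_duplex(tables: InterTables, key: DuplexKey) -> list[tuple[int, int]]:
    """Recover the intermolecular pairs of a duplex entry (reversed coords)."""
    i, k, j, l = key
    pairs = [(i, j)]
    while tables.back[(i, k, j, l)] is not None:
        i, j = tables.back[(i, k, j, l)]
        pairs.append((i, j))
    return pairs


def interaction_predict(
    pair: DuplexPair,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
    model: EnergyModel | None = None,
    all_favorable: bool = False,
    tol: float = 1e-9,
) -> list[InteractionResult]:
    """Accessibility-based prediction: I = D + dE1 + dE2 over all sites.

    Returns all minimal-energy interactions (or, with *all_favorable*,
    every interaction with I < 0), ordered by (site1 start, site2 start).
    dE2 is computed on the reversed view of S2; results are reported in
    original coordinates.
    """
    cfg = cfg or FoldConfig()
    rule = rule or PairRule()
    model = model or EnergyModel()
    tables = duplex_matrix(pair, rule, model, cfg.max_gap)
    if not tables.d:
        return []
    de1 = accessibility_penalties(pair.seq1, cfg, rule, model)
    de2 = accessibility_penalties(pair.seq2_reversed, cfg, rule, model)

    scored: list[tuple[float, DuplexKey]] = []
    for (i, k, j, l), dval in tables.d.items():
        scored.append((dval + de1.value(i, k) + de2.value(j, l), (i, k, j, l)))
    best = min(e for e, _ in scored)

    keep = [
        (e, key)
        for e, key in scored
        if (e < 0 if all_favorable else abs(e - best) <= tol)
    ]
    results = []
    for energy, key in keep:
        i, k, j, l = key
        pairs_rev = _traceback_duplex(tables, key)
        inter = tuple(sorted((a, pair.to_original2(b)) for a, b in pairs_rev))
        results.append(
            InteractionResult(
                site1=(i, k),
                site2=(pair.to_original2(l), pair.to_original2(j)),
                inter_pairs=inter,
                energy=energy,
                duplex_energy=tables.d[key],
                delta_e1=de1.value(i, k),
                delta_e2=de2.value(j, l),
            )
        )
    results.sort(key=lambda r: (r.site1[0], r.site2[0], r.energy))
    return results


def render_duplex_ascii(pair: DuplexPair, result: InteractionResult) -> str:
    """Three-line chart: S1 5'->3', pairing bars, S2 3'->5'."""
    i1, k1 = result.site1
    j2, l2 = result.site2
    seg1 = pair.seq1.residues[i1 - 1 : k1]
    seg2 = pair.seq2.residues[j2 - 1 : l2][::-1]  # shown 3'->5'
    width = max(len(seg1), len(seg2))
    bars = []
    paired1 = {a for a, _ in result.inter_pairs}
    paired2 = {b for _, b in result.inter_pairs}
    for offset in range(width):
        p1 = i1 + offset
        p2 = l2 - offset
        bars.append("|" if p1 in paired1 and p2 in paired2 else " ")
    return "\n".join(
        [
            f"5'-{seg1.ljust(width)}-3'  S1 {i1}..{k1}",
            f"   {''.join(bars)}",
            f"3'-{seg2.ljust(width)}-5'  S2 {j2}..{l2}",
        ]
    )
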