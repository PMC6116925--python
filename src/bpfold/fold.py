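"""Base-pair maximization (Nussinov) with optimal and suboptimal traceback.

Two recursion variants are provided.  The *unique* variant mirrors the
counting decomposition (case split on the pairing state of the last
position), so every structure corresponds to exactly one traceback:

    N[i,j] = max( N[i,j-1],
                  max_{i <= k < j-l, S_k~S_j} N[i,k-1] + N[k+1,j-1] + 1 )

The *ambiguous* variant uses the four-case textbook recursion (i unpaired;
j unpaired; pair (i,j); bipartition), which computes the same optimum but
considers the same structure through several recursion paths — visible as
duplicated entries during suboptimal enumeration.

Suboptimal enumeration follows the Wuchty scheme: partial tracebacks (a
list of unexpanded intervals, the pairs fixed so far, and the best total
still achievable) are kept on an explicit work stack and expanded only
while the achievable total stays within ``delta`` of the optimum.  The
same machinery drives maximum-expected-accuracy enumeration, which is why
case expansion is abstracted behind :class:`IntervalModel`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .model import (
    EnergyModel,
    FoldConfig,
    PairRule,
    RnaSequence,
    SecondaryStructure,
)

Cell = tuple[int, int]


@dataclass(frozen=True)
class ScoreMatrix:
    """Upper-triangular DP table; empty intervals score 0."""

    n: int
    entries: dict[Cell, float]
    variant: str = "unique"

    def value(self, i: int, j: int) -> float:
        if j < i:
            return 0
        return self.entries[(i, j)]

    @property
    def optimum(self) -> float:
        return self.value(1, self.n)


@dataclass(frozen=True)
class TracebackEntry:
    """One traceback result: structure, its score, and the case path."""

    structure: SecondaryStructure
    score: float
    trace: tuple[tuple[Cell, str], ...] = ()


@dataclass(frozen=True)
class Case:
    """One recursion case at a cell: sub-intervals it opens, pairs and
    score bonus it contributes, and a label naming the case."""

    label: str
    bonus: float
    intervals: tuple[Cell, ...]
    pairs: tuple[tuple[int, int], ...] = ()


class IntervalModel:
    """Interface the generic traceback machinery works against.

    ``value(i, j)`` is the filled DP entry (0 on empty intervals) and
    ``cases(i, j)`` yields every recursion case for cell (i, j) in the
    printed order of the recursion, so that
    ``value(i,j) = max over cases of bonus + sum(value over intervals)``.
    """

    def value(self, i: int, j: int) -> float:
        raise NotImplementedError

    def cases(self, i: int, j: int) -> Iterable[Case]:
        raise NotImplementedError


def _fill(seq: RnaSequence, cfg: FoldConfig, rule: PairRule, model: "IntervalModel") -> dict[Cell, float]:
    entries: dict[Cell, float] = {}

    def get(i: int, j: int) -> float:
        return 0 if j < i else entries[(i, j)]

    for span in range(0, seq.n):
        for i in range(1, seq.n - span + 1):
            j = i + span
            best = None
            for case in model.cases(i, j):
                val = case.bonus + sum(get(a, b) for a, b in case.intervals)
                if best is None or val > best:
                    best = val
            entries[(i, j)] = 0 if best is None else best
    return entries


class NussinovUnique(IntervalModel):
    """Unique last-position decomposition, +1 per pair."""

    variant = "unique"

    def __init__(self, seq: RnaSequence, cfg: FoldConfig, rule: PairRule):
        self.seq, self.cfg, self.rule = seq, cfg, rule
        self.entries = _fill(seq, cfg, rule, self)

    def value(self, i: int, j: int) -> float:
        return 0 if j < i else self.entries[(i, j)]

    def cases(self, i: int, j: int) -> Iterator[Case]:
        if j <= i:
            if j == i:
                yield Case("unpaired", 0, ())
            return
        yield Case("unpaired", 0, ((i, j - 1),))
        for k in range(i, j - self.cfg.min_loop):
            if self.cfg.admissible(self.seq, k, j, self.rule):
                yield Case(f"pair({k},{j})", 1, ((i, k - 1), (k + 1, j - 1)), ((k, j),))


class NussinovAmbiguous(IntervalModel):
    """Four-case textbook recursion; same optimum, non-unique decomposition."""

    variant = "ambiguous"

    def __init__(self, seq: RnaSequence, cfg: FoldConfig, rule: PairRule):
        self.seq, self.cfg, self.rule = seq, cfg, rule
        self.entries = _fill(seq, cfg, rule, self)

    def value(self, i: int, j: int) -> float:
        return 0 if j < i else self.entries[(i, j)]

    def cases(self, i: int, j: int) -> Iterator[Case]:
        if j <= i:
            if j == i:
                yield Case("unpaired", 0, ())
            return
        yield Case("i-unpaired", 0, ((i + 1, j),))
        yield Case("j-unpaired", 0, ((i, j - 1),))
        if self.cfg.admissible(self.seq, i, j, self.rule):
            yield Case(f"pair({i},{j})", 1, ((i + 1, j - 1),), ((i, j),))
        for k in range(i + 1, j - 1):
            yield Case(f"split@{k}", 0, ((i, k), (k + 1, j)))


def _matrix_from_model(model: IntervalModel, n: int) -> ScoreMatrix:
    return ScoreMatrix(n=n, entries=dict(model.entries), variant=model.variant)


def _coerce(seq: RnaSequence | str) -> RnaSequence:
    return RnaSequence.from_raw(seq) if isinstance(seq, str) else seq


def build_model(
    seq: RnaSequence | str,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
) -> IntervalModel:
    """Construct the filled DP model for ``cfg.variant``."""
    seq = _coerce(seq)
    cfg = cfg or FoldConfig()
    rule = rule or PairRule()
    cls = NussinovUnique if cfg.variant == "unique" else NussinovAmbiguous
    return cls(seq, cfg, rule)


def nussinov_matrix(
    seq: RnaSequence | str,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
) -> ScoreMatrix:
    """Maximal-pair-count table under the unique decomposition."""
    seq = _coerce(seq)
    cfg = cfg or FoldConfig()
    return _matrix_from_model(NussinovUnique(seq, cfg, rule or PairRule()), seq.n)


def nussinov_matrix_ambiguous(
    seq: RnaSequence | str,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
) -> ScoreMatrix:
    """Maximal-pair-count table under the ambiguous four-case recursion."""
    seq = _coerce(seq)
    cfg = cfg or FoldConfig()
    return _matrix_from_model(NussinovAmbiguous(seq, cfg, rule or PairRule()), seq.n)


# ---------------------------------------------------------------------------
# traceback
# ---------------------------------------------------------------------------

_FLOAT_TOL = 1e-9


@dataclass
class _Partial:
    intervals: tuple[Cell, ...]
    pairs: tuple[tuple[int, int], ...]
    bonus: float
    potential: float
    trace: tuple[tuple[Cell, str], ...] = ()


def enumerate_tracebacks(
    model: IntervalModel,
    n: int,
    delta: float = 0.0,
    tol: float = _FLOAT_TOL,
    max_results: int | None = None,
) -> list[TracebackEntry]:
    """All tracebacks scoring within *delta* of the optimum, best first.

    With a unique-decomposition model each structure appears exactly once;
    ambiguous models may emit the same structure repeatedly (one entry per
    recursion path).  Comparison of real-valued scores uses the absolute
    tolerance *tol*.
    """
    best = model.value(1, n)
    floor = best - delta - tol
    results: list[TracebackEntry] = []
    start = _Partial(
        intervals=((1, n),) if n >= 1 else (),
        pairs=(), bonus=0.0, potential=best,
    )
    stack = [start]
    while stack:
        st = stack.pop()
        while st.intervals and st.intervals[0][1] < st.intervals[0][0]:
            st = _Partial(st.intervals[1:], st.pairs, st.bonus, st.potential, st.trace)
        if not st.intervals:
            results.append(
                TracebackEntry(
                    SecondaryStructure(frozenset(st.pairs)), st.bonus, st.trace
                )
            )
            if max_results is not None and len(results) >= max_results:
                break
            continue
        (i, j), rest = st.intervals[0], st.intervals[1:]
        # expand in reverse printed order so the stack pops cases in order
        expansions = []
        for case in model.cases(i, j):
            sub = tuple(c for c in case.intervals if c[1] >= c[0])
            new_pot = (
                st.potential
                - model.value(i, j)
                + case.bonus
                + sum(model.value(a, b) for a, b in sub)
            )
            if new_pot < floor:
                continue
            expansions.append(
                _Partial(
                    sub + rest,
                    st.pairs + case.pairs,
                    st.bonus + case.bonus,
                    new_pot,
                    st.trace + (((i, j), case.label),),
                )
            )
        stack.extend(reversed(expansions))
    results.sort(key=lambda e: (-e.score, sorted(e.structure.pairs)))
    return results


def traceback_optimal(
    seq: RnaSequence | str,
    matrix: ScoreMatrix | None = None,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
) -> TracebackEntry:
    """One optimal structure, deterministic: cases are tried in the
    printed order of the active recursion, smallest pairing partner first.
    """
    seq = _coerce(seq)
    cfg = cfg or FoldConfig()
    rule = rule or PairRule()
    model = build_model(seq, cfg, rule)
    if matrix is not None and matrix.entries != model.entries:
        raise ValueError("matrix does not match the sequence/config variant")

    pairs: list[tuple[int, int]] = []
    trace: list[tuple[Cell, str]] = []
    work: list[Cell] = [(1, seq.n)] if seq.n >= 1 else []
    while work:
        i, j = work.pop()
        if j < i:
            continue
        target = model.value(i, j)
        for case in model.cases(i, j):
            val = case.bonus + sum(model.value(a, b) for a, b in case.intervals)
            if abs(val - target) <= _FLOAT_TOL:
                pairs.extend(case.pairs)
                trace.append(((i, j), case.label))
                work.extend(reversed(case.intervals))
                break
        else:
            raise RuntimeError(f"no recursion case reproduces cell ({i},{j})")
    return TracebackEntry(
        SecondaryStructure(frozenset(pairs)), model.value(1, seq.n), tuple(trace)
    )


def enumerate_suboptimal(
    seq: RnaSequence | str,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
    delta: float | None = None,
    max_results: int | None = None,
) -> list[TracebackEntry]:
    """Wuchty-style enumeration of all structures within *delta* pairs of
    the maximum, ordered by score descending."""
    seq = _coerce(seq)
    cfg = cfg or FoldConfig()
    model = build_model(seq, cfg, rule)
    d = cfg.subopt_delta if delta is None else delta
    return enumerate_tracebacks(model, seq.n, delta=d, max_results=max_results)


def mfe(
    seq: RnaSequence | str,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
    model: EnergyModel | None = None,
) -> float:
    """Minimum energy over the structure space: N[1,n] * e_bp for e_bp < 0."""
    seq = _coerce(seq)
    energy = model or EnergyModel()
    return nussinov_matrix(seq, cfg, rule).optimum * energy.e_bp
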