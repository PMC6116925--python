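"""Maximum expected accuracy (MEA) folding.

The expected accuracy of a structure P maps ensemble features onto a
single structure:

    acc(P) = sum_{(i,j) in P} 2 * gamma * Pr_bp(i,j)
           + sum_{k unpaired in P} Pr_u(k)

Pairs count twice (they cover two positions) and gamma trades pair
against unpaired probability mass.  The maximizing structure is found
with the unique Nussinov decomposition over real-valued scores:

    M[i,j] = max( M[i,j-1] + Pr_u(j),
                  max_{i <= k < j-l, S_k~S_j} M[i,k-1] + M[k+1,j-1]
                                              + 2*gamma*Pr_bp(k,j) )

and (sub)optimal MEA structures come from the shared work-stack traceback
with an absolute 1e-9 comparator for the floating-point scores.
"""

from __future__ import annotations

from typing import Iterator

from .ensemble import EnsembleStats, basepair_probabilities
from .fold import Case, IntervalModel, ScoreMatrix, TracebackEntry, _fill, enumerate_tracebacks
from .model import EnergyModel, FoldConfig, PairRule, RnaSequence, SecondaryStructure


def accuracy(
    structure: SecondaryStructure,
    stats: EnsembleStats,
    gamma: float = 1.0,
) -> float:
    """Expected accuracy of *structure* against ensemble *stats*."""
    total = 0.0
    for i, j in structure.pairs:
        if (i, j) not in stats.pr_bp:
            raise ValueError(
                f"pair ({i},{j}) not admissible for the ensemble these "
                "statistics were computed from"
            )
        total += 2.0 * gamma * stats.bp(i, j)
    for k in structure.unpaired_positions(stats.n):
        total += stats.u(k)
    return total


class MeaModel(IntervalModel):
    """Unique-decomposition DP over expected-accuracy scores."""

    variant = "unique"

    def __init__(self, seq: RnaSequence, cfg: FoldConfig, rule: PairRule, stats: EnsembleStats):
        self.seq, self.cfg, self.rule, self.stats = seq, cfg, rule, stats
        self.entries = _fill(seq, cfg, rule, self)

    def value(self, i: int, j: int) -> float:
        return 0.0 if j < i else self.entries[(i, j)]

    def cases(self, i: int, j: int) -> Iterator[Case]:
        if j < i:
            return
        if j == i:
            yield Case("unpaired", self.stats.u(j), ())
            return
        yield Case("unpaired", self.stats.u(j), ((i, j - 1),))
        for k in range(i, j - self.cfg.min_loop):
            if self.cfg.admissible(self.seq, k, j, self.rule):
                yield Case(
                    f"pair({k},{j})",
                    2.0 * self.cfg.gamma * self.stats.bp(k, j),
                    ((i, k - 1), (k + 1, j - 1)),
                    ((k, j),),
                )


def _coerce(seq: RnaSequence | str) -> RnaSequence:
    return RnaSequence.from_raw(seq) if isinstance(seq, str) else seq


def mea_matrix(
    seq: RnaSequence | str,
    stats: EnsembleStats | None = None,
    gamma: float | None = None,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
    model: EnergyModel | None = None,
) -> ScoreMatrix:
    """Fill the expected-accuracy table M."""
    seq = _coerce(seq)
    cfg = cfg or FoldConfig()
    if gamma is not None:
        cfg = FoldConfig(**{**cfg.__dict__, "gamma": gamma})
    rule = rule or PairRule()
    stats = stats or basepair_probabilities(seq, cfg, rule, model)
    m = MeaModel(seq, cfg, rule, stats)
    return ScoreMatrix(n=seq.n, entries=dict(m.entries), variant="mea")


def mea_structure(
    seq: RnaSequence | str,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
    model: EnergyModel | None = None,
    gamma: float | None = None,
    delta: float = 0.0,
    max_results: int | None = None,
) -> list[TracebackEntry]:
    """Optimal and suboptimal MEA structures, scores are acc values."""
    seq = _coerce(seq)
    cfg = cfg or FoldConfig()
    if gamma is not None:
        cfg = FoldConfig(**{**cfg.__dict__, "gamma": gamma})
    rule = rule or PairRule()
    stats = basepair_probabilities(seq, cfg, rule, model)
    m = MeaModel(seq, cfg, rule, stats)
    return enumerate_tracebacks(m, seq.n, delta=delta, max_results=max_results)
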