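"""Partition function and ensemble probabilities for the base-pair model.

Structures P are Boltzmann-distributed, Pr(P) = exp(-E(P)/RT) / Z, and
because E(P) = |P| * e_bp the weight of a structure is a product of
per-pair weights q_bp = exp(-e_bp/RT).  The partition function therefore
follows the counting recursion with the pair case weighted by q_bp:

    Q[i,j]   = Q[i,j-1] + sum_{i <= k < j-l} Q[i,k-1] * Qbp[k,j]
    Qbp[i,j] = Q[i+1,j-1] * q_bp   if (i,j) admissible, else 0

Base-pair probabilities are recovered outside-in: a pair (i,j) is either
external (not enclosed by any pair) or directly enclosed by some pair
(p,q), giving

    Pr_bp(i,j) = Q[1,i-1] * Qbp[i,j] * Q[j+1,n] / Z
               + sum_{p<i, j<q} Pr_bp(p,q) * q_bp
                   * Q[p+1,i-1] * Qbp[i,j] * Q[j+1,q-1] / Qbp[p,q]

evaluated in order of decreasing span so enclosing probabilities are
final.  Unpaired-region probabilities Pr_ss(i,j) use the same scheme with
Qbp[i,j] replaced by 1 (the only admissible content of an unpaired region
is the empty structure, weight 1).  All arithmetic is plain double
precision behind a sequence-length guard; overflow is refused rather than
rescaled, which keeps the recursions exactly as written.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
    EnergyModel,
    FoldConfig,
    NumericGuardError,
    PairRule,
    RnaSequence,
    SecondaryStructure,
    boltzmann_weight,
)

_REL_TOL = 1e-12


@dataclass(frozen=True)
class PartitionMatrices:
    """Q / Qbp tables and the partition function Z = Q[1,n]."""

    n: int
    q: dict[tuple[int, int], float]
    qbp: dict[tuple[int, int], float]

    def q_value(self, i: int, j: int) -> float:
        """Q over [i,j]; 1 on empty intervals (only the empty structure)."""
        if j < i:
            return 1.0
        return self.q[(i, j)]

    def qbp_value(self, i: int, j: int) -> float:
        return self.qbp.get((i, j), 0.0)

    @property
    def z(self) -> float:
        return self.q_value(1, self.n)


@dataclass(frozen=True)
class EnsembleStats:
    """Z plus the base-pair probability table and unpaired vector."""

    n: int
    z: float
    pr_bp: dict[tuple[int, int], float]
    pr_u: dict[int, float]

    def bp(self, i: int, j: int) -> float:
        return self.pr_bp.get((i, j), 0.0)

    def u(self, k: int) -> float:
        return self.pr_u[k]


def _coerce(seq: RnaSequence | str) -> RnaSequence:
    return RnaSequence.from_raw(seq) if isinstance(seq, str) else seq


def partition_matrices(
    seq: RnaSequence | str,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
    model: EnergyModel | None = None,
) -> PartitionMatrices:
    """Fill Q and Qbp; cross-checks the single-table recursion
    (pair case weighted directly by q_bp) against the Q/Qbp split."""
    seq = _coerce(seq)
    cfg = cfg or FoldConfig()
    rule = rule or PairRule()
    model = model or EnergyModel()
    n = seq.n
    if n > cfg.partition_guard:
        raise NumericGuardError(
            f"length {n} exceeds partition guard {cfg.partition_guard}; "
            "double-precision weights may overflow"
        )
    qbp_w = model.q_bp
    q: dict[tuple[int, int], float] = {}
    qbp: dict[tuple[int, int], float] = {}
    direct: dict[tuple[int, int], float] = {}

    def qv(i: int, j: int) -> float:
        return 1.0 if j < i else q[(i, j)]

    def dv(i: int, j: int) -> float:
        return 1.0 if j < i else direct[(i, j)]

    for span in range(0, n):
        for i in range(1, n - span + 1):
            j = i + span
            if cfg.admissible(seq, i, j, rule):
                qbp[(i, j)] = qv(i + 1, j - 1) * qbp_w
            total = qv(i, j - 1)
            d_total = dv(i, j - 1)
            for k in range(i, j - cfg.min_loop):
                if (k, j) in qbp:
                    total += qv(i, k - 1) * qbp[(k, j)]
                if cfg.admissible(seq, k, j, rule):
                    d_total += dv(i, k - 1) * dv(k + 1, j - 1) * qbp_w
            q[(i, j)] = total
            direct[(i, j)] = d_total

    z, z_direct = qv(1, n), dv(1, n)
    if abs(z - z_direct) > _REL_TOL * max(abs(z), 1.0):
        raise AssertionError(
            f"partition recursions disagree: split {z} vs direct {z_direct}"
        )
    return PartitionMatrices(n=n, q=q, qbp=qbp)


def structure_probability(
    structure: SecondaryStructure,
    seq: RnaSequence | str,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
    model: EnergyModel | None = None,
) -> float:
    """Boltzmann probability of one structure within the ensemble."""
    model = model or EnergyModel()
    z = partition_matrices(seq, cfg, rule, model).z
    return boltzmann_weight(structure, model) / z


def _enclosing_terms(
    pm: PartitionMatrices,
    pr_bp: dict[tuple[int, int], float],
    q_bp: float,
    i: int,
    j: int,
) -> float:
    """Sum over admissible directly-enclosing pairs (p,q), p<i, j<q, of
    Pr_bp(p,q) * q_bp * Q[p+1,i-1] * Q[j+1,q-1] / Qbp[p,q]."""
    total = 0.0
    for p in range(1, i):
        for q in range(j + 1, pm.n + 1):
            w = pm.qbp_value(p, q)
            if w > 0.0:
                total += (
                    pr_bp.get((p, q), 0.0)
                    * q_bp
                    * pm.q_value(p + 1, i - 1)
                    * pm.q_value(j + 1, q - 1)
                    / w
                )
    return total


def basepair_probabilities(
    seq: RnaSequence | str,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
    model: EnergyModel | None = None,
    matrices: PartitionMatrices | None = None,
) -> EnsembleStats:
    """Pr_bp for every admissible pair (outside-in) and Pr_u per position.

    Pr_u(k) = 1 - sum_{i<k} Pr_bp(i,k) - sum_{k<j} Pr_bp(k,j).
    """
    seq = _coerce(seq)
    cfg = cfg or FoldConfig()
    rule = rule or PairRule()
    model = model or EnergyModel()
    pm = matrices or partition_matrices(seq, cfg, rule, model)
    n, z, q_bp = pm.n, pm.z, model.q_bp

    pr_bp: dict[tuple[int, int], float] = {}
    cells = sorted(pm.qbp, key=lambda ij: ij[1] - ij[0], reverse=True)
    for i, j in cells:
        external = pm.q_value(1, i - 1) * pm.qbp_value(i, j) * pm.q_value(j + 1, n) / z
        enclosed = pm.qbp_value(i, j) * _enclosing_terms(pm, pr_bp, q_bp, i, j)
        pr_bp[(i, j)] = external + enclosed

    pr_u: dict[int, float] = {}
    for k in range(1, n + 1):
        pr_u[k] = 1.0 - sum(
            p for (a, b), p in pr_bp.items() if a == k or b == k
        )
    return EnsembleStats(n=n, z=z, pr_bp=pr_bp, pr_u=pr_u)


def unpaired_probability(
    seq: RnaSequence | str,
    i: int,
    j: int,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
    model: EnergyModel | None = None,
    matrices: PartitionMatrices | None = None,
    stats: EnsembleStats | None = None,
) -> float:
    """Pr_ss(i,j): probability that no pair end lies inside [i,j].

    Pairs spanning the region entirely from outside remain allowed; the
    computation substitutes 1 for Qbp[i,j] in the pair-probability scheme.
    """
    seq = _coerce(seq)
    cfg = cfg or FoldConfig()
    rule = rule or PairRule()
    model = model or EnergyModel()
    if not 1 <= i <= j <= seq.n:
        raise ValueError(f"region [{i},{j}] outside 1..{seq.n}")
    pm = matrices or partition_matrices(seq, cfg, rule, model)
    st = stats or basepair_probabilities(seq, cfg, rule, model, matrices=pm)
    external = pm.q_value(1, i - 1) * pm.q_value(j + 1, pm.n) / pm.z
    return external + _enclosing_terms(pm, st.pr_bp, model.q_bp, i, j)


@dataclass(frozen=True)
class DotPlot:
    """Sparse dot-plot: (i, j, Pr_bp) records plus per-position Pr_u."""

    n: int
    records: tuple[tuple[int, int, float], ...]
    unpaired: tuple[float, ...]

    def to_rows(self) -> list[dict]:
        return [{"i": i, "j": j, "probability": p} for i, j, p in self.records]


def dotplot(stats: EnsembleStats, threshold: float = 1e-6) -> DotPlot:
    """Keep base-pair records above *threshold* (tiny dots are invisible
    in the graphical convention this mirrors)."""
    records = tuple(
        (i, j, p)
        for (i, j), p in sorted(stats.pr_bp.items())
        if p > threshold
    )
    unpaired = tuple(stats.u(k) for k in range(1, stats.n + 1))
    return DotPlot(n=stats.n, records=records, unpaired=unpaired)
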