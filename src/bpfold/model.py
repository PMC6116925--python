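"""Core domain model for nested RNA secondary structures.

The model here is deliberately minimal: a secondary structure is a set of
nested base pairs, every pair contributes the same energy ``E_bp`` and the
energy of a structure is ``|P| * E_bp``.  This strips the Nearest Neighbor
loop decomposition away so that the dynamic-programming recursions built on
top (counting, base-pair maximization, partition function, expected
accuracy, interaction prediction) expose their algorithmic skeleton.

All user-facing coordinates are 1-based and intervals are inclusive, which
matches dot-bracket conventions and the standard presentation of these
recursions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator

RNA_ALPHABET = frozenset("ACGU")
LINKER_CHAR = "X"

#: minimum number of unpaired positions a hairpin loop must enclose
DEFAULT_MIN_LOOP = 3


class RnaError(ValueError):
    """Malformed sequence or structure input."""


class OracleGuardError(RuntimeError):
    """Exhaustive enumeration requested for a sequence beyond the guard."""


class NumericGuardError(RuntimeError):
    """Partition-function arithmetic requested beyond the overflow guard."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A,C,G,U}, positions indexed 1..n.

    ``concatenated=True`` additionally admits the linker character ``X``
    used by cofold-style prediction; ``X`` can never pair.
    """

    residues: str
    concatenated: bool = False

    def __post_init__(self) -> None:
        allowed = RNA_ALPHABET | ({LINKER_CHAR} if self.concatenated else set())
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise RnaError(
                    f"illegal residue {ch!r} at position {pos}; "
                    f"allowed: {''.join(sorted(allowed))}"
                )

    @classmethod
    def from_raw(cls, raw: str, concatenated: bool = False) -> "RnaSequence":
        """Normalize free-form input: uppercase, DNA T mapped to U."""
        return cls(raw.strip().upper().replace("T", "U"), concatenated=concatenated)

    @property
    def n(self) -> int:
        return len(self.residues)

    def base(self, i: int) -> str:
        """Residue at 1-based position *i*."""
        if not 1 <= i <= self.n:
            raise IndexError(f"position {i} outside 1..{self.n}")
        return self.residues[i - 1]

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n

    def __str__(self) -> str:
        return self.residues


_WC = frozenset({frozenset("AU"), frozenset("CG")})
_WC_GU = _WC | {frozenset("GU")}


@dataclass(frozen=True)
class PairRule:
    """Which unordered base-letter pairs may form a base pair.

    Modes: ``wc-gu`` (Watson-Crick plus G-U wobble, the default), ``wc``
    (Watson-Crick only) and ``any`` (every letter pair, the
    sequence-agnostic structure space used for growth-rate estimates).
    The linker character ``X`` never pairs in any mode.
    """

    mode: str = "wc-gu"

    def __post_init__(self) -> None:
        if self.mode not in ("wc-gu", "wc", "any"):
            raise RnaError(f"unknown pair rule mode {self.mode!r}")

    @property
    def allowed_pairs(self) -> frozenset[frozenset[str]]:
        if self.mode == "wc":
            return _WC
        if self.mode == "wc-gu":
            return _WC_GU
        return frozenset(
            frozenset((a, b)) for a in RNA_ALPHABET for b in RNA_ALPHABET
        )

    def complementary(self, a: str, b: str) -> bool:
        if LINKER_CHAR in (a, b):
            return False
        if self.mode == "any":
            return a in RNA_ALPHABET and b in RNA_ALPHABET
        return frozenset((a, b)) in self.allowed_pairs


def is_complementary(a: str, b: str, rule: PairRule | None = None) -> bool:
    """True iff letters *a*, *b* may pair under *rule* (default wc-gu)."""
    return (rule or PairRule()).complementary(a, b)


@dataclass(frozen=True)
class EnergyModel:
    """Base-pair energy model: every pair contributes ``e_bp``.

    ``rt`` is the product of the Boltzmann (or gas) constant and the
    temperature; both quantities are kept dimensionless with defaults
    ``e_bp = -1`` and ``rt = 1`` since the model fixes no unit system.
    """

    e_bp: float = -1.0
    rt: float = 1.0

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise RnaError("RT must be positive")

    @property
    def q_bp(self) -> float:
        """Boltzmann weight of a single base pair, exp(-e_bp / rt)."""
        return math.exp(-self.e_bp / self.rt)


@dataclass(frozen=True)
class FoldConfig:
    """Shared algorithm parameters.

    min_loop
        minimal loop length *l*: pair (i,j) admissible iff j - i > l,
        i.e. at least *l* positions are enclosed.
    variant
        recursion flavour for traceback/enumeration: "unique" or
        "ambiguous".
    subopt_delta
        score band for suboptimal enumeration (absolute, >= 0).
    gamma
        weight of base-pair versus unpaired probabilities in expected
        accuracy.
    max_gap
        largest allowed distance between consecutive intermolecular
        pairs on either molecule in site-based interaction prediction;
        ``None`` means unbounded.
    linker_length
        cofold linker length; defaults to min_loop + 1 so the joined
        sequence ends may pair.
    oracle_limit
        length guard for exhaustive enumeration (structure space grows
        roughly as 2.3^n).
    partition_guard
        length guard for double-precision partition arithmetic.
    """

    min_loop: int = DEFAULT_MIN_LOOP
    variant: str = "unique"
    subopt_delta: float = 0.0
    gamma: float = 1.0
    max_gap: int | None = 15
    linker_length: int | None = None
    oracle_limit: int = 25
    partition_guard: int = 150

    def __post_init__(self) -> None:
        if self.min_loop < 0:
            raise RnaError("min_loop must be non-negative")
        if self.variant not in ("unique", "ambiguous"):
            raise RnaError(f"unknown recursion variant {self.variant!r}")
        if self.subopt_delta < 0:
            raise RnaError("subopt_delta must be non-negative")
        if self.gamma < 0:
            raise RnaError("gamma must be non-negative")
        if self.max_gap is not None and self.max_gap < 1:
            raise RnaError("max_gap must be positive or None")
        if self.linker_length is not None and self.linker_length < 1:
            raise RnaError("linker_length must be positive")

    @property
    def effective_linker_length(self) -> int:
        return self.linker_length if self.linker_length is not None else self.min_loop + 1

    def admissible(self, seq: RnaSequence, i: int, j: int, rule: PairRule) -> bool:
        """Pair (i,j) allowed: complementary and j - i > min_loop."""
        return j - i > self.min_loop and rule.complementary(seq.base(i), seq.base(j))


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure: a set of ordered base pairs (i, j), i < j."""

    pairs: frozenset[tuple[int, int]] = frozenset()

    @classmethod
    def from_pairs(cls, pairs) -> "SecondaryStructure":
        return cls(frozenset((int(i), int(j)) for i, j in pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)

    def paired_positions(self) -> frozenset[int]:
        return frozenset(itertools.chain.from_iterable(self.pairs))

    def unpaired_positions(self, n: int) -> list[int]:
        paired = self.paired_positions()
        return [k for k in range(1, n + 1) if k not in paired]


EMPTY_STRUCTURE = SecondaryStructure()


def validate_structure(
    seq: RnaSequence,
    structure: SecondaryStructure,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
) -> list[str]:
    """Check all structural invariants; return human-readable violations.

    Checked: i < j and indices in range (raised as :class:`RnaError`,
    malformed input), each position in at most one pair, no two pairs
    crossing, complementarity under *rule*, and the minimal loop length.
    """
    cfg = cfg or FoldConfig()
    rule = rule or PairRule()
    pairs = structure.sorted_pairs()
    for i, j in pairs:
        if not (1 <= i <= seq.n and 1 <= j <= seq.n):
            raise RnaError(f"pair ({i},{j}) outside sequence 1..{seq.n}")
        if i >= j:
            raise RnaError(f"pair ({i},{j}) not ordered i < j")

    violations: list[str] = []
    seen: dict[int, tuple[int, int]] = {}
    for i, j in pairs:
        for end in (i, j):
            if end in seen and seen[end] != (i, j):
                violations.append(
                    f"position {end} in two pairs: {seen[end]} and ({i},{j})"
                )
            seen[end] = (i, j)
        if not rule.complementary(seq.base(i), seq.base(j)):
            violations.append(
                f"pair ({i},{j}): {seq.base(i)}-{seq.base(j)} not complementary"
            )
        if j - i <= cfg.min_loop:
            violations.append(
                f"pair ({i},{j}): loop length {j - i - 1} below minimum {cfg.min_loop}"
            )
    for (i, j), (p, q) in itertools.combinations(pairs, 2):
        if i < p < j < q:
            violations.append(f"pairs ({i},{j}) and ({p},{q}) cross")
    return violations


def structure_energy(structure: SecondaryStructure, model: EnergyModel | None = None) -> float:
    """Energy of a structure: number of pairs times e_bp."""
    model = model or EnergyModel()
    return len(structure.pairs) * model.e_bp


def boltzmann_weight(structure: SecondaryStructure, model: EnergyModel | None = None) -> float:
    """exp(-E(P)/RT) = q_bp ** |P|."""
    model = model or EnergyModel()
    return model.q_bp ** len(structure.pairs)


# ---------------------------------------------------------------------------
# dot-bracket codec
# ---------------------------------------------------------------------------

def parse_dotbracket(s: str) -> SecondaryStructure:
    """Parse a plain dot-bracket string ('.', '(', ')') into a structure.

    Intermolecular brackets '[]' and linker 'X' are accepted too so that
    cofold output round-trips; both bracket families must balance.
    """
    pairs: set[tuple[int, int]] = set()
    stacks: dict[str, list[int]] = {"(": [], "[": []}
    closing = {")": "(", "]": "["}
    for pos, ch in enumerate(s, start=1):
        if ch in ".Xx":
            continue
        if ch in stacks:
            stacks[ch].append(pos)
        elif ch in closing:
            stack = stacks[closing[ch]]
            if not stack:
                raise RnaError(f"unbalanced {ch!r} at position {pos}")
            pairs.add((stack.pop(), pos))
        else:
            raise RnaError(f"illegal dot-bracket character {ch!r} at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise RnaError(f"unclosed {opener!r} at position {stack[-1]}")
    return SecondaryStructure(frozenset(pairs))


def render_dotbracket(structure: SecondaryStructure, n: int) -> str:
    """Render a structure over *n* positions as a dot-bracket string."""
    out = ["."] * n
    for i, j in structure.pairs:
        if not (1 <= i < j <= n):
            raise RnaError(f"pair ({i},{j}) outside 1..{n}")
        out[i - 1] = "("
        out[j - 1] = ")"
    return "".join(out)


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_structures(
    seq: RnaSequence,
    cfg: FoldConfig | None = None,
    rule: PairRule | None = None,
    force: bool = False,
) -> list[SecondaryStructure]:
    """Every valid nested structure of *seq*, each exactly once.

    Brute-force ground truth for the dynamic programs.  Uses the unique
    last-position decomposition (position j unpaired, or paired to some
    admissible k), so no structure is produced twice.  Guarded by
    ``cfg.oracle_limit`` since the structure space grows exponentially;
    pass ``force=True`` to override deliberately.
    """
    cfg = cfg or FoldConfig()
    rule = rule or PairRule()
    if seq.n > cfg.oracle_limit and not force:
        raise OracleGuardError(
            f"sequence length {seq.n} exceeds oracle guard {cfg.oracle_limit}"
        )

    cache: dict[tuple[int, int], list[frozenset[tuple[int, int]]]] = {}

    def rec(i: int, j: int) -> list[frozenset[tuple[int, int]]]:
        if j <= i:
            return [frozenset()]
        key = (i, j)
        if key in cache:
            return cache[key]
        out = list(rec(i, j - 1))
        for k in range(i, j - cfg.min_loop):
            if cfg.admissible(seq, k, j, rule):
                for left in rec(i, k - 1):
                    for inner in rec(k + 1, j - 1):
                        out.append(left | inner | {(k, j)})
        cache[key] = out
        return out

    return [SecondaryStructure(p) for p in rec(1, seq.n)]


def iter_admissible_pairs(
    seq: RnaSequence, cfg: FoldConfig, rule: PairRule
) -> Iterator[tuple[int, int]]:
    """All (i, j) with i < j admissible under complementarity and min loop."""
    for i in range(1, seq.n + 1):
        for j in range(i + cfg.min_loop + 1, seq.n + 1):
            if rule.complementary(seq.base(i), seq.base(j)):
                yield (i, j)
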