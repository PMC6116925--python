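"""Shared fixtures: seeded random sequences and exhaustive-oracle helpers.

The oracle helpers recompute every ensemble quantity by explicit
enumeration of the structure space, independently of the dynamic
programs they are used to check.
"""

from __future__ import annotations

import pytest

from bpfold import (
    EnergyModel,
    FoldConfig,
    FixtureSpec,
    PairRule,
    RnaSequence,
    boltzmann_weight,
    enumerate_structures,
    generate_fixtures,
)

#: study conditions for the randomized oracle suite: 50 sequences of
#: length 4..12 at balanced GC content, one fixed seed for the whole run
SUITE_SPEC = FixtureSpec(count=50, length_range=(4, 12), gc_bias=0.5, seed=20180830)

#: canonical hand-checkable inputs included alongside the random suite
CANONICAL = ("GAAAC", "GGGAAACCC")


@pytest.fixture(scope="session")
def default_cfg() -> FoldConfig:
    return FoldConfig()


@pytest.fixture(scope="session")
def default_rule() -> PairRule:
    return PairRule()


@pytest.fixture(scope="session")
def default_model() -> EnergyModel:
    return EnergyModel()


@pytest.fixture(scope="session")
def suite_sequences() -> list[RnaSequence]:
    return [RnaSequence(s) for s in CANONICAL] + generate_fixtures(SUITE_SPEC)


@pytest.fixture(scope="session")
def suite_ensembles(suite_sequences, default_cfg, default_rule):
    """Sequence -> exhaustively enumerated structure list (ground truth)."""
    return {
        seq.residues: enumerate_structures(seq, default_cfg, default_rule)
        for seq in suite_sequences
    }


def oracle_partition(structures, model: EnergyModel) -> float:
    return sum(boltzmann_weight(p, model) for p in structures)


def oracle_pair_probability(structures, i: int, j: int, model: EnergyModel) -> float:
    z = oracle_partition(structures, model)
    hit = sum(boltzmann_weight(p, model) for p in structures if (i, j) in p.pairs)
    return hit / z


def oracle_unpaired_probability(structures, i: int, j: int, model: EnergyModel) -> float:
    """Weight share of structures with no pair end inside [i, j]."""
    z = oracle_partition(structures, model)
    free = 0.0
    for p in structures:
        if all(not (i <= a <= j or i <= b <= j) for a, b in p.pairs):
            free += boltzmann_weight(p, model)
    return free / z
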