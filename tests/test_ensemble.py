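"""Partition function and ensemble probabilities against the oracle."""

import math

import pytest

from bpfold import (
    EnergyModel,
    FoldConfig,
    SecondaryStructure,
    basepair_probabilities,
    count_matrix,
    count_structures,
    dotplot,
    partition_matrices,
    structure_probability,
    unpaired_probability,
)
from bpfold.model import NumericGuardError, RnaSequence
from conftest import (
    oracle_pair_probability,
    oracle_partition,
    oracle_unpaired_probability,
)

E = math.e


def test_partition_closed_forms():
    assert partition_matrices("AAAA").z == pytest.approx(1.0)
    assert partition_matrices("GAAAC").z == pytest.approx(1 + E, rel=1e-12)


def test_structure_probability_closed_forms():
    empty = SecondaryStructure()
    paired = SecondaryStructure.from_pairs([(1, 5)])
    assert structure_probability(empty, "GAAAC") == pytest.approx(1 / (1 + E))
    assert structure_probability(paired, "GAAAC") == pytest.approx(E / (1 + E))


def test_mfe_structure_is_most_probable(suite_sequences, suite_ensembles, default_model):
    for seq in suite_sequences[:10]:
        structures = suite_ensembles[seq.residues]
        probs = {
            p: structure_probability(p, seq, model=default_model) for p in structures
        }
        max_pairs = max(len(p.pairs) for p in structures)
        best = max(probs.values())
        assert any(
            len(p.pairs) == max_pairs and probs[p] == pytest.approx(best)
            for p in structures
        )


def test_basepair_probability_closed_forms():
    stats = basepair_probabilities("GAAAC")
    assert stats.bp(1, 5) == pytest.approx(E / (1 + E), rel=1e-12)
    assert stats.u(3) == pytest.approx(1.0)


def test_partition_equals_weight_sum_across_suite(suite_sequences, suite_ensembles, default_model):
    for seq in suite_sequences:
        z = partition_matrices(seq, model=default_model).z
        oracle = oracle_partition(suite_ensembles[seq.residues], default_model)
        assert z == pytest.approx(oracle, rel=1e-9)


def test_probabilities_normalize(suite_sequences, suite_ensembles, default_model):
    for seq in suite_sequences[:15]:
        total = sum(
            structure_probability(p, seq, model=default_model)
            for p in suite_ensembles[seq.residues]
        )
        assert total == pytest.approx(1.0, abs=1e-9)


def test_pair_probabilities_match_oracle(suite_sequences, suite_ensembles, default_model, default_cfg, default_rule):
    for seq in suite_sequences:
        structures = suite_ensembles[seq.residues]
        stats = basepair_probabilities(seq, default_cfg, default_rule, default_model)
        for (i, j), p in stats.pr_bp.items():
            oracle = oracle_pair_probability(structures, i, j, default_model)
            assert p == pytest.approx(oracle, abs=1e-9)
            assert -1e-12 <= p <= 1 + 1e-12


def test_unpaired_region_probabilities_match_oracle(suite_sequences, suite_ensembles, default_model):
    for seq in suite_sequences[:20]:
        structures = suite_ensembles[seq.residues]
        for i in range(1, seq.n + 1):
            for j in range(i, seq.n + 1):
                got = unpaired_probability(seq, i, j, model=default_model)
                oracle = oracle_unpaired_probability(structures, i, j, default_model)
                assert got == pytest.approx(oracle, abs=1e-9)


def test_unpaired_closed_forms():
    assert unpaired_probability("GAAAC", 2, 4) == pytest.approx(1.0)
    assert unpaired_probability("GAAAC", 1, 1) == pytest.approx(1 / (1 + E))


def test_pointwise_unpaired_consistency(suite_sequences, default_model):
    """Pr_u from the pair-probability marginal equals Pr_ss(k,k)."""
    for seq in suite_sequences[:20]:
        stats = basepair_probabilities(seq, model=default_model)
        for k in range(1, seq.n + 1):
            assert stats.u(k) == pytest.approx(
                unpaired_probability(seq, k, k, model=default_model), abs=1e-9
            )


def test_region_probability_monotone_under_inclusion():
    seq = RnaSequence("GGGAAACCC")
    for i in range(1, 10):
        for j in range(i, 10):
            outer = unpaired_probability(seq, i, j)
            if j > i:
                assert outer <= unpaired_probability(seq, i + 1, j) + 1e-12
                assert outer <= unpaired_probability(seq, i, j - 1) + 1e-12


def test_zero_energy_reduces_to_counting():
    model = EnergyModel(e_bp=0.0)
    pm = partition_matrices("GGGAAACCC", model=model)
    cm = count_matrix("GGGAAACCC")
    for i in range(1, 10):
        for j in range(i, 10):
            assert pm.q_value(i, j) == cm.value(i, j)


def test_high_temperature_limit(suite_sequences):
    model = EnergyModel(e_bp=-1.0, rt=1e6)
    for seq in suite_sequences[:15]:
        z = partition_matrices(seq, model=model).z
        c = count_structures(seq)
        assert abs(z - c) / c < 1e-3


def test_partition_guard():
    with pytest.raises(NumericGuardError):
        partition_matrices(RnaSequence("GC" * 100))


def test_dotplot_records():
    assert dotplot(basepair_probabilities("AAAA")).records == ()
    assert dotplot(basepair_probabilities("AAAA")).unpaired == (1.0,) * 4
    single = dotplot(basepair_probabilities("GAAAC"))
    assert len(single.records) == 1
    i, j, p = single.records[0]
    assert (i, j) == (1, 5) and p == pytest.approx(E / (1 + E))
    assert len(dotplot(basepair_probabilities("GGGAAACCC")).records) == 9
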