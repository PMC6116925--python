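"""The three interaction paradigms: hybrid-only, cofold, accessibility."""

import itertools
import math

import pytest

from bpfold import (
    DuplexPair,
    EnergyModel,
    FixtureSpec,
    FoldConfig,
    PairRule,
    RnaSequence,
    accessibility_penalties,
    cofold,
    duplex_matrix,
    enumerate_structures,
    generate_fixtures,
    hybrid_only,
    interaction_predict,
    nussinov_matrix,
    render_duplex_ascii,
)

E = math.e

WORKED = DuplexPair.from_raw("CCC", "CCCGGGGGG")


@pytest.fixture(scope="module")
def random_pairs():
    """30 seeded random duplexes, lengths 4..10 each."""
    seqs = generate_fixtures(FixtureSpec(count=60, length_range=(4, 10), seed=777))
    return [DuplexPair(a, b) for a, b in zip(seqs[::2], seqs[1::2])]


def brute_hybrid_max(pair: DuplexPair, rule: PairRule) -> int:
    """Independent check: maximum antiparallel-monotone intermolecular
    matching by explicit recursion over position pairs."""
    s1, s2r = pair.seq1, pair.seq2_reversed

    def rec(i: int, j: int) -> int:
        if i > pair.n or j > pair.m:
            return 0
        best = 0
        for a in range(i, pair.n + 1):
            for b in range(j, pair.m + 1):
                if rule.complementary(s1.base(a), s2r.base(b)):
                    best = max(best, 1 + rec(a + 1, b + 1))
        return best

    return rec(1, 1)


# ---------------------------------------------------------------------------
# hybridization-only
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "s1,s2,expected",
    [("AAA", "CCC", 0), ("CCC", "GGG", 3), ("CCC", "CCCGGGGGG", 3)],
)
def test_hybrid_optimum_examples(s1, s2, expected):
    matrix, _ = hybrid_only(DuplexPair.from_raw(s1, s2))
    assert matrix.optimum == expected
    assert matrix.optimum == brute_hybrid_max(DuplexPair.from_raw(s1, s2), PairRule())


def test_hybrid_matrix_shape_and_monotonicity():
    matrix, _ = hybrid_only(WORKED)
    assert matrix.value(0, 0) == 0 and matrix.value(3, 9) == 3
    for i in range(1, 4):
        for j in range(1, 10):
            assert matrix.value(i, j) >= matrix.value(i - 1, j)
            assert matrix.value(i, j) >= matrix.value(i, j - 1)
            assert matrix.value(i, j) <= min(i, j)


def test_hybrid_results_antiparallel_and_deduplicated():
    _, results = hybrid_only(WORKED)
    seen = set()
    for r in results:
        assert r.inter_pairs not in seen
        seen.add(r.inter_pairs)
        ones = [a for a, _ in r.inter_pairs]
        twos = [b for _, b in r.inter_pairs]
        assert ones == sorted(ones)
        assert twos == sorted(twos, reverse=True)  # original 5'->3' coords


def test_hybrid_ascii_rendering():
    _, results = hybrid_only(DuplexPair.from_raw("CCC", "GGG"))
    art = render_duplex_ascii(DuplexPair.from_raw("CCC", "GGG"), results[0])
    lines = art.splitlines()
    assert "CCC" in lines[0] and "|||" in lines[1] and "GGG" in lines[2]


# ---------------------------------------------------------------------------
# cofold
# ---------------------------------------------------------------------------

def test_cofold_no_pairs_possible():
    results = cofold(DuplexPair.from_raw("AAA", "AAA"))
    assert len(results) == 1 and results[0].score == 0


def test_cofold_worked_example_matches_concatenation_oracle():
    cfg = FoldConfig()
    results = cofold(WORKED, cfg, delta=0)
    assert all(r.score == 4 for r in results)
    hybrid_seq = RnaSequence("CCC" + "X" * 4 + "CCCGGGGGG", concatenated=True)
    oracle = enumerate_structures(hybrid_seq)
    oracle_opt = {s.pairs for s in oracle if len(s.pairs) == 4}
    assert max(len(s.pairs) for s in oracle) == 4
    assert {r.structure.pairs for r in results} == oracle_opt
    # intermolecular contacts sit at the 3' side of S2; an optimum using
    # exactly the three terminal Gs exists and positions 1..5 never engage
    inter_sets = {frozenset(b for _, b in r.inter_pairs) for r in results}
    assert frozenset({7, 8, 9}) in inter_sets
    assert all(min(s) >= 6 for s in inter_sets)


def test_cofold_never_pairs_linker(random_pairs):
    cfg = FoldConfig()
    for pair in random_pairs[:10]:
        lk_lo, lk_hi = pair.n + 1, pair.n + cfg.effective_linker_length
        for r in cofold(pair, cfg, delta=1):
            for a, b in r.structure.pairs:
                assert not (lk_lo <= a <= lk_hi or lk_lo <= b <= lk_hi)


def test_cofold_with_inert_partner_reduces_to_single_folding(random_pairs):
    # poly-A cannot pair with U-free sequences, so cofolding against it
    # must reproduce plain single-sequence folding of S1
    inert = RnaSequence("AAAA")
    candidates = [p.seq1 for p in random_pairs if "U" not in p.seq1.residues]
    candidates.append(RnaSequence("GGGAAACCC"))
    for seq in candidates:
        solo = nussinov_matrix(seq).optimum
        best = cofold(DuplexPair(seq, inert))[0]
        assert best.score == solo
        assert not best.inter_pairs


def test_cofold_dotbracket_encoding():
    r = cofold(WORKED)[0]
    assert set(r.dotbracket) <= set("().[]X")
    assert r.dotbracket.count("X") == 4
    assert r.dotbracket.count("[") == r.dotbracket.count("]") == len(r.inter_pairs)


# ---------------------------------------------------------------------------
# accessibility-based
# ---------------------------------------------------------------------------

def test_accessibility_closed_forms():
    assert accessibility_penalties("A").value(1, 1) == 0.0
    # G4 of the worked-example target has no admissible partner
    de = accessibility_penalties("CCCGGGGGG")
    assert de.value(4, 4) == pytest.approx(0.0, abs=1e-12)
    got = accessibility_penalties("GAAAC").value(1, 1)
    assert got == pytest.approx(math.log(1 + E), rel=1e-9)


def test_accessibility_nonnegative_everywhere(random_pairs):
    for pair in random_pairs[:8]:
        de = accessibility_penalties(pair.seq1)
        assert all(v >= 0 for v in de.entries.values())


def test_duplex_matrix_examples():
    assert duplex_matrix(DuplexPair.from_raw("C", "G")).d[(1, 1, 1, 1)] == -1
    assert duplex_matrix(DuplexPair.from_raw("CC", "GG")).d[(1, 2, 1, 2)] == -2


def test_duplex_minimum_matches_prefix_maximum(random_pairs):
    """Site-based duplex optimization with unbounded gaps reproduces the
    prefix-matrix optimum (scored in pair counts)."""
    rule = PairRule()
    for pair in random_pairs:
        matrix, _ = hybrid_only(pair, rule)
        tables = duplex_matrix(pair, rule, max_gap=None)
        best = -tables.min_energy() if tables.d else 0
        assert best == matrix.optimum


def test_interaction_single_pair_molecules():
    results = interaction_predict(DuplexPair.from_raw("C", "G"))
    assert len(results) == 1
    r = results[0]
    assert r.energy == pytest.approx(-1.0)
    assert r.favorable and r.delta_e1 == 0.0 and r.delta_e2 == 0.0
    assert r.inter_pairs == ((1, 1),)


def test_interaction_without_admissible_pairs():
    assert interaction_predict(DuplexPair.from_raw("AAA", "AAA")) == []


def test_interaction_worked_example_targets_loop_region():
    """The S2 hairpin leaves its central Gs accessible, so the optimal
    accessibility-based interaction forms there — a kissing-loop-style
    site, not the terminal Gs favored by the other paradigms."""
    results = interaction_predict(WORKED)
    assert results
    for r in results:
        lo, hi = r.site2
        assert 4 <= lo <= hi <= 6
        assert r.favorable
    # exhaustive scan over all scored boundaries confirms the optimum
    cfg, rule, model = FoldConfig(), PairRule(), EnergyModel()
    tables = duplex_matrix(WORKED, rule, model, cfg.max_gap)
    de1 = accessibility_penalties(WORKED.seq1, cfg, rule, model)
    de2 = accessibility_penalties(WORKED.seq2_reversed, cfg, rule, model)
    best = min(
        d + de1.value(i, k) + de2.value(j, l)
        for (i, k, j, l), d in tables.d.items()
    )
    assert results[0].energy == pytest.approx(best)


def test_interaction_energy_decomposition(random_pairs):
    for pair in random_pairs[:8]:
        for r in interaction_predict(pair, all_favorable=True):
            assert r.energy == pytest.approx(
                r.duplex_energy + r.delta_e1 + r.delta_e2
            )
            assert r.energy >= r.duplex_energy - 1e-12
            assert r.energy < 0


def test_interaction_pairs_antiparallel(random_pairs):
    for pair in random_pairs[:10]:
        for r in interaction_predict(pair):
            ones = [a for a, _ in r.inter_pairs]
            twos = [b for _, b in r.inter_pairs]
            assert ones == sorted(ones)
            assert twos == sorted(twos, reverse=True)


def test_paradigm_pair_count_hierarchy(random_pairs):
    """Hybridization-only bounds the intermolecular pair count of every
    cofold optimum and of every favorable accessibility interaction:
    both search restricted subsets of antiparallel matchings."""
    for pair in random_pairs:
        h, _ = hybrid_only(pair)
        best_cofold_inter = 0
        for r in cofold(pair):
            assert len(r.inter_pairs) <= h.optimum
            best_cofold_inter = max(best_cofold_inter, len(r.inter_pairs))
        for r in interaction_predict(pair, all_favorable=True):
            assert len(r.inter_pairs) <= h.optimum
            # the least-constrained paradigm that still models structure
            # also dominates the penalized one on this suite
            assert len(r.inter_pairs) <= best_cofold_inter
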