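# Methods

## Model

A secondary structure of an RNA `S ∈ {A,C,G,U}ⁿ` is a set `P` of base pairs
`(i,j)`, `i < j`, such that every position occurs in at most one pair, no
two pairs cross (`∄ (i,j),(p,q): i < p < j < q`), every pair is
complementary under the active rule, and `j − i > l` for the minimal loop
length `l`. Complementarity rules: `wc-gu` = {A–U, C–G, G–U} (default),
`wc` = {A–U, C–G}, `any` = all letter pairs (the sequence-agnostic
structure space used for asymptotics). The energy model assigns every pair
the same energy `E_bp`, so `E(P) = |P|·E_bp` and the Boltzmann weight of a
structure factorizes into per-pair weights `q_bp = exp(−E_bp/RT)`. `E_bp`
and `RT` are dimensionless (defaults −1 and 1): the simplified model fixes
no unit system, so temperature-like effects are explored by scaling `RT`.

All public coordinates are 1-based with inclusive intervals, matching
dot-bracket conventions; a pair `(i,j)` encloses at least `l` positions
(`j − i > l`), which is the bound the recursions use (`k < j − l`).

## Algorithms

**Counting.** `C[i,j] = C[i,j−1] + Σ_{i≤k<j−l, S_k~S_j} C[i,k−1]·C[k+1,j−1]`,
with empty intervals counting 1 (the empty structure). Counts are exact
Python integers — they exceed 64-bit range near n ≈ 60 for pairable
sequences, and the oracle comparisons demand exactness. The growth-factor
utility specializes the recursion to lengths (valid when every pair is
admissible): `f(m) = f(m−1) + Σ_{k=1..m−l−1} f(k−1)·f(m−k−1)`,
`f(0..l+1) = 1`, an O(n²) big-integer computation, and reports
`f(n+1)/f(n)`; at `l = 3` the ratio approaches ≈ 2.29 (≈ 2.3 at one
decimal) by n = 500.

**Base-pair maximization.** The unique variant mirrors the counting
decomposition with max/+1 in place of Σ/×. The ambiguous four-case variant
(i unpaired; j unpaired; pair (i,j); bipartition) fills identical optima
but decomposes non-uniquely; it is retained deliberately because its
duplicated suboptimal enumeration is instructive — duplicates are reported,
never collapsed. Traceback ties are broken by evaluating cases in the
printed order of the active recursion with the smallest pairing partner
first, making outputs deterministic.

**Suboptimal enumeration.** A work-stack over partial tracebacks (list of
unexpanded intervals, fixed pairs, achievable total); a partial is expanded
only while its achievable total stays within `delta` of the optimum. The
stack formulation bounds recursion depth and streams results. The same
machinery drives MEA enumeration; real-valued cell comparisons use an
absolute tolerance of 1e−9. The suboptimal band is absolute (pairs, or acc
units for MEA).

**Partition function & probabilities.** `Q`/`Qbp` follow the counting
recursion with the pair case weighted by `q_bp`; the module also fills the
single-table variant (pair case weighted directly) and asserts agreement to
1e−12 relative as an internal consistency check. Pair probabilities are
computed outside-in: the external term plus, for every admissible directly
enclosing pair `(p,q)`, a term `Pr_bp(p,q)·q_bp·Q[p+1,i−1]·Qbp[i,j]·
Q[j+1,q−1]/Qbp[p,q]`, evaluated in decreasing span order so enclosing
probabilities are final; the division is only ever taken for admissible
`(p,q)` (`Qbp > 0`). This direct evaluation is O(n⁴); the known O(n³)
outer-partition-function refinement is deliberately not implemented, to
keep the recursion in its canonical form. Unpaired-region probabilities
`Pr_ss(i,j)` substitute 1 for `Qbp[i,j]` in the same scheme: the region
carries no pair **end**, while pairs spanning it entirely from outside
remain allowed — consequently `Pr_ss` is monotone under region inclusion.
`Pr_u(k)` is the marginal `1 − Σ Pr_bp(·,k) − Σ Pr_bp(k,·)` and equals
`Pr_ss(k,k)` (tested to 1e−9).

Arithmetic is plain double precision guarded by a sequence-length cap
(default 150, configurable): overflow is refused with a clear error rather
than silently rescaled or moved to log space. At teaching scale this keeps
every intermediate value inspectable.

**MEA.** `acc(P) = Σ_{(i,j)∈P} 2γ·Pr_bp(i,j) + Σ_{k unpaired} Pr_u(k)`;
pairs count twice because they cover two positions, and γ (default 1)
scales pair against unpaired evidence. The maximization uses the unique
decomposition with `Pr_u(j)` in the unpaired case and `2γ·Pr_bp(k,j)` in
the pair case; traceback and suboptimal enumeration are shared with the
pair-maximization module. γ = 0 always yields the empty structure (pairs
contribute nothing but consume positions with non-negative `Pr_u`).

**Interaction prediction.** Molecules bind antiparallel; S2 is processed
through its reversed view (view position j ↔ original m−j+1) and all
results are mapped back to original 5′→3′ coordinates.

- *Hybridization-only*: `H[i,j] = max(H[i−1,j−1] + [S1_i ~ S2rev_j],
  H[i−1,j], H[i,j−1])`, a global-alignment-shaped DP with no gap cost; all
  optimal pair sets are collected by traceback and deduplicated (distinct
  paths that differ only in pure shifts carry identical pair sets).
- *Cofold*: fold `S1 + Xᴸ + S2` (linker length `L = l + 1` so the joined
  ends may pair) with the unique recursion; any pair touching an `X` is
  inadmissible, and linker-containing loops carry no special energy in this
  model. Output uses `()` for intramolecular, `[]` for linker-spanning
  pairs, `X` for the linker.
- *Accessibility-based*: duplex energies `D(i,k|j,l)` over all site
  combinations whose boundaries pair, built by extending a right-anchored
  interaction one pair at a time, with the distance between consecutive
  paired positions bounded by `max_gap` (default 15, configurable,
  `None` = unbounded) symmetrically on both molecules. Total energy
  `I = D + ΔE¹(i..k) + ΔE²(j..l)` with `ΔE = −RT·log Pr_ss ≥ 0` computed
  per molecule in isolation (for S2 on the reversed view). All co-minimal
  interactions are reported (ordered by site starts), or every favorable
  one (`I < 0`) behind a flag; `D`/`I` are stored sparsely keyed by the
  four boundaries, which is trivial at the intended scale. Tiny negative
  `ΔE` values arising from roundoff when `Pr_ss ≈ 1` are clamped to 0.

## Synthetic data

The fixture generator draws sequences of a given length range with a GC
bias (probability of emitting G/C, split evenly; A/U otherwise) from a
seeded `random.Random`, so a spec reproduces byte-identical fixtures. The
randomized test-suite uses 50 sequences of length 4–12 at balanced GC
(one fixed seed) plus the canonical inputs GAAAC, GGGAAACCC and the duplex
(CCC, CCCGGGGGG); the interaction suite uses 30 seeded duplexes of lengths
4–10. These lengths keep exhaustive enumeration exact and fast; they probe
algorithmic correctness, not biological realism — real RNAs are far longer,
pair with stacking-dependent energies, and fold under kinetic and cellular
constraints this model ignores, so passing tests certify the recursions,
not predictive accuracy on natural sequences.

## Verification strategy

Every dynamic program is checked against `enumerate_structures`, a
brute-force generator of the complete structure space built on the unique
decomposition (guarded at n = 25, overridable): counts exactly, optima
exactly, `Z`/`Pr_bp`/`Pr_ss`/MEA to 1e−9. The hybridization prefix DP is
cross-checked against the site-based duplex table with unbounded gaps
(their optima provably coincide) and, on small inputs, against a direct
recursive matching maximizer. Cofold results on the worked duplex are
compared to exhaustive enumeration of the 16-mer concatenation.

## Limitations and notes

- No Nearest Neighbor energies, dangling ends, or duplex initiation terms;
  no pseudoknots; no concentration dependence.
- Among the co-optimal cofold structures of (CCC, CCCGGGGGG), the
  intermolecular contacts occupy S2 positions 6–9, not only the three
  terminal Gs: sacrificing one hairpin pair and re-pairing internally ties
  the optimum. Enumeration reports all nine co-optima.
- A co-optimal cofold structure may carry no intermolecular pair at all
  while the accessibility paradigm still finds a favorable (kissing-style)
  interaction, so cofold intermolecular counts bound accessibility-based
  ones only in their best-over-optima form; the hybridization-only optimum
  bounds both paradigms unconditionally.
- The partition guard rejects rather than rescales; for sequences beyond
  ~150 nt a log-space implementation would be required.
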