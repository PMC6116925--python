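"""Partition function, base-pair probabilities and accessibility.

Structures are Boltzmann-weighted (weight q_bp per pair); Z normalizes
the distribution, Pr_bp(i,j) is the chance a pair forms somewhere in
the ensemble and Pr_ss(i,j) the chance a region stays single-stranded.
"""

from bpfold import (
    basepair_probabilities,
    dotplot,
    partition_matrices,
    unpaired_probability,
)

seq = "GGGAAACCC"
pm = partition_matrices(seq)
print(f"sequence: {seq}")
print(f"partition function Z = {pm.z:.6f}")

stats = basepair_probabilities(seq)
print("dot-plot records (i, j, Pr_bp > 1e-6):")
for i, j, p in dotplot(stats).records:
    print(f"  {i}\t{j}\t{p:.6f}")

loop = unpaired_probability(seq, 4, 6)
print(f"loop accessibility Pr_ss(4,6) = {loop:.6f}")

print()
print("The innermost helix pairs (1,9),(2,8),(3,7) dominate the ensemble;")
print("the A-loop 4..6 can never pair, so its accessibility is 1.")
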