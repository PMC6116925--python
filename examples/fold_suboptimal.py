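"""Base-pair maximization with optimal and suboptimal traceback.

The score matrix N holds the maximal number of base pairs per
subsequence; tracebacks within a score band of the optimum enumerate
structural alternatives.
"""

from bpfold import enumerate_suboptimal, mfe, nussinov_matrix, render_dotbracket

seq = "GGGAAACCC"
n = nussinov_matrix(seq)
print(f"sequence: {seq}")
print(f"maximal pairs N[1,n] = {n.optimum},  mfe (e_bp=-1) = {mfe(seq)}")

print("structures within 1 pair of the optimum:")
for entry in enumerate_suboptimal(seq, delta=1):
    print(f"  {render_dotbracket(entry.structure, len(seq))}  score {entry.score:g}")

print()
print("Each line is one distinct structure (unique decomposition: no")
print("duplicates); scores count base pairs, the optimum forms 3.")
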