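"""Karlin-Altschul similarity statistics for a sequence pair.

Aligns two related sequences, builds the null score distribution from
composition-preserving shuffles, fits a Gumbel (extreme value)
distribution, and reports the similarity score S, tail P-value, and
E-value (E = -ln(1 - P)).
"""

import phyloca as pc

model = pc.SubstitutionModel(pc.load_matrix("wag"))
tree = pc.read_newick("(A:0.4,B:0.4);")
alignment = pc.simulate_on_tree(tree, model, L=120, seed=5)
s1, s2 = alignment.rows

matrix = pc.blosum62()
(aligned1, aligned2), S = pc.align_pair(s1, s2, matrix, mode="global")
null = pc.null_scores(s1, s2, n_shuffles=500, seed=0, matrix=matrix)
evd = pc.fit_evd(null)
P = pc.pvalue(S, evd)
E = pc.evalue_from_score(S, evd)

print(f"observed score S = {S:.0f}")
print(f"null EVD: mu = {evd.mu:.1f}, beta = {evd.beta:.1f}")
print(f"P-value  = {P:.3g}")
print(f"E-value  = {E:.3g}")
# A tiny P/E says only that this much similarity is unlikely between
# shuffled sequences; it is not, by itself, evidence for homology —
# that question needs the model comparisons in the other examples.
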