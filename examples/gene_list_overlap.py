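"""Hypergeometric overlap of two disease gene lists.

Builds two lists of 125 and 397 genes sharing 20 symbols — the shape of the
hyperkalemia / lung-squamous-cell-carcinoma comparison — and tests whether
the overlap exceeds what random lists of those sizes would share in a
20,000-gene universe.
"""

import lfcmeta as lm

shared = [f"SHARED{i}" for i in range(20)]
hyperkalemia = shared + [f"HK{i}" for i in range(105)]
lscc = shared + [f"LSCC{i}" for i in range(377)]

pair = lm.GeneSetPair(hyperkalemia, lscc, universe_n=20000)
a_only, k, b_only = lm.venn_counts(pair)
res = lm.overlap_test(pair)

print(f"Venn decomposition:   {a_only} | {k} | {b_only}")
print(f"shared fraction of A: {res.percent_of_a:.1f}%")
print(f"enrichment p-value:   {res.p_value:.3g}")
# The p-value is P(X >= 20) for a hypergeometric draw of 397 genes against
# a 125-gene list in a 20,000-gene universe; it depends strongly on the
# universe size, which must be chosen by the analyst.
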