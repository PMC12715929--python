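"""Sampling-size vs cumulative Pfam count trends.

A Pfam genuinely co-localised with the anchor accumulates occurrences
steadily as regions are added, giving Spearman rho near 1; a rare
background Pfam plateaus and correlates weakly or not at all.
"""

from locus_colocal import build_count_table, default_spec, generate_corpus, subsample_trend

corpus = generate_corpus(default_spec(n_test=150, n_control=10, vocab_size=800), seed=6)
table = build_count_table(corpus.windows_test)

targets = {"PF03412",   # companion protease, planted in every region
           "PF01420",   # planted defence Pfam, ~5% of regions
           "PF90750"}   # a rank-751 background Pfam
for t in subsample_trend(table, targets, n_max=100, seed=7):
    rho = "undefined (constant)" if t.rho is None else f"{t.rho:.3f}"
    total = t.counts[-1] if t.counts else 0
    print(f"{t.pfam}: rho = {rho:<22} cumulative count at n=100: {total}")
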