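"""Consensus targets, bidirectional genes and condition discordance.

Recovers the planted estrogen-receptor response program from a simulated
comparison matrix, then shows the threshold-based call sets: genes in the
top regulated decile in at least half the comparisons (consensus), genes
strongly up in some comparisons and strongly down in others
(bidirectional), and genes whose average response differs by more than 70
percentile points between two conditions (discordant).
"""

from ermeta import synthetic as syn
from ermeta.harmonize import average_percentile, build_matrix, percentile_rank, presence_filter
from ermeta.meta_stats import bidirectional_genes, consensus_targets, discordance_genes

tables, metas, truth = syn.generate_comparisons(syn.ComparisonConfig.strong(seed=4))
m = presence_filter(build_matrix({c: percentile_rank(t) for c, t in tables.items()}, metas))

cons = consensus_targets(m, direction="up", top_frac=0.10, min_frac=0.5)
planted = set(truth.roles["core_up"]) & set(m.index)
print(f"consensus up-targets (top decile in >= 50% of comparisons): {len(cons)}")
print(f"of which planted core ER-response genes: {len(set(cons.index) & planted)}/{len(planted)}")
print("\ntop of the ranking (consistency = fraction of comparisons in the top decile):")
print(cons.head(5).round(3).to_string())

pm, ptruth = syn.planted_percentile_matrix(seed=4)
bid = bidirectional_genes(pm, top_frac=0.10, min_frac=0.15)
hits = bid.genes & set(ptruth.roles["bidirectional"])
print(f"\nbidirectional genes called: {len(bid)} ({len(hits)} of "
      f"{len(ptruth.roles['bidirectional'])} planted)")
print("a bidirectional gene is in the top up-decile in >=15% of comparisons AND")
print("the top down-decile in >=15% — context-dependent ER targets behave this way.")

# discordance between the two simulated drug classes
serd = [c for c, meta in metas.items() if meta.compound_class == "SERD" and c in m.columns]
serm = [c for c, meta in metas.items() if meta.compound_class == "SERM" and c in m.columns]
a_pref, b_pref = discordance_genes(
    average_percentile(m, serd), average_percentile(m, serm), delta_cut=70
)
print(f"\nSERD-preferential genes (delta percentile > 70): {len(a_pref)}")
print(f"SERM-preferential genes: {len(b_pref)}")
print("(both classes act through the same simulated program, so few genes diverge)")
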