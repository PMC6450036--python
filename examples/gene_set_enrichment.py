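"""Gene-set activity for one cluster.

Tests gene sets for enrichment in a cluster's expressed genes (median > 0)
with a one-sided Fisher's exact test; only sets with 10-500 genes are
admitted and Bonferroni (alpha = 0.01) controls multiple testing.
"""

import celltyper as ct

# a cluster expressing genes g0..g19 out of a 200-gene universe
profile = ct.ClusterProfile(
    cluster_id=0, n_cells=30,
    median_expression={f"g{i}": (1.5 if i < 20 else 0.0) for i in range(200)},
)

collection = ct.GeneSetCollection(sets={
    "PATHWAY_ON":   tuple(f"g{i}" for i in range(15)),        # expressed
    "PATHWAY_OFF":  tuple(f"g{i}" for i in range(100, 115)),  # silent
    "TOO_SMALL":    ("g0", "g1"),                             # not admitted
})

rows = ct.cluster_gene_set_activity(profile, collection)
print("set          overlap  size  p          significant")
for row in rows:
    print(f"{row['set_name']:<12} {row['overlap']:>7}  {row['set_size']:>4}  "
          f"{row['p']:<9.3g}  {row['significant']}")

# PATHWAY_ON overlaps all 15 of its genes with the 20 expressed ones - far
# more than chance in a 200-gene universe - and survives Bonferroni;
# TOO_SMALL is never tested (below the 10-gene floor).
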