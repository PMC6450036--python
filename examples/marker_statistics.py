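"""Marker frequencies, down-weighting and the ubiquitousness index.

Builds a compendium in which some markers are shared between cell types,
then prints f(g) (how many cell types list the gene) and the weight
w(g) = 1 + sqrt((max f - f(g)) / (max f - min f)) used by the CTA score.
"""

import celltyper as ct
from celltyper.simulate import marker_table_with_frequencies

table = marker_table_with_frequencies(
    {"specific": 1, "narrow": 2, "mid": 3, "broad": 5}
)
freq = ct.gene_frequency(table)

print("gene      f(g)  w(g)")
for gene in ("specific", "narrow", "mid", "broad"):
    print(f"{gene:<9} {freq[gene]:>4}  {ct.marker_weight(gene, freq):.4f}")

# Weights are bounded in [1, 2]: a gene listed by a single cell type scores
# with double weight, a gene shared by every cell type contributes with
# weight 1, so broad markers cannot dominate the annotation.

profiles = [
    ct.ClusterProfile(cluster_id=i, n_cells=20,
                      median_expression={"specific": 1.0 if i == 0 else 0.0,
                                         "broad": 1.0})
    for i in range(8)
]
print(f"\nUI(specific) = {ct.ubiquitousness_index('specific', profiles):.3f}  "
      f"(expressed in 1 of 8 clusters)")
print(f"UI(broad)    = {ct.ubiquitousness_index('broad', profiles):.3f}  "
      f"(expressed everywhere: housekeeping-like)")
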