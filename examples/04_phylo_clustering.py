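"""Cluster ASVs by cutting the phylogeny, and filter by subject prevalence.

Exact sequence variants are sparse across subjects; grouping tips whose
patristic distances merge below a cut height h recovers genus-like units.
A height is interpretable as percent sequence identity via the median
pairwise base-pair difference of cluster members.
"""

from plasticome import (
    aggregate_by_cluster,
    cut_tree,
    fixture_small,
    height_to_identity,
    prevalence_filter,
)

table, metadata, tree, taxonomy, truth = fixture_small()

ca = cut_tree(tree, h=0.1)
print(f"{len(ca.assignment)} ASVs -> {ca.n_clusters} clusters at h=0.1")
multi = ca.summary[ca.summary.n_members > 1]
print(f"multi-member clusters: {len(multi)}, "
      f"largest has {ca.summary.n_members.max()} ASVs")

# a median within-cluster difference of 7.5 bp over 233 bp amplicons
print(f"7.5 bp median difference over 233 bp = "
      f"{height_to_identity(7.5, 233)}% sequence identity")

clustered = aggregate_by_cluster(table, ca)
assert (clustered.sum(axis=1) == table.sum(axis=1)).all()
print(f"aggregated table: {clustered.shape[0]} samples x {clustered.shape[1]} clusters "
      "(per-sample totals conserved)")

for diet in ("low-carb", "low-fat"):
    kept = prevalence_filter(clustered, metadata, diet, min_frac=0.10)
    print(f"{diet}: {len(kept)}/{clustered.shape[1]} clusters in >=10% of subjects")
# Downstream differential abundance only tests the features that survive
# this per-diet subject-prevalence filter.
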