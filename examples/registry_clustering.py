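"""Inspect and re-derive the template registry's cluster structure.

Loads the packaged 55-template registry, shows its 16 clusters, then
re-clusters a small subset from scratch (all-vs-all TM-score, average
linkage on d = 1 - TM) and verifies the shipped grouping is recovered.
"""

from igstrand.registry import (
    cluster_templates,
    default_registry,
    pairwise_tm_distance,
    partitions_equal,
    select_representatives,
)

registry = default_registry()
print(f"packaged registry: {len(registry)} templates in {len(registry.clusters)} clusters")
for cid, members in list(registry.clusters.items())[:5]:
    rep = registry.representatives[cid]
    print(f"  cluster {cid:>2} ({len(members):>2} members) representative: {rep}")

# re-cluster a subset spanning four shipped clusters
ids = (
    registry.clusters[1][:3]   # V-set
    + registry.clusters[2][:3] # C1-set
    + registry.clusters[7]     # cadherin
    + registry.clusters[12]    # lamin tail domain
)
sub = registry.subset(ids)
dist, order = pairwise_tm_distance(sub)
assignment = cluster_templates(sub, k=4, distance=dist)
shipped = {tid: registry[tid].cluster_id for tid in ids}
print(f"\nre-clustered {len(ids)} templates at k=4;",
      "matches shipped partition:" , partitions_equal(assignment, shipped))

reps = select_representatives(sub, distance=dist)
print("medoid representatives:", reps)
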