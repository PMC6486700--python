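"""Reproducibility check: cluster samples on all metaproteins.

Cityblock distance on normalized metaprotein profiles with unweighted
average linkage (UPGMA); technical replicates should merge before any
cross-plant merge.
"""

from metaprofiler import (
    SimulationConfig,
    build_metaproteins,
    cluster_samples,
    default_community,
    filter_by_fdr,
    merge_engines,
    normalize,
    simulate_psms,
)
from metaprofiler.profiles import matrix_from_metaproteins

sim = simulate_psms(
    default_community(),
    SimulationConfig(n_plants=2, spectra_depth=4000, seed=3),
)
merged = merge_engines(filter_by_fdr(s) for s in sim.psm_sets.values())
metaproteins = build_metaproteins(
    merged, sim.reference.annotations, sim.reference.tree
)
fractions = normalize(matrix_from_metaproteins(metaproteins))
dendrogram = cluster_samples(fractions)

print("merge order (height = cityblock distance):")
for left, right, height in dendrogram.merges:
    print(f"  {'+'.join(left):>24s}  |  {'+'.join(right):24s} at {height:.4f}")
print("\nNewick:", dendrogram.to_newick())
# The first merges pair _R1 with _R2 samples (technical replicates), then
# time points within a plant, and only then samples from different plants.
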