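"""The disease space: proximity network backbone.

Proximity between two diseases is the minimum conditional probability of
sharing a relative disease disadvantage.  The backbone keeps the maximum
spanning tree plus the strongest remaining links until the average degree
reaches four.
"""

from healthspace import (
    binarize,
    build_disease_space,
    compute_proximity,
    compute_rdd,
    generate_world,
)

world = generate_world(l=40, k=60, noise=0.05, seed=7)
M = binarize(compute_rdd(world.to_matrix()))
Phi = compute_proximity(M)
net = build_disease_space(Phi, target_avg_degree=4.0)

k = net.number_of_nodes()
mst_edges = sum(1 for _, _, d in net.edges(data=True) if d["in_mst"])
print(f"diseases: {k}; backbone edges: {net.number_of_edges()}")
print(f"  on the maximum spanning tree: {mst_edges} (= k - 1)")
print(f"  added strongest links: {net.number_of_edges() - mst_edges}")
print(f"average degree: {2 * net.number_of_edges() / k:.2f}")
print(f"weakest added proximity (cut-off): {net.graph['cutoff']:.3f}")
print(
    "-> diseases close in this network tend to afflict the same countries;\n"
    "   the tree is the co-occurrence backbone, extra links fill in clusters."
)
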