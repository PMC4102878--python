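"""Consensus co-occurrence networks and their modules.

Builds, for each simulated ecosystem, the network of taxon pairs whose
Spearman correlation exceeds the stringency cutoffs (0.5 gray, 0.75 black
in the usual rendering) in EVERY replicate, then partitions each network
into modules by divisive edge-betweenness removal.
"""

from cooccurnet import (
    build_consensus,
    girvan_newman,
    intersect_networks,
    module_summary,
    preset_signal,
    replicate_correlations,
    simulate_study,
)

study = simulate_study(preset_signal(seed=1))
nets, parts = {}, []
for eco in study.ecosystems():
    css = [replicate_correlations(study, eco, r) for r in study.replicates(eco)]
    net = build_consensus(css, sign="positive", cutoffs=(0.5, 0.75))
    nets[eco] = net
    part = girvan_newman(net)
    parts.append((eco, "positive", 0.5, part))
    by_level = {}
    for _, d in net.edges.items():
        by_level[d["level"]] = by_level.get(d["level"], 0) + 1
    print(f"{eco}: {net.graph.number_of_nodes()} taxa, "
          f"{net.graph.number_of_edges()} consensus edges "
          f"(per level: {by_level}); {part.n_modules} modules, "
          f"Q = {part.modularity:.3f}")

print("\nModule summary:")
print(module_summary(parts).to_string(index=False))

shared = intersect_networks(nets["E1"], nets["E2"])
print(f"\nEdges shared between ecosystems: {shared or 'none'}")
print(
    "\nEach ecosystem's modules recover its planted correlation blocks; the\n"
    "two ecosystems were given disjoint pair sets, so the cross-ecosystem\n"
    "intersection is (up to rare spurious edges) empty."
)
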