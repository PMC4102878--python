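"""Keystone ranking from the degree-betweenness power-law mixed model.

Simulates a community whose taxa share one latent habitat factor with
heterogeneous loadings (pairwise latent correlation lambda_i * lambda_j, a
rank-one structure that is always jointly feasible). Thresholding the
resulting correlations gives a core-periphery network: high-loading taxa
become hubs with both high degree and high betweenness. The example fits
betweenness = alpha * degree^beta across replicate networks with a random
intercept per replicate, and ranks taxa by predicted betweenness.
"""

import itertools

import numpy as np

from cooccurnet import (
    SimConfig,
    fit_power_mixed,
    node_stats,
    rank_keystones,
    replicate_correlations,
    replicate_network,
    simulate_study,
)

n_taxa = 14
loadings = np.linspace(0.55, 0.97, n_taxa)
pairs = [
    # Spearman target implied by latent correlation lambda_i * lambda_j
    (i, j, float(6 / np.pi * np.arcsin(loadings[i] * loadings[j] / 2)))
    for i, j in itertools.combinations(range(n_taxa), 2)
]
cfg = SimConfig(
    n_ecosystems=1, replicates_per_ecosystem=3, samples_per_replicate=100,
    n_taxa=n_taxa, correlated_pairs={"E1": pairs}, seed=5,
)
study = simulate_study(cfg)

stats = []
for rep in study.replicates("E1"):
    cs = replicate_correlations(study, "E1", rep)
    net = replicate_network(cs, cutoff=0.5, sign="positive")
    stats.extend(node_stats(net, replicate=rep, level=0.5))
    print(f"{rep}: {net.graph.number_of_nodes()} taxa, "
          f"{net.graph.number_of_edges()} edges above the 0.5 cutoff")

fit = fit_power_mixed(stats, "E1", 0.5)
print(f"\npower fit: betweenness ~ {fit.alpha:.3f} * degree^{fit.beta:.2f} "
      f"(p[beta] = {fit.beta_p:.2g}, n = {fit.n_obs}, "
      f"{fit.n_excluded_zero} zero-betweenness nodes excluded)")

print("\ntop keystone candidates (highest predicted betweenness):")
for rank, (taxon, pred) in enumerate(rank_keystones(fit, stats, k=3), 1):
    print(f"  {rank}. {taxon}  predicted betweenness {pred:.3f}")

print(
    "\nThe highest-loading taxa sit at the network core, carrying most\n"
    "shortest paths between peripheral taxa; the fitted power law ranks\n"
    "them on top - the taxa whose loss would most fragment co-occurrence."
)
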