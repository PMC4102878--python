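# cooccurnet

Multi-scale analysis of microbial co-occurrence from replicated abundance
tables: a community-level test for differences in co-occurrence structure
between ecosystems, within-ecosystem consensus networks with
edge-betweenness modules, and node-level statistics with keystone-taxon
ranking — plus a seeded simulator that generates replicated
multi-ecosystem count tables with controlled correlation structure, so
every part of the pipeline can be exercised and calibrated without any
external data.

## Who it is for

Microbial ecologists with taxon-by-sample count tables (e.g., 16S rRNA
amplicon abundances summarized at order or family level) collected as
replicate groups nested within ecosystems, who want to ask, at three
scales:

1. **Communities** — do ecosystems differ in their co-occurrence
   patterns? Each (taxon, ecosystem, replicate) abundance profile becomes
   an object; objects are compared by Spearman distance `d = 1 − ρ`
   (strong positive co-occurrence ⇒ small distance) and ecosystems by a
   one-way PERMANOVA (pseudo-F, label permutation; default 9999
   permutations).
2. **Modules** — which taxa form densely connected groups? An edge joins
   two taxa when `ρ` passes a stringency cutoff (0.5 / 0.75) in **every**
   replicate of the ecosystem; modules come from divisive edge-betweenness
   removal with the partition chosen by maximum modularity Q.
3. **Pairs and nodes** — which pairs co-occur in *several* ecosystems
   (network intersection), and which taxa are keystones? Betweenness is
   modeled against normalized degree as a power law `b = α·x^β` via a
   mixed model (random intercept per replicate); keystones are the taxa
   with the highest predicted betweenness.

## Worked example

```python
from cooccurnet import (simulate_study, preset_signal,
                        spearman_distance_matrix, permanova,
                        replicate_correlations, build_consensus,
                        girvan_newman)

study = simulate_study(preset_signal(seed=1))     # 2 ecosystems x 3 replicates
dm = spearman_distance_matrix(study)
print(permanova(dm, n_permutations=9999, seed=1))

css = [replicate_correlations(study, "E1", r) for r in study.replicates("E1")]
net = build_consensus(css, sign="positive", cutoffs=(0.5, 0.75))
part = girvan_newman(net)
print(net.graph.number_of_edges(), part.n_modules, round(part.modularity, 3))
```

Output:

```
PermanovaResult(pseudo_F=5.362783454140965, r_squared=0.043471647639456296,
                p=0.0001, n_permutations=9999, group_sizes={'E1': 60, 'E2': 60},
                seed=1)
30 5 0.8
```

The signal preset plants ecosystem-specific correlation blocks, so
ecosystem membership explains a significant share of co-occurrence
distance (p = 0.0001, far below the 0.02 the simulated workflow is
calibrated to beat), the consensus network keeps exactly the planted
30 within-block edges of E1, and module detection recovers the five
blocks (Q = 0.8). The `examples/` directory has one narrative script per
capability (community test, consensus networks + modules, keystones,
rarefaction + composition test); each prints its numbers with a short
interpretation.

## Command line

Every stage is also a subcommand of `cooccurnet`:

```sh
cooccurnet simulate --preset signal --seed 1 --out-table t.tsv --out-meta m.tsv
cooccurnet correlate --table t.tsv --meta m.tsv --out corr.tsv
cooccurnet distance --table t.tsv --meta m.tsv --out d.tsv --groups-out g.tsv
cooccurnet permanova --distances d.tsv --groups g.tsv --seed 1
cooccurnet network --edges corr.tsv --ecosystem E1 --out net.tsv --graphml net.graphml
cooccurnet modules --net net.graphml --out modules.tsv
cooccurnet demo --preset signal --seed 1 --outdir demo_out   # all 9 stages + manifest
```

Inputs are plain TSV: an abundance table (`taxon` + one column per
sample) and a metadata table (`sample_id`, `ecosystem`, `replicate`).
Networks export as edge-list TSV and GraphML.

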