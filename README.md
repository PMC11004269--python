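# asvnet

Cross-domain (bacteria + fungi) microbial co-occurrence network analysis for
ASV count tables, built for amplicon studies that ask how a treatment
gradient — e.g. phosphorus addition to a grassland soil — reshapes the
complexity and stability of the soil community's interaction structure.

Nodes are amplicon sequence variants (ASVs) from both the 16S (bacterial)
and ITS (fungal) domains; edges are strong, significant rank correlations
between their abundance profiles. The package covers the full workflow:

* **Screening** — keep taxa with relative abundance > 0.1 % of reads that
  occur in > 60 % of samples.
* **Edge inference** — Spearman ρ over all retained pairs; keep edges with
  ρ² > 0.9 and p < 0.05 (sign retained, ties averaged, optional BH
  correction).
* **Topology panel** — edges/nodes by sign and domain, edge density
  2E/(N(N−1)), average degree 2E/N, average path length, Freeman degree /
  betweenness / closeness centralizations.
* **Stability** — natural connectivity λ̄ = ln((1/N) Σᵢ e^{λᵢ}) of the
  adjacency spectrum, and robustness = the ratio of natural connectivity
  after random removal of 50 % of nodes to the intact value, plus the full
  removal decay curve.
* **Keystone cartography** — modularity-based module detection, Zi
  (within-module degree z-score) and Pi (participation coefficient),
  Guimerà–Amaral roles with thresholds Zi > 2.5, Pi > 0.62, and keystone
  relative-abundance summaries by rank and treatment.
* **Supporting statistics** — ACE and Gini–Simpson indices, analytic
  rarefaction curves, Bray–Curtis + ANOSIM, one-way ANOVA with Fisher-LSD
  compact letter displays, percent change vs control, Pearson
  environment-vs-topology panels, and LMG relative-importance decomposition
  of regression R².
* **Synthetic data** — a treatment-structured multi-domain generator with
  planted correlation modules and hub taxa, giving ground truth for every
  stage (see `docs/methods.md`).

File formats are plain TSV (feature table, taxonomy, metadata), CSV edge
lists and GraphML (Cytoscape-compatible), all with lossless round-trips.

## Worked example

```python
import asvnet as av

design = av.default_design(seed=0)          # 4 treatments x 3 replicates,
counts, taxonomy = av.simulate_counts(design)  # 505 + 87 retained taxa
metadata = av.simulate_env_and_traits(design)

retained = av.filter_taxa(counts)           # 592 of 2592 taxa survive
edges = av.spearman_edges(retained)         # rho^2 > 0.9, p < 0.05
net = av.build_network(edges, taxonomy)

panel = av.topology_summary(net)
print(panel.nodes, panel.edges, round(panel.average_degree, 2),
      round(panel.positive_pct, 1))
# 590 10340 35.05 70.1

stab = av.robustness(net, fraction=0.5, n_reps=50, seed=1)
print(round(stab.natural_connectivity_full, 2), round(stab.robustness_mean, 3))
# 49.05 0.453

modules = av.detect_modules(net)
roles = av.classify_nodes(av.zi_pi(net, modules))
print(modules.n_modules, roles["role"].value_counts().to_dict())
# 8 {'peripheral': 588, 'module_hub': 2}
```

The simulated network lands at the scale such studies report (≈590 nodes,
≈10⁴ edges, average degree ≈40); half-removal robustness near 0.45 says the
spectral redundancy of the network degrades almost proportionally with
random node loss; and the eight planted modules are recovered exactly
(adjusted Rand index 1.0 for this seed), with the planted hub taxa carrying
the highest within-module connectivity.

The same pipeline is scriptable from the shell:

```bash
asvnet simulate --seed 0 --out-dir run/
asvnet network run/counts.tsv run/taxonomy.tsv --out run/net
asvnet metrics run/net.graphml
asvnet stability run/net.graphml --fraction 0.5 --reps 100 --seed 1
asvnet keystone run/net.graphml run/counts.tsv run/taxonomy.tsv \
    run/metadata.tsv --out-prefix run/key
asvnet summarize run/metadata.tsv --out run/summary.tsv
```

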