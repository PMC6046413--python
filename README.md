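# micronet

Graph-theoretic analysis of the microbial communities shared between an
arthropod vector and its vertebrate host. The package was built around the
study system of *Ixodes ricinus* ticks and bank voles (*Myodes glareolus*)
sampled in two biotopes (forest and ecotone), but every step works on any
sample × taxon read-count table with carrier/biotope metadata.

Pairwise comparisons of microbiomes ("sample A shares k genera with sample
B") carry little ecological meaning on their own. `micronet` instead treats
co-occurrence as a graph problem:

* **Genus networks.** Two bacterial genera are linked when they are detected
  together in at least one individual carrier; the edge weight counts those
  carriers. One network is built per carrier × biotope stratum, and each
  genus is ranked by weighted degree `WD(v) = Σ_u w(v,u)`, betweenness
  centrality (BNC), local clustering coefficient (CC) and PageRank (PR).
  The WD distribution is tested for scale-freeness with a
  Clauset–Shalizi–Newman power-law fit (`p(x) ∝ x^(-γ)` with KS-selected
  `x_min`), and communities of co-occurring genera are found by Louvain
  modularity maximisation.
* **Phylogenetic structure.** Pagel's λ ∈ [0, 1] rescales the off-diagonal
  entries of the Brownian-motion tip covariance `C_ij = shared root-to-MRCA
  path length`; its ML estimate measures whether a tip trait (prevalence,
  BNC, CC, PR) clusters on the 16S genus tree. Faith's PD (total branch
  length of the minimal rooted subtree spanning a genus set) measures the
  phylogenetic diversity a community of carriers circulates. Trees come in
  as Newick or are built from a distance matrix by Saitou–Nei neighbor
  joining.
* **Host specificity.** Per biotope, each genus is scored by
  `log10(0.1 + mean reads in voles) − log10(0.1 + mean reads in ticks)`,
  plotted against its WD: extreme scores flag genera tied to one carrier.
* **Carrier networks.** Individual ticks and voles become nodes linked by
  their number of shared genera; Louvain communities on this joint graph
  reveal whether the two carriers mix and how concentrated the circulated
  PD is (the Pareto-style "20% of ticks carry most of the PD" pattern).

Before any network is built, read tables pass the three standard filters:
drop taxa unassigned at genus level, drop singletons (taxa detected in one
sample overall), and zero out occurrences below each taxon's 10th-percentile
read cutoff. PCR replicates can be merged with the both-positive rule
(a taxon counts only if both replicates detect it; reads are then summed).

A synthetic-data module generates full datasets with known ground truth —
latent "packets" of co-circulating genera, carrier- and biotope-structured
genus pools, negative-binomial read depths, Yule trees and λ-Brownian
traits — so the whole pipeline is testable without sequencing data.

## Worked example

```bash
python analysis/01_simulate.py 1          # default study design, seed 1
python analysis/02_filter_and_networks.py 1
```

prints

```
samples: 570  genera: 126
mean genera per tick: 15.39 (min 7, max 24)
mean genera per vole: 13.68 (min 5, max 22)
     stratum  n_nodes  n_links  n_communities  powerlaw_gamma  powerlaw_ks
 tick_forest       55     1483              5       35.512265     0.098455
tick_ecotone       60     1619              5       22.140653     0.084022
 vole_forest       60     1752              6       17.685232     0.071671
vole_ecotone       59     1607              5        3.835643     0.123154

genera shared between carriers: 12 of 126 (9.5%)
```

Each row is one carrier × biotope co-occurrence network: ~55–60 genera
survive filtering in each stratum and are densely interlinked (1.5–1.8 k
weighted edges). `analysis/03_phylo_signal.py` then shows Pagel's λ ≈ 0 for
prevalence and all centrality indexes — as expected here, because the
generator assigns genera to packets independently of the tree, so closely
related genera should *not* co-occur preferentially — and
`analysis/05_carrier_communities.py` reports, per biotope, how the minority
tick communities accumulate more Faith's PD than the single largest one
(e.g. forest ticks: largest community holds 32 % of individuals with PD
74.7, the remaining 68 % accumulate PD 175.5, ratio 2.35).

The same steps are available as a CLI (`micronet simulate | filter |
net-build | net-metrics | communities | phylo-signal | specificity |
carrier-net | run`); `micronet run --config config.yaml` executes the whole
pipeline and writes node-metric tables, GEXF graphs, λ tables, specificity
tables, community summaries and a JSON manifest of every seed and filter
parameter used.

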