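# Methods

This note records the models, estimators, defaults and numerical choices
behind `micronet`, and what the synthetic-data tests do and do not show
about real sequencing data.

## Data model and filtering

The unit of observation is one individual carrier (a questing tick or a
vole spleen) with a vector of genus-level read counts from two pooled PCR
replicates of a 16S rRNA amplicon. Replicate merging uses the
both-positive rule: a genus is accepted for a sample only when both
replicates detect it, and accepted reads are summed. Merging is applied at
whatever taxonomic rank the input table carries (OTU tables can first be
collapsed to genus with `sample_io.aggregate_taxa`).

Three filters run, in order, once each:

1. **Unassigned taxa** (no genus-level classification) are dropped.
2. **Singletons** — taxa detected in exactly one sample of the whole
   table — are dropped.
3. **Per-taxon low-read cutoff.** For each taxon the 10th percentile of
   its *nonzero* read counts (linear interpolation between order
   statistics) becomes its individual cutoff; occurrences strictly below
   the cutoff are zeroed, equal values are retained. Zeros are excluded
   from the percentile because they are non-detections, not low reads.

The cutoff is *established once* from the unfiltered distribution. It
cannot be idempotent under re-estimation — removing the lowest decile
shifts the next percentile upward, so repeated re-estimation would ratchet
away the whole tail — and the implementation therefore exposes the
recorded cutoffs so the identical filter can be re-applied as a no-op.
Singleton removal is idempotent as-is (removing a column does not change
other columns' occurrence counts). Re-running singleton removal after the
cutoff step is off by default and available as `iterate_filters`.

Accumulation (rarefaction) curves use the exact hypergeometric
expectation for subsampling without replacement,
`E[taxa at depth d] = Σ_t (1 − C(N−n_t, d)/C(N, d))`, evaluated with
log-gamma; a Monte-Carlo mode is retained as the sampling oracle.

## Genus co-occurrence networks

Within one carrier × biotope stratum, the presence matrix `P` (samples ×
taxa, booleans after filtering) yields the co-occurrence count matrix
`PᵀP`; off-diagonal entries ≥ 1 become weighted undirected edges. Genera
detected in the stratum but never jointly with another genus remain as
isolated nodes.

Node indexes:

* **WD** — sum of incident edge weights.
* **BNC** — Brandes betweenness on *unweighted* shortest paths,
  unnormalized. **CC** — local clustering on the binarized graph.
  These are the classic topological variants (the defaults of the common
  desktop network tools); weighted alternatives (`1/w` edge lengths) are
  available behind a flag for sensitivity analysis.
* **PR** — power iteration on the weight-proportional transition matrix
  with damping 0.85 (standard default) and tolerance 1e-9. Isolated nodes
  hold teleport-only mass during iteration; a final renormalisation makes
  the vector sum to exactly 1. On graphs without isolated nodes this
  coincides with the usual PageRank.
* **Communities** — Louvain modularity maximisation on edge weights,
  seed-fixed, labels 0..k−1 by decreasing community size with ties broken
  by the lowest member label (greedy CNM agglomeration is the available
  alternative). Modularity maximisation is the operative contract for
  "Newman-type" community detection.

**Power-law fit of WD.** Continuous maximum likelihood
`γ̂ = 1 + n / Σ ln(x_i/x_min)` with `x_min` selected by minimising the KS
distance between the empirical tail and the fitted CDF
(Clauset–Shalizi–Newman). At most 200 quantile-spaced unique values are
scanned as `x_min` candidates (keeps the scan O(200·n); recovery of
γ = 2.5 at n = 10 000 is within 0.01 on average in the tests). Fits need
≥ 10 tail points; an all-equal input returns a degenerate flag. A log-log
CCDF regression slope is reported alongside for comparability with older
practice, but the MLE is the estimator of record.

## Phylogenetics

Trees are rooted, with branch lengths, tips labelled by genus. From a
pairwise distance matrix (e.g. 16S distances computed elsewhere) a tree is
built by Saitou–Nei neighbor joining; on additive matrices the
reconstruction reproduces the input path lengths to 1e-9. Negative branch
estimates are clamped to 0 with the deficit moved to the sibling branch
(standard practice) and flagged with a warning. Q-criterion ties break on
the lexicographically first pair so results are deterministic.

**Faith's PD** uses the rooted convention: the total branch length of the
minimal subtree connecting the chosen tips *and* the root, so a single tip
contributes its root-to-tip path. The convention is fixed and documented
because community-level PD values cannot adjudicate it.

**Pagel's λ.** For trait vector `y` over tips, the model is
`y ~ N(β·1, σ² C(λ))` where `C` holds shared root-to-MRCA path lengths and
`C(λ)` multiplies the off-diagonal entries by λ ∈ [0, 1]. At each λ, β and
σ² are profiled analytically by GLS through a Cholesky factorisation; λ is
then optimised by bounded scalar search (tolerance 1e-6) with the boundary
log-likelihoods at 0 and 1 always evaluated, so `λ̂ ∈ [0, 1]` by
construction and `ℓ(λ̂) ≥ max(ℓ(0), ℓ(1))`. A star tree (all off-diagonal
shared paths zero) makes λ unidentifiable; the fit is flagged
(`identifiable = False`, λ̂ = NaN) instead of returning an arbitrary
interior optimum. Network indexes are used as traits untransformed (a
log1p option exists for heavy-tailed indexes); a likelihood-ratio p-value
against λ = 0 is provided as a convenience.

## Host specificity

Per biotope, each genus's mean reads per carrier (zeros included; an
option restricts to positive samples) is transformed as
`log10(0.1 + mean)` — base 10 is a pure rescaling and affects no ranking —
and the vole−tick difference is the specificity score, antisymmetric under
carrier swap. The raw read-sum ratio (voles/ticks) is reported alongside
(`inf` when only voles carry the genus, NaN when neither does). The WD on
the score-vs-WD chart comes from the pooled within-biotope network by
default; carrier-specific networks can be passed instead.

## Carrier networks and PD concentration

All samples of one biotope, both carriers together, form a graph whose
edge weights count shared genera (no weight threshold by default;
`min_shared` is available). Louvain communities run on this joint graph,
because tick/vole separation is a *finding* to be read off the partition,
not an input. Per community and carrier: percent of that carrier's
individuals, size of the pooled genus union, Faith's PD of the union, and
the mean per-individual PD (both the union-PD and the mean are emitted;
neither is silently preferred). `pd_concentration` splits communities into
the largest (by percent of individuals) versus the rest and reports the
minors' *summed* PDs ("accumulated PD") over the major's PD; the
pooled-union variant can be derived from the emitted per-community values.

## Synthetic data

The generator emulates the study design: groups (tick, vole) × (forest,
ecotone) with 228/73/177/92 samples, 126 genera, and mean per-sample
richness `E[packets per sample] × packet size + noise rate
= 1.5 × 8 + 1.4 = 13.4` genera (the observed study means were ≈ 13.4 per
carrier). Structure:

* **Packets.** Disjoint genus blocks of size `1 + Poisson(mean − 1)`
  (exact mean, minimum 1). Each sample draws 1–2 packets from its group's
  packet pool; all packet genera are present. This encodes the working
  hypothesis that microorganisms circulate together in packets, and gives
  community detection a recoverable planted partition (recovered exactly
  at zero noise).
* **Pools.** Each packet (and each free "noise" genus) is assigned to both
  biotopes with probability `biotope_overlap`, else to one at random, and
  independently to carriers via `carrier_overlap`. An overlap `o` implies
  an expected pool Sørensen of `2o/(1+o)`; the defaults 0.65 / 0.15 target
  the observed geometry of ≈ 0.77 same-carrier-across-biotope vs
  ≈ 0.24–0.28 between-carrier-within-biotope similarity. Assignments are
  redrawn (seeded rejection, capped at 1000 tries) until every sampled
  group holds enough packets, so overlap 0 yields exactly disjoint pools.
* **Reads.** Present genera draw `max(1, NegBin(mean = 600, dispersion =
  0.5))` reads — a present genus must be observable — giving per-sample
  totals of the order of the study's ≈ 8 000 reads with realistic
  overdispersion. The negative binomial is a modelling stand-in: no
  within-sample abundance distribution was available to fit.
* **Trees and traits.** Yule (pure-birth) trees supply tip sets matching
  the genus catalogue; λ-Brownian traits are drawn from
  `N(0, σ² C(λ))` via Cholesky (1e-12 jitter) for estimator-recovery
  tests (λ̂ within 0.1 of truth at λ ∈ {0, 1} on 200-tip trees over 50
  seeds).

What the synthetic data does **not** emulate: phylogenetic structure in
packet membership (genera join packets independently of the tree, so true
λ of prevalence is 0 — a generator that plants λ > 0 in presence patterns
would need a different presence model); PCR/chimera artifacts and
cross-contamination; correlation between read depth and richness; and the
real study's coexistence of high *pooled* between-carrier genus sharing
(62 %) with low within-biotope between-carrier Sørensen — the independent
carrier × biotope membership model ties these together, and the defaults
preserve the Sørensen geometry at the cost of understating pooled
sharing. Passing tests therefore certify the correctness of the graph,
phylogenetic and scoring machinery and the recoverability of planted
structure, not distributional realism of 16S read data.

## Determinism and degenerate inputs

Every stochastic component takes an explicit seed (NumPy `default_rng`);
the pipeline rerun with the same config is byte-identical in all TSV/JSON
outputs. Degenerate inputs fail loudly: empty strata, matrices with
non-integer or negative counts, duplicate sample ids, malformed Newick,
asymmetric distance matrices, star trees for λ, all-equal inputs to the
power-law fit, and single-community inputs to `pd_concentration` raise or
flag rather than returning silently arbitrary values.

## Problem sizes used in the checks

Oracle-equivalence checks run on instances small enough for exhaustive
enumeration (≤ 10 samples × 10 genera for co-occurrence; ≤ 8 nodes for
betweenness/clustering/modularity, where brute force enumerates all 4 140
partitions; ≤ 5 nodes for the PageRank linear solve; 16 tips for PD; 8
taxa for NJ). Recovery experiments use 200-tip trees × 50 replicates for
λ and n = 10 000 × 20 replicates for γ. The end-to-end pipeline runs on
the default 570-sample design in a few seconds.
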