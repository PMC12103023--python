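# Methods

## Model

`signedrole` treats a gene regulatory network as an undirected signed graph
G = (V, E⁺, E⁻).  Direction is deliberately ignored: the structural summary
used throughout is the signed degree d = [d⁺, d⁻], which has no in/out
split.  Directed input rows (u→v, v→u) with one sign collapse to a single
edge; opposite signs for the same pair are an error unless
`allow_conflicts=True`, in which case the pair contributes one unit to both
d⁺ and d⁻.  Self-loops are dropped (neighbourhood-based statistics assume
neighbour ≠ self) and isolated genes are dropped at ingestion — a gene with
no surviving connection has no measurable role.

### Structural dissimilarity

For genes u, v the cumulative dissimilarity is

- f₀(u,v) = EBED(dᵤ, dᵥ), with
  EBED(a, b) = exp √( ln²((a⁺+1)/(b⁺+1)) + ln²((a⁻+1)/(b⁻+1)) );
- f_k(u,v) = f_{k−1}(u,v) + DTW(EBED, R_k(u), R_k(v)) for k ≥ 1, where
  R_k(u) is the sorted sequence of signed degrees of the genes exactly k
  hops from u.

Numerical and combinatorial choices:

- **Logarithm base.**  Natural log, with exp as its inverse.  This yields
  the clean identity EBED([a,0],[b,0]) = max(a+1, b+1)/min(a+1, b+1) and
  makes EBED ≥ 1 with equality iff the degrees coincide.  A `minus_one`
  switch subtracts 1 (so identical degrees give 0) for sensitivity
  analysis; it is off by default and nothing downstream depends on it.
- **Hops** are measured on the unsigned union of E⁺ and E⁻: sign affects
  cost, not reachability.
- **Ring order.**  "Sorted" is implemented as ascending by
  (d⁺+d⁻, d⁺, d⁻): total-degree-major ordering aligns hubs with hubs under
  DTW, which is the alignment that matters in scale-free graphs.
- **DTW** is the exact O(|s||t|) dynamic program with steps
  (1,0), (0,1), (1,1) and sum aggregation — no banding or coarsening.  The
  numba-compiled kernel makes the exact computation affordable for the
  complete all-pairs set up to the 3000-node guard, past which the run
  aborts with guidance rather than silently approximating.
- **Unequal eccentricities.**  If exactly one of R_k(u), R_k(v) is empty,
  DTW is undefined; the pair's comparison truncates at k−1 and the pair is
  simply absent from deeper layers.  Truncated values are stored as NaN.

### Multilayer context graph and walks

Layer k (k = 0..k_max) links every pair with f_k defined, weight
w_k = e^{−f_k} ∈ (0, e^{−1}] (the bound follows from EBED ≥ 1).  Γ_k(u)
counts u's layer-k links with weight strictly above the *layer-wide* mean
link weight (the mean over all links of the layer, not just u's own — the
literal reading of the definition, and the only implemented one).  Upward
inter-layer weight ln(Γ_k(u)+e) ≥ 1; downward weight 1.  Because the upward
pull grows with the number of strong same-layer partners, walks are drawn
deeper exactly when the current horizon still finds many similar genes.

Walks start at layer 0 and emit a token for the start node and for every
intra-layer step; layer switches emit nothing (tokens must be genes, not
(gene, layer) pairs, for the Skip-Gram vocabulary to equal the gene set).
Intra-layer probability mass is q = 0.8, inter-layer 1−q, split between
up/down proportionally to their weights; at the boundary layers the whole
inter-layer mass goes in the only available direction.  A gene with no
intra-layer links at some layer (possible after truncation) moves only
between layers, with a warning.  A stall guard (64 consecutive tokenless
steps) terminates pathological walks early; ordinary walks have exactly
`walk_length` tokens.

### Embedding

Skip-Gram with negative sampling, implemented in-repo (numba kernel):
dynamic window, unigram^0.75 noise distribution, linear learning-rate decay
from 0.025, single-threaded with a fixed seed — training is exactly
reproducible, which the test suite asserts byte-for-byte.  Defaults:
walks_per_node 10, walk_length 80, window 5, dim 128 (2 for visualisation,
16 in the recovery experiments below), negative 5, epochs 5.  These follow
common node-embedding practice; all are exposed in the API and CLI.

### Comparative statistics

For C contexts merged as `gene::context`, a gene present in every context
gets cen_u = mean of its C vectors, distances d_u^c = ‖emb_u^c − cen_u‖₂,
mean d̄_u, and population SD σ_u (divide by C, not C−1 — the population
form is used deliberately).  For C = 2 the two centroid distances are each
half the pair distance, so ranking by d̄_u equals ranking by pair distance.
Flagging is **rank-based**: ceil(0.10·N) genes for C = 2; for C > 2,
ceil(0.05·N) by mean distance plus genes with σ_u above a threshold
(default 0.4, or "auto" = the 95th percentile of σ).  Rank-based selection
keeps the flag count deterministic under ties (ties break by distance
descending, then gene id).  Genes missing from any context are excluded
from DTG analysis — the method can only compare genes that retain at least
one connection everywhere.

Module stability: Louvain on the anchor context's unsigned union graph
(standard modularity is undefined with negative weights; signs are ignored
for community detection only), modules under 10 genes excluded.  Per
module: mean cross-context embedding shift of the genes shared with the
other context, and NA% = 1 − |shared|/|module|.

Topology metrics (8): degree centrality d±/(n−1); clustering coefficient
and degree assortativity on each sign-restricted subgraph (the network-level
assortativity value is attributed to every node carrying at least one edge
of that sign, NaN elsewhere); betweenness and eigenvector centrality on the
unsigned union (configurable to pos/neg).  K-means profiling (K = 10,
k-means++, 10 restarts, seeded) reports per-cluster metric means plus a
per-metric min-max scaled copy for heatmaps.

### GRN construction from counts

Highly variable genes are ranked by variance of log1p counts after
library-size normalisation to the median cell depth — a deliberately simple,
deterministic dispersion statistic (ties break by gene name).  All-pairs
Spearman ρ is computed as Pearson correlation of average ranks; two-sided
p-values use the t approximation, with an exact permutation p-value for
≤ 10 cells.  Defaults: 2000 HVGs, p < 0.01, |ρ| ≥ 0.3, no multiple-testing
correction on edges (a raw-p rule; an FDR variant would be a one-line
change), then the top 2000 edges by |ρ| with deterministic tie-breaking.
The |ρ| floor of 0.3 is a stand-in where no canonical value exists; it is
configurable and logged.

## What the synthetic generators emulate

- `make_sim_tree`: a fixed 31-gene tree with a root hub, five intermediate
  hubs, leaf fans, and two leaves attached by single negative edges — the
  minimal network in which sign-aware role equivalence (the two negative
  leaves) separates role embedding from proximity embedding.  The exact
  wiring is this package's own construction; only the role classes (hub /
  fan / negative-leaf twins) and the 31-gene size are meaningful.
- `make_scale_free`: Barabási–Albert preferential attachment (exactly
  m(n−m) edges) with i.i.d. Bernoulli negative signs, default
  neg_fraction 0.3 — GRN-like heavy-tailed degrees with a realistic
  minority of repressing edges.
- `make_twins`: planted automorphic leaf pairs (two same-sign leaves on one
  anchor) — ground-truth structural twins.
- `make_iso_pair`: a relabelled isomorphic copy merged as a second context —
  ground truth for cross-context alignment.
- `make_perturbed_pair` / `make_multi_context`: targeted rewiring of k
  selected genes: total degree preserved (density roughly constant),
  neighbours redrawn among non-selected genes, d⁺ shifted by 1–2 so the
  signed degree moves ≥ 2 in L1.  Multi-context runs plant two truth
  classes: genes rewired in *every* context (high mean distance) and in
  *exactly one* context (high SD).

These fixtures capture degree heavy-tails, sign mixture, and planted role
structure.  They do **not** emulate dropout, measurement noise in edge
inference, correlated edge errors between states, or biological module
structure beyond what preferential attachment induces — so passing recovery
tests demonstrates the method's behaviour under clean structural ground
truth, not performance on inferred single-cell GRNs.

## Experiment configurations

Problem sizes were chosen so the complete test suite and the acceptance
script each run in minutes on one CPU:

- Twin recovery: n = 150 with 10 planted pairs, k_max 3, dim 16, 5 seeds.
- Isomorphic alignment: n = 100 per context, k_max 2, dim 16, 5 seeds.
- Rewired-gene recovery: n = 300 (600 merged nodes), 30 rewired genes,
  **k_max 1**, walks_per_node 20, epochs 10, dim 16, 5 seeds.  The shallow
  horizon is a scientific choice, not a shortcut: the rewiring perturbation
  is local (hop 0–1), while in small-world preferential-attachment graphs
  hop-2+ rings cover large fractions of the network and are nearly
  identical across genes, so deeper layers add alignment cost that is
  common to all genes and dilutes the contrast between rewired and stable
  genes.  Per-experiment horizon tuning is the intended usage pattern; the
  library default stays k_max 3.

## Known limitations

- All-pairs DTW is O(n²·r²) in nodes and ring sizes; the 3000-node guard is
  a hard stop, and no struc2vec-style compression (degree-bucketing, OPT
  approximations) is provided.
- Louvain and K-means are seeded but remain heuristic optimisers; module
  boundaries can shift between networkx versions.
- The Spearman GRN builder is a baseline co-expression method; it does not
  model dropout or confounding and is not a substitute for dedicated GRN
  inference.
- Multi-worker (parallel) Skip-Gram training would be faster but
  non-deterministic; only the reproducible single-worker path is shipped.
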