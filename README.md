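# signedrole

Role-based embedding of **signed gene regulatory networks** (GRNs), plus the
comparative statistics it enables: identification of **differentially
topological genes (DTGs)** across cell types or states, and **stability
scoring of gene modules** between two cellular states.

## The problem

A GRN is a graph G = (V, E⁺, E⁻) whose nodes are genes and whose edges are
activating (+) or repressing (−) interactions.  Most network embeddings place
*adjacent* genes together.  For comparative questions — "did this gene's
regulatory role change between cell states?" — adjacency is the wrong notion:
two hub repressors in different networks should embed together even though
they share no neighbours.  `signedrole` embeds genes by their *structural
role*, with edge signs as first-class information.

## The method

1. **Signed degree.**  Each gene is summarised as d = [d⁺, d⁻], its counts of
   positive and negative edges.
2. **EBED.**  Two signed degrees are compared with the exponential biased
   Euclidean distance

   EBED(dᵤ, dᵥ) = exp √( ln²((dᵤ⁺+1)/(dᵥ⁺+1)) + ln²((dᵤ⁻+1)/(dᵥ⁻+1)) ),

   a log-ratio distance suited to the power-law degree spread of GRNs;
   identical degrees give exactly 1.
3. **Hop-k rings and DTW.**  R_k(u) is the sorted signed-degree sequence of
   the genes exactly k hops from u.  Rings of two genes are aligned with
   dynamic time warping (EBED as local cost), giving D_k(u,v), and
   accumulated into f_k(u,v) = f_{k−1}(u,v) + D_k(u,v) with
   f₀ = EBED(dᵤ, dᵥ).  Lower f_k ⇒ more similar roles.
4. **Multilayer context graph.**  Layer k links every gene pair with weight
   e^{−f_k}; each gene's copies in adjacent layers are joined by a directed
   upward weight ln(Γ_k(u) + e) (Γ_k counts u's above-average links in layer
   k) and a downward weight 1.
5. **Biased walks + Skip-Gram.**  Random walks spend probability q = 0.8 on
   intra-layer moves (emitting gene tokens) and 1−q on layer switches
   (emitting nothing); Skip-Gram with negative sampling turns the walk corpus
   into embeddings in which *structurally similar genes are close*.
6. **Comparative statistics.**  Networks from C contexts are merged (node ids
   `gene::context`) and embedded jointly.  Per gene: the centroid of its C
   vectors, the per-context centroid distances d_u^c, their mean and
   population SD.  DTGs = top 10% by distance (C = 2), or top 5% by mean
   distance plus genes above an SD threshold (C > 2).  Module stability =
   Louvain modules (≥ 10 genes) of an anchor state scored by mean embedding
   shift of shared genes and NA%, the fraction of genes missing from the
   other state.

Signed GRNs can be read from edge lists or built from a gene×cell count
matrix (2000 highly variable genes → all-pairs Spearman ρ with p < 0.01 and
|ρ| ≥ 0.3 → sign from the sign of ρ → top 2000 edges by |ρ|).

## Worked example

```python
import numpy as np
import signedrole as sr
from signedrole.simulate import make_sim_tree

net = sr.simulate.make_sim_tree()          # 31-gene tree, 2 negative leaves
emb = sr.embed_networks(net, k_max=3, dim=2, seed=1)

print(emb.distance("S9", "S15"))           # the two negative-edge leaves
dm = emb.pairwise_distances()
print(np.median(dm[np.triu_indices(len(emb), 1)]))
```

Output:

```
0.019
1.447
```

S9 and S15 hang from different hubs by a single repressing edge — the same
structural role, four hops apart.  Their embedding distance (0.019) is ~75×
smaller than the median gene-gene distance (1.447): the embedding groups
genes by role, not by proximity.  The scripts in `examples/` walk through
the other capabilities (GRN construction from counts, DTG calling between
two states, module stability), each printing and explaining its numbers.

A thin CLI mirrors the library:

```bash
signedrole simulate --kind perturbed_pair --n 300 --k 30 --seed 7 --out-dir fx/
printf "c1\tfx/c1.tsv\nc2\tfx/c2.tsv\n" > fx/nets.txt
signedrole embed --manifest fx/nets.txt --kmax 1 --dim 16 --seed 7 --out fx/emb.txt
signedrole dtg --emb fx/emb.txt --manifest fx/nets.txt --mode pair --out fx/dtg.tsv
```

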