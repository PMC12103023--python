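"""Find differentially topological genes (DTGs) between two cell states.

Thirty genes of a 300-gene scale-free GRN are structurally rewired in the
second state.  Both states are embedded into one role space and each gene's
cross-state embedding distance ranks how much its role changed; the top 10%
are flagged as DTGs.
"""

import numpy as np

import signedrole as sr
from signedrole.simulate import make_perturbed_pair, make_scale_free

seed = 10
base = make_scale_free(300, 2, neg_fraction=0.3, seed=seed)
state_a, state_b, rewired = make_perturbed_pair(base, k_genes=30, seed=seed)
merged = sr.merge_networks([state_a, state_b])

emb = sr.embed_networks(merged, k_max=1, walks_per_node=20, epochs=10,
                        dim=16, seed=seed)
report = sr.dtg_report(emb, merged)

flagged = report[report["flag"] == "dtg_mean"]
recovered = sum(g in rewired for g in flagged.index)
print(f"{len(report)} genes compared across the two states")
print(f"{len(flagged)} flagged as DTGs (top 10% by cross-state distance)")
print(f"{recovered} of the {len(rewired)} truly rewired genes are among them")

from sklearn.metrics import roc_auc_score
labels = np.array([g in rewired for g in report.index])
auc = roc_auc_score(labels, report["mean_distance"].values)
print(f"distance-ranking AUC vs planted truth: {auc:.3f}")
print("-> genes whose wiring changed rank near the top; stable genes sink")
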