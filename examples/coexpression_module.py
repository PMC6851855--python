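"""Recover a planted co-expression module around a focal gene triad.

Simulates a TPM matrix (5000 genes x 209 samples) in which 50 genes,
including the three focal homoeologs, follow a shared latent factor; then
normalizes, selects variable genes and builds the local network: genes in
the top 1% of correlation with any focal homoeolog that also exceed
|PCC| > 0.6.
"""

from triadkit import coexpression, simulate

sim = simulate.gen_expression_matrix(simulate.SimConfig(seed=7))
norm = coexpression.quantile_normalize_log2(sim.tpm)

members, edges = coexpression.build_local_network(norm, sim.focal_genes)

truth = set(sim.truth[sim.truth.module_member].gene_id) - set(sim.focal_genes)
recall = len(members & truth) / len(truth)
precision = len(members & truth) / len(members)

print(f"local network members: {len(members)}")
print(f"recall vs planted module: {recall:.2f}")
print(f"precision vs planted module: {precision:.2f}")
print(edges.head(5).to_string(index=False))

# Each edge links a focal homoeolog to a member gene with its Pearson
# correlation; recall/precision near 1.0 show the conjunctive rule (top 1%
# AND |PCC| > 0.6) isolates exactly the genes generated from the shared
# latent factor.
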