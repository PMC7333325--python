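"""Differential-expression concordance: quasi-UMIs vs raw reads.

Simulates a two-group experiment (10% of genes differentially expressed),
computes per-gene Fisher exact tests on pseudobulk tables for the UMI
ground truth, the quasi-UMIs and the raw reads, and reports Manhattan,
Kendall and Jaccard distances of each normalization's DE results to the
truth. Smaller is more concordant on all three metrics.
"""

import numpy as np

import quasiumi as q

sim = q.simulate_umi(
    q.SimulationConfig(n_genes=800, n_cells=50, seed=7, de=q.DEConfig(frac_de=0.1, lfc=1.0))
)
reads = q.amplify_reads(sim.umi, amp_mean=50.0, amp_sd_log=1.0, seed=8)
qumi = q.quminorm_matrix(reads, shape=2.0)

keep = np.diff(sim.umi.values.tocsr().indptr) > 0  # genes expressed somewhere


def de_pvalues(matrix):
    sub = q.CountMatrix(
        matrix.values.tocsr()[keep].tocsc(), matrix.gene_ids[keep],
        matrix.cell_ids, matrix.layer,
    )
    return q.fisher_de(sub, sim.groups)


p_truth = de_pvalues(sim.umi)
print(f"{'':>11}  manhattan  kendall  jaccard  n_significant")
for name, m in [("quasi-UMIs", qumi), ("raw reads", reads)]:
    r = q.concordance(p_truth, de_pvalues(m), alpha=0.05)
    print(f"{name:>11}  {r.manhattan:9.2f}  {r.kendall:7.4f}  {r.jaccard:7.4f}  "
          f"{r.n_sig_other:6d} (truth: {r.n_sig_ref})")
print()
print("Raw reads inflate counts ~50x, so Fisher tests on them overstate "
      "significance; quasi-UMIs restore p-values and gene sets close to the "
      "UMI ground truth.")
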