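"""Benchmark quasi-UMIs against ground-truth UMI counts.

Simulates matched UMI and read-count matrices, normalizes the reads to
quasi-UMIs, and compares per-cell log-space Euclidean distances to the UMI
truth (zeros omitted; all methods preserve sparsity). Quasi-UMIs should sit
far closer to the truth than raw reads. Gene-level means and coefficients
of variation are compared the same way.
"""

import numpy as np

import quasiumi as q

sim = q.simulate_umi(q.SimulationConfig(n_genes=2000, n_cells=40, seed=5))
reads = q.amplify_reads(sim.umi, amp_mean=50.0, amp_sd_log=1.0, seed=6)
qumi = q.quminorm_matrix(reads, shape=2.0)

for name, m in [("raw reads", reads), ("quasi-UMIs", qumi)]:
    d = q.log_distance(m, sim.umi)["distance"]
    print(f"{name:>11}: median per-cell log distance to UMI truth = {d.median():7.3f}")

stats_umi = q.gene_stats(sim.umi)
for name, m in [("raw reads", reads), ("quasi-UMIs", qumi)]:
    stats = q.gene_stats(m)
    err = np.nanmedian(np.abs(np.log(stats["mean"] + 1) - np.log(stats_umi["mean"] + 1)))
    print(f"{name:>11}: median |log mean expression error| = {err:.3f}")
print()
print("Smaller distances mean the normalization recovers the molecule-scale "
      "expression profile that PCR amplification distorted.")
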