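"""Differential expression with biological replicates.

Simulates over-dispersed (Gamma-Poisson) counts with 3 replicates per
condition, runs the hierarchical pipeline (within-condition quantile
normalisation, replicate-moment dispersion, marginal posteriors), and prints
what it found.  A second run on an exact null shows the specificity control.
"""

import numpy as np

from ebdiff import make_synthetic_prior, run_de_replicates, simulate_dataset3

prior = make_synthetic_prior(seed=3)
matrix, truth = simulate_dataset3(
    prior, theta=0.5, n_genes=1_000, n_de=100, fold=4.0, n_reps=3,
    libsize_range=(150_000, 400_000), seed=3,
)
res = run_de_replicates(matrix)
called = res[res["fdr"] <= 0.1]
hits = truth.genes.loc[called["feature_id"], "is_de"].sum()
print(f"dispersion estimates: theta_A = {res['theta_a'][0]:.3f}, "
      f"theta_B = {res['theta_b'][0]:.3f} (count-scale)")
print(f"genes called at FDR 0.1: {len(called)}, of which truly DE: {hits}")

null_matrix, _ = simulate_dataset3(
    prior, theta=0.5, n_genes=1_000, n_de=0, n_reps=2,
    libsize_range=(300_000, 500_000), seed=4,
)
null_res = run_de_replicates(null_matrix)
print(f"null control (no DE genes): {(null_res['fdr'] <= 0.1).sum()} calls at FDR 0.1")
print("\nThe dispersion scale inflates each replicate's variance to")
print("lambda * (1 + theta); the null run shows the FDR control holds.")
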