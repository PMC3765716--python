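"""Fit a nonparametric expression prior and shrink low counts.

Draws one sample of counts from a known two-point mixture, fits the discrete
prior by NPMLE on the zero-truncated mixture, and prints empirical-Bayes
expression estimates — note the finite, positive estimate for a gene with
zero observed reads.
"""

import numpy as np

from ebdiff import MixingDistribution, eb_estimate, fit_prior, mixture_pmf

rng = np.random.default_rng(0)
true = MixingDistribution([2.0, 50.0], [0.7, 0.3])
lam = rng.choice(true.support, 10_000, p=true.weights)
counts = rng.poisson(lam)

g_hat = fit_prior(counts)
xs = np.arange(0, 400)
tv = 0.5 * np.abs(mixture_pmf(g_hat, xs) - mixture_pmf(true, xs)).sum()

print(f"fitted prior: {len(g_hat)} support points, "
      f"mean {g_hat.mean():.2f} (true {true.mean():.2f})")
print(f"total-variation distance of count marginals: {tv:.4f}")
print("\ncount  EB expression estimate")
for x in (0, 1, 2, 5, 20, 50, 100):
    print(f"{x:5d}  {eb_estimate(g_hat, x):10.3f}")
print("\nA zero count shrinks to the prior's low-expression mass instead of 0;")
print("a count of 20, between the components, is attributed to the high one.")
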