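"""Test whether a set of origins is enriched near centromeres.

We build a stand-in genome of 213 origins, 16 of them within 10 kb of a
centromere, and label 31 origins such that 11 of the labeled set are
centromere-proximal (the configuration observed for wild-type-specific
origins). A permutation test draws 10,000 random 31-origin subsets and asks
how often the proximal count reaches the observed one; the exact
hypergeometric tail provides the closed-form answer for comparison.
"""

from oriquant.enrichment import count_proximal, hypergeom_tail, permutation_test
from oriquant.simulate import simulate_enrichment_scenario

annotation, labeled = simulate_enrichment_scenario(
    N=213, K=16, n_labeled=31, enriched=True, seed=2
)
x_obs = count_proximal(labeled, annotation, window=10_000)
print(f"labeled origins: {len(labeled)}, of which {x_obs} within 10 kb of a centromere")

result = permutation_test(
    annotation, sorted(labeled), window=10_000, trials=10_000, seed=2
)
print(result.summary())
print(f"conservative companion estimate (k+1)/(T+1): {result.p_corrected:.2e}")

p_exact = hypergeom_tail(result.task.N, result.task.K, result.task.n, result.task.x_obs)
print(f"exact hypergeometric tail P(X >= {result.task.x_obs}): {p_exact:.2e}")
print("\nZero exceedances in 10,000 trials gives the reported bound p < 1e-4;")
print("the exact tail shows the true null probability is far smaller still.")
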