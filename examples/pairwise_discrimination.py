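"""Discriminating two iris classes modeled as AR Gaussian processes.

Builds two random stable AR(3) classes, scores queries from the first class
with the asymptotic (Whittle) log-likelihood ratio and the exact Gaussian
likelihood, and compares both with the spectral relative entropy — the
expected statistic under the true class and the package's distance metric.
"""

import numpy as np

from iriscap import (
    ar_psd,
    exact_gaussian_llr,
    pairwise_error_mc,
    random_stable_ar,
    relative_entropy,
    simulate_ar,
    whittle_llr,
)

n = 512
class_m = random_stable_ar(3, seed=2, max_pole_radius=0.8)
class_k = random_stable_ar(3, seed=9, max_pole_radius=0.8)
s_m, s_k = ar_psd(class_m, n), ar_psd(class_k, n)

queries = list(simulate_ar(class_m, n, 100, seed=5))
stat = whittle_llr(s_m, s_k, queries, class_m="m", class_k="k")
exact = exact_gaussian_llr(class_m, class_k, queries)
d = relative_entropy(s_m, s_k)

print(f"Whittle LLR (100 queries from class m): {stat.lambda_total:10.2f}")
print(f"Exact Gaussian LLR (same queries):      {exact:10.2f}")
print(f"Relative entropy d(m, k):               {d:10.2f}")

errors = pairwise_error_mc(class_m, class_k, n_images=1, n=n, reps=2000, seed=11)
print(f"MC error P(k|m) = {errors['p_k_given_m']:.4f}, "
      f"P(m|k) = {errors['p_m_given_k']:.4f}")
print(
    "\nA large positive LLR correctly favors class m; the Whittle and exact"
    " statistics agree to a few percent at this length, and the LLR mean"
    " tracks the relative entropy.  Well-separated spectra (large d) drive"
    " the pairwise error rates toward zero."
)
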