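"""Ground-truth recovery: can the sampler find the true sparse effects?

Simulates sequences whose λmax is generated by 10 truly nonzero coefficients
out of 432, refits with the Gibbs sampler, and compares posterior means on
the true support with the generating values.
"""

import numpy as np

import rhodoscreen as rs

ds = rs.simulate_dataset(
    rs.SimulationSpec(n_train=300, n_candidates=5, n_nonzero_coefficients=10,
                      noise_sd=5.0, seed=11))
post = rs.fit_blasso(
    ds.train_encoded, rs.BlassoConfig(n_samples=2000, burn_in=500, seed=11),
    standardizer=ds.standardizer)

truth = ds.ground_truth
sup = list(truth.support)
bm = post.beta.mean(axis=0)
r = np.corrcoef(bm[sup], truth.true_beta[sup])[0, 1]
nulls = np.setdiff1d(np.arange(post.n_features), sup)

print(f"true support size: {len(sup)} / {post.n_features} coefficients")
print(f"Pearson r (posterior mean vs truth, support): {r:.3f}")
print(f"sign agreement on support: "
      f"{np.mean(np.sign(bm[sup]) == np.sign(truth.true_beta[sup])):.0%}")
print(f"median |posterior mean| off support: {np.median(np.abs(bm[nulls])):.3f} "
      f"(true effects are ±{ds.spec.coefficient_scale:.0f} nm)")

# High support correlation with near-zero off-support estimates shows the
# Laplace prior recovering a sparse color-tuning signal from 300 sequences
# even though coefficients outnumber them.
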