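"""Reduce a large noisy phenotype block to a few reproducible components.

High-dimensional connectivity phenotypes are individually too noisy for
association testing. The reduction is SVD to a small basis followed by ICA on
the phenotype-weight vectors; the (SVD, ICA) dimension pair is selected by
split-half reproducibility across random subject halves, keeping only
dimensions whose components reproduce at |r| > 0.9.

Run:  python examples/05_connectivity_reduction.py
"""

import numpy as np

import mtgwas as m

# --- a phenotype block with 4 reproducible modes buried in noise -------------
rng = np.random.default_rng(90)
n, p, k = 1200, 60, 4
weights = rng.laplace(size=(k, p)) ** 3           # sparse, heavy-tailed
weights /= np.linalg.norm(weights, axis=1, keepdims=True)
scores = rng.standard_normal((n, k))
Y = scores @ weights + 0.4 * rng.standard_normal((n, p))

# --- split-half reproducibility for one candidate dimension ------------------
rep = m.split_half_reproducibility(Y, svd_dim=4, ica_dim=4,
                                   n_splits=5, seed=1)
print("reproducibility at (svd=4, ica=4):", np.round(rep, 3))

# --- select dimensions automatically and refit on all subjects ---------------
red = m.ica_reduce(Y, candidate_svd_dims=[3, 4, 6, 10],
                   candidate_ica_dims=[2, 3, 4, 6],
                   r_threshold=0.9, n_splits=5, seed=2)
print(f"\nselected svd_dim={red.svd_dim}, ica_dim={red.ica_dim}")
print("component reproducibility:", np.round(red.reproducibility, 3))

# --- how well do the components match the planted modes? ---------------------
corr = np.abs(np.corrcoef(np.vstack([red.weight_vectors, weights]))[:k, k:])
print("recovery |r| per planted mode:", np.round(corr.max(axis=0), 3))

# the subject scores are new, denoised phenotypes ready for prepare/gwas
print(f"\nreduced phenotypes: {red.subject_scores.shape} "
      f"(from {Y.shape}), score correlations with planted scores:")
sc = np.abs(np.corrcoef(np.vstack([red.subject_scores.T, scores.T]))[:k, k:])
print(np.round(sc.max(axis=0), 3))
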