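"""Build the imaging confound matrix and prepare phenotypes for association.

The confound recipe expands a handful of acquisition variables into 53
columns: sex, age/sex interactions in raw and quantile-normalized form, head
motion (rest and task) with squares, head size, four position variables with
squares, and ten data-driven scanner-drift components estimated from the
phenotypes themselves. Phenotypes are then quantile normalized and
residualized on the confounds (plus genetic principal components) before any
genetic analysis.

Run:  python examples/02_confounds_and_preparation.py
"""

import numpy as np

import mtgwas as m

n = 500
cov = m.simulate_covariates(n, seed=30)
G = m.simulate_genotypes(n, 600, seed=31)
truth = m.random_truth(n_phenotypes=20, n_variants=600, seed=32)
Y = m.simulate_phenotypes(G, np.eye(n), truth)

# --- scanner drift components from the phenotype block itself --------------
# slow site/scanner drift shows up as shared temporal structure; it is
# estimated by outlier-limiting, low-rank completion, smoothing against scan
# date, then PCA
drift = m.drift_confounds(Y.values, cov.scan_date, n_components=10, seed=33)
print(f"drift components: {drift.shape}, mutually orthogonal:",
      np.allclose(drift.T @ drift, np.eye(10), atol=1e-8))

# --- the full 53-column confound matrix -------------------------------------
C = m.assemble_confounds(cov, drift=drift)
print(f"confound matrix: {C.values.shape[0]} samples x {C.n_columns} columns")
print("first columns:", C.names[:6])
print("max |column mean| (all demeaned):",
      f"{np.abs(C.values.mean(axis=0)).max():.2e}")
s = np.linalg.svd(C.values, compute_uv=False)
print(f"condition number {s[0] / s[-1]:.1f} (full rank)")

# --- prepare phenotypes: quantile normalize + residualize -------------------
pcs = m.genotype_pcs(G, n_pcs=10)
prepared = m.prepare_phenotypes(Y, C, pcs=pcs)
r = prepared.values[:, 0]
print("\nprepared phenotype 0:")
print(f"  mean {np.nanmean(r):+.2e}, sd {np.nanstd(r):.3f}")
corr = max(abs(np.corrcoef(r, C.values[:, j])[0, 1])
           for j in range(C.n_columns))
print(f"  max |corr| with any confound column: {corr:.2e}")
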