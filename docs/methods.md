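# Methods

This note documents the statistical model, the algorithms, the numerical
choices, and the validation conditions behind `mtgwas`.

## 1. Model

For N samples and P traits the phenotype matrix follows

```
Y = G·alpha + U + eps,    U ~ MN(0, K, B),    eps ~ MN(0, I_N, E)
```

where `MN(0, R, C)` is the matrix-normal distribution with row covariance R
and column covariance C. K is the realized relationship matrix (RRM) over
samples; B and E are the P×P genetic and residual trait covariances. Derived
quantities:

- SNP heritability of trait p: `h²_p = B_pp / (B_pp + E_pp)`
- genetic correlation of traits i, j: `r_g = B_ij / sqrt(B_ii · B_jj)`,
  clipped to [−1, 1]

### Kinship

`compute_rrm` builds `K = X Xᵀ / M` over standardized dosages
`x_std = (x − 2p) / sqrt(2p(1−p))`, dropping monomorphic variants.
`loco_exclude` removes one chromosome (LOCO) so a tested variant's own
chromosome does not contribute to the relatedness it is conditioned on.
`KinshipMatrix` caches its eigendecomposition `K = Q Λ Qᵀ` (negative
eigenvalues from round-off are clipped to zero); rotating rows by Qᵀ makes
them independent with covariance `λ_n B + E`.

## 2. EM estimation of (B, E)

`fit_matrix_normal` treats U as latent. Each iteration works in a joint basis
`T = Wᵀ L⁻¹` (L the Cholesky factor of E, W the eigenvectors of
`L⁻¹ B L⁻ᵀ`), in which `T E Tᵀ = I` and `T B Tᵀ = diag(d)`. The E-step is
then elementwise over the N×P rotated data — each entry has scalar posterior
mean and variance with weight `λ_n d_p / (λ_n d_p + 1)` — and one iteration
costs O(N·P²) after the one-off eigendecomposition of K.

Details that matter:

- **Initialization**: B = E = S/2 with S the sample covariance of the rotated
  data.
- **B update support**: the B M-step averages posterior second moments only
  over rows with `λ_n > 0`; rows in the null space of K carry no information
  about B (important for rank-deficient RRMs, where N − rank(K) rows would
  otherwise bias B toward zero).
- **PSD projection**: after each M-step, B and E are projected onto the
  positive-semidefinite cone by eigenvalue clipping. A tiny jitter is added
  when E must be Cholesky-factored but has a null direction.
- **Convergence**: relative log-likelihood change below `tol` (default 1e-6,
  `max_iter` 1000). The log-likelihood uses
  `log det(λ_n B + E) = Σ_p log(λ_n d_p + 1) + log det E` and is checked to be
  non-decreasing in tests. Near the optimum EM is slow: agreement with a
  grid-search ML oracle to ±0.005 in h² requires `tol=1e-10`; the default is
  kept at 1e-6 because parameter-level accuracy of ~1e-3 is already reached
  there at a fraction of the iterations.

### Heritability standard errors

`heritability` computes, per trait, the observed Fisher information of the
marginal single-trait likelihood in `(B_pp, E_pp)` by central finite
differences, then applies the delta method to `h² = B/(B+E)`. For P > 1 this
is a per-trait marginal approximation (it ignores cross-trait information);
coverage of the 95% CI is validated empirically (see §6). Significance is a
one-sided test of `B_pp = 0` at 5%.

### Multi-trait association test

`multi_trait_scan` tests each variant jointly across the P traits with a
generalized-least-squares Wald statistic computed in the joint basis: with
per-row, per-component weights `w_np = 1/(λ_n d_p + 1)`,

```
chi² = Σ_p ( Σ_n g̃_n z̃_np w_np )² / ( Σ_n g̃²_n w_np )
```

which is chi-square with P degrees of freedom under the null. Effect sizes
are mapped back from the joint basis by `alpha = alpha_z · T_inv ᵀ`. The null
(B, E) fit is estimated once per LOCO kinship and reused across that
chromosome's variants.

## 3. Mass univariate engine

`run_mass_gwas` runs simple linear regression of every phenotype on every
variant dosage, blockwise over variants with matrix products, grouping
phenotypes that share a missingness pattern so each group uses complete
cases. P-values come from the t distribution with n−2 degrees of freedom,
computed in log space (`−log10 P = −(ln 2 + logsf(|t|))/ln 10`) and capped at
350 so exact linear relations do not overflow. Zero-variance dosages within
the used subset are flagged, not tested.

Variant QC (`variant_qc`) filters on MAF (default > 0.001), imputation INFO
(default ≥ 0.3), and a 1-df chi-square Hardy–Weinberg test on hard calls
(default P ≥ 1e-7).

## 4. Confounds and phenotype preparation

`assemble_confounds` produces 53 columns from the acquisition variables: sex;
age, age², age×sex, age²×sex in both raw and quantile-normalized form; two
head-motion variables with squares; head size; four position variables with
squares; and ten drift components. Continuous variables are demeaned before
powers and interactions are formed; missing entries become 0 after the final
demeaning; outliers beyond 5 median absolute deviations are removed first.
`predicted_column_count` gives the count for other variable configurations.

`drift_confounds` estimates slow scanner drift from the phenotype block:
5×MAD outlier limiting → low-rank soft-impute completion (rank chosen by
held-out cross-validation) → least-squares cubic B-spline smoothing against
scan date with interior knots every `smoothing_scale` days (default 90,
fitted to per-date means so drift is a pure function of date and the output
is permutation-equivariant) → PCA, returning the top 10 unit-norm components.

`prepare_phenotypes` quantile normalizes each phenotype
(`Φ⁻¹(rank/(n+1))`, average ranks) and residualizes it on the confounds plus
optional genetic PCs using complete cases per phenotype; phenotypes with too
few samples beyond the regressor count are skipped with a warning.

## 5. Connectivity reduction

`fit_reduction` takes SVD to `svd_dim`, then runs FastICA **on the phenotype
loadings** `(s·Vt)ᵀ` — independence is sought over phenotype-weight vectors,
not subject scores, because reproducible connectivity modes are sparse in
phenotype space while subject scores are approximately Gaussian. Components
are returned with unit-norm weight vectors, canonical sign (largest-|weight|
entry positive), ordered by subject-score variance; FastICA restarts up to 5
times on non-convergence.

`split_half_reproducibility` fits the reduction on random subject halves and
scores components by greedy |correlation| matching of weight vectors
(descending match quality); `ica_reduce` grids over candidate (svd, ica)
dimension pairs and keeps the pair maximizing the number of components with
mean split-half |r| above the threshold (default 0.9), breaking ties toward
smaller dimensions. If no component reproduces, an empty reduction with the
full diagnostics table is returned rather than an error.

Validation fixtures therefore plant **heavy-tailed weight vectors**
(cubed-Laplace draws, normalized) mixed by Gaussian subject scores. Dense
heavy-tailed draws occasionally produce two planted "independent" vectors
correlated at ~0.4, which no estimator can fully separate; where the fixture
must hold for arbitrary seeds (the acceptance script) the planted vectors get
disjoint phenotype supports so they are uncorrelated by construction.

## 6. Multiplicity, loci, replication

- `thresholds(n_phenotypes, n_groups)`: study-wide −log10 P threshold
  `7.5 + round(log10(n_phenotypes), 1)` (e.g. 11.0 for 3,144 phenotypes);
  multi-trait threshold `round(7.5 + log10(n_groups), 2)` (8.86 for 23);
  PheWAS threshold `floor(−log10(0.05/n_phenotypes)·100)/100` (4.79).
- `prune_leads`: greedy clumping — repeatedly take the strongest remaining
  association above threshold and remove everything on the same chromosome
  within 0.25 cM. Validated against an exhaustive re-scan oracle on random
  instances.
- `cluster_leads`: single-linkage clustering of leads per chromosome with the
  same window, plus manual merge/split curation directives.
- `assess_replication`: nominal (P < 0.05), BH FDR at q = 0.05, expected
  null count `round(0.05·n)` (21 for 427 leads), and sign concordance.

## 7. Synthetic data generator

`simulate_genotypes` draws haplotypes from a latent Gaussian AR(1) process
thresholded at `Φ⁻¹(f)` per variant, giving dosages in {0,1,2} with local LD
controlled by `ld_decay` (`np.inf` → independent variants); genetic-map
positions are `map_rate × bp / 1e6` cM; INFO scores are U(0.35, 1) tags only.
`simulate_covariates` draws ages 40–69, scan dates over four years,
correlated log-normal motion, and position variables. `simulate_phenotypes`
draws Y from the matrix-normal model with planted sparse causal effects and
group-shared missingness.

The generator emulates: dosage data with LD and a genetic map, imaging
confound structure, polygenic trait covariance through any supplied K, sparse
major effects, block missingness. It does **not** emulate: realistic allele
frequency spectra or LD panels, population stratification, non-Gaussian trait
distributions, genotype–confound correlation, or imputation error consistent
with the INFO tags.

## 8. Validation conditions

Conditions were fixed before the acceptance checks were written:

- **Structured kinship for (B, E) recovery**: an RRM computed from 500
  independent simulated variants at N = 2,000. The spread of its eigenvalues
  (including a null space of dimension N − rank) is what identifies B versus
  E; exchangeable family-block kinships at plausible relatedness were tried
  first and are too spectrally concentrated to recover both matrices within
  0.1 reliably at this N.
- **Recovery criteria**: B, E entrywise within 0.1 in ≥ 90% of 50 replicates
  (truth B = [[0.5, 0.25], [0.25, 0.5]], E = 0.5·I); 95% CI for h² = 0.6
  covering in ≥ 18/20; r̂_g within ±0.15 of 0.7 in ≥ 90% of 50; single-trait
  EM within ±0.005 of a 0.001-step grid-search ML oracle (the oracle must
  return −∞ whenever a rotated variance `h·λ + (1−h)` is non-positive, which
  happens at h = 1 for rank-deficient RRMs).
- **Calibration**: mass-GWAS null p-values uniform (KS < 0.02 over 50,000
  tests); multi-trait Wald type-I error at α = 0.05 within [0.03, 0.07]
  (P = 5, N = 1,000, 2,000 independent null variants).
- **Likelihood**: the rotated matrix-normal log-likelihood equals the
  brute-force `N·P`-dimensional Gaussian density with covariance
  `B ⊗ K + E ⊗ I` to 1e-8 at small sizes.
- **Problem sizes** are chosen so the full test suite runs in minutes on one
  CPU; all heavier objects (the N = 2,000 kinship eigendecomposition) are
  computed once per session.

## 9. Limitations

- Heritability SEs are marginal per-trait approximations for P > 1.
- The EM point estimate at default tolerance is accurate to ~1e-3 in h²;
  tighten `tol` for boundary-precision work.
- The multi-trait test conditions on (B, E) estimated once under the null;
  no per-variant refitting.
- The generator's LD model is AR(1)-like and not calibrated to any reference
  panel; INFO scores are decorative tags for QC plumbing.
- `drift_confounds` models drift as a pure function of scan date; scanner
  effects uncorrelated with date are not captured.
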