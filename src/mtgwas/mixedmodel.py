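"""Kinship construction and the matrix-normal multi-trait mixed model.

Model: for an N x P phenotype matrix Y,

    Y = G alpha + U + eps,   U ~ MN(0, K, B),   eps ~ MN(0, I_N, E),

where K is the kinship (realized relationship) matrix between samples, B the
P x P genetic covariance between traits and E the residual covariance.
Rotating Y by the eigenvectors of K = Q Lambda Q' makes the rows of Q'Y
independent with covariance lambda_n B + E, which underlies all three
computations here:

* EM estimation of (B, E) with the genetic effects U as latent data,
* per-trait SNP heritability h2_p = B_pp / (B_pp + E_pp) and genetic
  correlations r_ij = B_ij / sqrt(B_ii B_jj),
* a P-degree-of-freedom Wald test of alpha = 0 per variant, with B, E
  plugged in from the null fit and a leave-one-chromosome-out kinship.

Each EM iteration works in a basis that simultaneously diagonalizes B and E
(whiten by E, eigendecompose), so the per-row conditional moments are
elementwise and an iteration costs O(N P^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import GenotypeSet, PhenotypeTable
from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "KinshipMatrix", "CovarianceFit", "compute_rrm", "fit_matrix_normal",
    "matrix_normal_loglik", "heritability", "genetic_correlation",
    "genetic_correlation_matrix", "multi_trait_test", "multi_trait_scan",
]

_LOG10 = np.log(10.0)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """Symmetric PSD relatedness matrix with a cached eigendecomposition."""

    values: np.ndarray
    samples: list[str]
    source: str = "rrm"
    loco_excluded_chrom: str | None = None
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.samples) != n:
            raise ParameterError("kinship must be square and sample-aligned")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ParameterError("kinship must be symmetric")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues ascending, eigenvectors); negative round-off
        eigenvalues are clipped to zero."""
        if self._eig is None:
            lam, q = np.linalg.eigh(self.values)
            if lam.min() < -1e-8 * max(np.trace(self.values) / self.n_samples, 1.0):
                raise ParameterError("kinship is not positive semidefinite")
            lam = np.clip(lam, 0.0, None)
            self._eig = (lam, q)
        return self._eig


def compute_rrm(G: GenotypeSet, loco_exclude: str | None = None) -> KinshipMatrix:
    """Realized relationship matrix K = X X' / M from column-standardized
    dosages (mean 2p, variance 2p(1-p)); monomorphic columns are dropped and,
    with ``loco_exclude``, all variants on that chromosome are left out."""
    keep = np.ones(G.n_variants, dtype=bool)
    if loco_exclude is not None:
        keep &= (G.variants["chrom"].astype(str) != str(loco_exclude)).to_numpy()
    X = G.dosages[:, keep]
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    X = X[:, poly]
    p = p[poly]
    if X.shape[1] < 2:
        raise ParameterError("fewer than 2 polymorphic variants left for the RRM")
    Xs = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    K = Xs @ Xs.T / Xs.shape[1]
    return KinshipMatrix(values=K, samples=list(G.samples),
                         source=f"rrm[{Xs.shape[1]} variants]",
                         loco_excluded_chrom=loco_exclude)


# ---------------------------------------------------------------------------
# Matrix-normal EM
# ---------------------------------------------------------------------------

@dataclass
class CovarianceFit:
    """EM-estimated genetic (B) and residual (E) trait covariances."""

    B: np.ndarray
    E: np.ndarray
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    eigenvalues: np.ndarray            # of K, ascending
    eigenvectors: np.ndarray
    samples: list[str] = field(default_factory=list)
    rotated_Y: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_traits(self) -> int:
        return self.B.shape[0]


def _psd_clip(m: np.ndarray, floor: float = 0.0) -> np.ndarray:
    m = (m + m.T) / 2.0
    w, q = np.linalg.eigh(m)
    w = np.clip(w, floor, None)
    return (q * w) @ q.T


def _joint_basis(B: np.ndarray, E: np.ndarray):
    """T with T E T' = I and T B T' = diag(d); returns (T, T_inv, d)."""
    p = E.shape[0]
    jitter = 0.0
    for _ in range(5):
        try:
            L = np.linalg.cholesky(E + jitter * np.eye(p))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10 * max(np.trace(E), 1.0))
    else:  # pragma: no cover - E pathologically singular
        raise np.linalg.LinAlgError("residual covariance not factorizable")
    Linv = np.linalg.inv(L)
    Bt = Linv @ B @ Linv.T
    d, W = np.linalg.eigh((Bt + Bt.T) / 2.0)
    d = np.clip(d, 0.0, None)
    T = W.T @ Linv
    T_inv = L @ W
    return T, T_inv, d


def matrix_normal_loglik(Yr: np.ndarray, lam: np.ndarray, B: np.ndarray,
                         E: np.ndarray) -> float:
    """Log-likelihood of rotated data whose rows are independent
    N(0, lam_n B + E)."""
    n, p = Yr.shape
    T, _, d = _joint_basis(B, E)
    Z = Yr @ T.T
    v = lam[:, None] * d[None, :] + 1.0          # row-wise variances in T-basis
    sign, logdet_E = np.linalg.slogdet(E)
    if sign <= 0:
        return -np.inf
    quad = (Z * Z / v).sum()
    logdet = np.log(v).sum() + n * logdet_E
    return -0.5 * (n * p * np.log(2 * np.pi) + logdet + quad)


def fit_matrix_normal(Y: PhenotypeTable | np.ndarray, K: KinshipMatrix,
                      tol: float = 1e-6, max_iter: int = 1000) -> CovarianceFit:
    """Maximum-likelihood (B, E) by EM with the genetic effects latent.

    E-step: in the joint basis the conditional mean and variance of each
    rotated genetic effect are elementwise functions of lam_n and the
    diagonalized B.  M-step: closed-form covariance updates, projected back
    to PSD by eigenvalue clipping.  The log-likelihood trace is recorded and
    is non-decreasing up to the PSD projection.
    """
    if isinstance(Y, PhenotypeTable):
        samples = list(Y.samples)
        Ymat = Y.values
    else:
        Ymat = np.asarray(Y, dtype=float)
        samples = list(K.samples)
    if np.isnan(Ymat).any():
        raise ParameterError("fit_matrix_normal requires complete cases (no missing values)")
    n, p = Ymat.shape
    if p >= n:
        raise ParameterError("need more samples than traits (N > P)")
    if K.n_samples != n:
        raise ParameterError("kinship is not sample-aligned with the phenotypes")

    lam, Q = K.eigendecomposition()
    Yr = Q.T @ Ymat
    pos = lam > 1e-12
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ParameterError("kinship has no positive eigenvalues")

    S = Ymat.T @ Ymat / n
    B = S / 2.0
    E = S / 2.0
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        T, T_inv, d = _joint_basis(B, E)
        Z = Yr @ T.T                                 # N x P, noise cov diag per row
        v = lam[:, None] * d[None, :] + 1.0
        # conditional moments of the rotated genetic effect u_n (T-basis)
        g = lam[:, None] * d[None, :]                # prior variance of u in T-basis
        M = (g / v) * Z                              # conditional mean
        C = g - g * g / v                            # conditional variance (diagonal)
        # M-step sums
        Mp = M[pos]
        Cp = C[pos]
        lp = lam[pos][:, None]
        SB_z = (Mp / lp).T @ Mp + np.diag((Cp / lp).sum(axis=0))
        R = Z - M
        SE_z = R.T @ R + np.diag(C.sum(axis=0))
        B_new = _psd_clip(T_inv @ (SB_z / n_pos) @ T_inv.T)
        E_new = _psd_clip(T_inv @ (SE_z / n) @ T_inv.T)

        ll = matrix_normal_loglik(Yr, lam, B, E)
        trace.append(ll)
        if len(trace) > 1:
            prev = trace[-2]
            rel = abs(ll - prev) / max(abs(prev), 1.0)
            if rel < tol:
                converged = True
                B, E = B_new, E_new
                break
        B, E = B_new, E_new
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    trace.append(matrix_normal_loglik(Yr, lam, B, E))
    return CovarianceFit(B=B, E=E, loglik_trace=trace, converged=converged,
                         n_iter=it, eigenvalues=lam, eigenvectors=Q,
                         samples=samples, rotated_Y=Yr)


# ---------------------------------------------------------------------------
# Heritability and genetic correlation
# ---------------------------------------------------------------------------

def _marginal_info(yr: np.ndarray, lam: np.ndarray, b: float, e: float):
    """Observed information of the single-trait marginal log-likelihood at
    (b, e), by central finite differences."""

    def ll(bb, ee):
        v = lam * bb + ee
        if v.min() <= 0:
            return -np.inf
        return -0.5 * (np.log(v).sum() + (yr * yr / v).sum())

    scale = max(b + e, 1e-8)
    h = 1e-4 * scale
    f0 = ll(b, e)
    d2b = (ll(b + h, e) - 2 * f0 + ll(b - h, e)) / h**2
    d2e = (ll(b, e + h) - 2 * f0 + ll(b, e - h)) / h**2
    dbe = (ll(b + h, e + h) - ll(b + h, e - h) - ll(b - h, e + h) + ll(b - h, e - h)) / (4 * h**2)
    H = np.array([[d2b, dbe], [dbe, d2e]])
    return -H  # observed information


def heritability(fit: CovarianceFit, alpha: float = 0.05):
    """Per-trait SNP heritability h2 = B_pp/(B_pp+E_pp) with a standard error
    from the observed Fisher information of the marginal single-trait
    likelihood (delta method) and a one-sided test of B_pp = 0.

    Returns a list of dicts with h2, se, ci lower/upper, significant flag.
    """
    import pandas as pd

    lam = fit.eigenvalues
    z_one = stats.norm.ppf(1 - alpha)
    z_two = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for p_idx in range(fit.n_traits):
        b = float(fit.B[p_idx, p_idx])
        e = float(fit.E[p_idx, p_idx])
        tot = b + e
        if tot <= 0:
            rows.append({"trait": p_idx, "h2": np.nan, "se": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "significant": False, "flag": "zero total variance"})
            continue
        h2 = b / tot
        se = np.nan
        sig = False
        if fit.rotated_Y is not None:
            yr = fit.rotated_Y[:, p_idx]
            # evaluate the information just inside the boundary if b == 0
            b_eval = max(b, 1e-6 * tot)
            info = _marginal_info(yr, lam, b_eval, e)
            try:
                cov = np.linalg.inv(info)
                grad = np.array([e / tot**2, -b / tot**2])
                var_h2 = float(grad @ cov @ grad)
                se_b = float(np.sqrt(max(cov[0, 0], 0.0)))
                if var_h2 > 0:
                    se = float(np.sqrt(var_h2))
                if b > 0 and se_b > 0:
                    sig = (b / se_b) > z_one
            except np.linalg.LinAlgError:
                pass
        lo = h2 - z_two * se if np.isfinite(se) else np.nan
        hi = h2 + z_two * se if np.isfinite(se) else np.nan
        rows.append({"trait": p_idx, "h2": h2, "se": se,
                     "ci_low": lo, "ci_high": hi,
                     "significant": bool(sig), "flag": ""})
    return pd.DataFrame(rows)


def genetic_correlation(fit: CovarianceFit, i: int, j: int) -> float:
    """r_ij = B_ij / sqrt(B_ii B_jj), clipped to [-1, 1]."""
    bii, bjj = fit.B[i, i], fit.B[j, j]
    if bii <= 0 or bjj <= 0:
        raise ParameterError("genetic correlation undefined: zero genetic variance")
    return float(np.clip(fit.B[i, j] / np.sqrt(bii * bjj), -1.0, 1.0))


def genetic_correlation_matrix(fit: CovarianceFit) -> np.ndarray:
    d = np.sqrt(np.diag(fit.B))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = fit.B / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Multi-trait association test
# ---------------------------------------------------------------------------

def _scan_core(Yr: np.ndarray, Gr: np.ndarray, lam: np.ndarray,
               B: np.ndarray, E: np.ndarray):
    """Vectorized GLS over rotated data: per variant, alpha-hat, its GLS
    precision in the joint basis, and the P-df Wald chi-square."""
    ridge = 0.0
    if np.linalg.eigvalsh(E).min() <= 1e-12 * max(np.trace(E), 1.0):
        ridge = 1e-8 * np.trace(E + B)
        logger.info("singular residual covariance: ridge %.3g added", ridge)
    T, T_inv, d = _joint_basis(B, E + ridge * np.eye(E.shape[0]))
    Z = Yr @ T.T                                   # N x P
    W = 1.0 / (lam[:, None] * d[None, :] + 1.0)    # N x P weights
    NUM = Gr.T @ (Z * W)                           # m x P
    DEN = (Gr * Gr).T @ W                          # m x P
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_z = np.where(DEN > 0, NUM / DEN, 0.0)
    chi2 = np.where(DEN > 0, NUM * NUM / DEN, 0.0).sum(axis=1)
    alpha = alpha_z @ T_inv.T                      # back to trait coordinates
    return alpha, chi2


def multi_trait_scan(Y: PhenotypeTable | np.ndarray, G_dosages: np.ndarray,
                     null_fit: CovarianceFit, K_loco: KinshipMatrix | None = None):
    """Wald multi-trait test for every dosage column.

    Uses B, E from ``null_fit`` (plug-in null covariances); rotation uses the
    kinship eigendecomposition stored in the fit unless ``K_loco`` is given,
    in which case that kinship must be the one the null was fitted under.
    Returns (alpha m x P, chi2 m, neglog10_p m).
    """
    Ymat = Y.values if isinstance(Y, PhenotypeTable) else np.asarray(Y, dtype=float)
    if np.isnan(Ymat).any():
        raise ParameterError("multi-trait test requires complete cases")
    if K_loco is not None:
        lam, Q = K_loco.eigendecomposition()
    else:
        lam, Q = null_fit.eigenvalues, null_fit.eigenvectors
    Gm = np.asarray(G_dosages, dtype=float)
    if Gm.ndim == 1:
        Gm = Gm[:, None]
    Gc = Gm - Gm.mean(axis=0, keepdims=True)
    Yr = Q.T @ Ymat
    Gr = Q.T @ Gc
    alpha, chi2 = _scan_core(Yr, Gr, lam, null_fit.B, null_fit.E)
    p_traits = Ymat.shape[1]
    neglog10_p = -stats.chi2.logsf(chi2, df=p_traits) / _LOG10
    return alpha, chi2, neglog10_p


def multi_trait_test(Y: PhenotypeTable | np.ndarray, g: np.ndarray,
                     null_fit: CovarianceFit, K_loco: KinshipMatrix | None = None):
    """Single-variant multi-trait Wald test; returns (alpha-hat vector,
    chi-square, -log10 P with P_traits degrees of freedom)."""
    alpha, chi2, nlp = multi_trait_scan(Y, np.asarray(g, dtype=float)[:, None],
                                        null_fit, K_loco)
    return alpha[0], float(chi2[0]), float(nlp[0])
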