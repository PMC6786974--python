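"""Synthetic cohorts with the statistical structure the analyses assume.

Generates biallelic dosages with a tunable minor-allele-frequency spectrum
and local linkage disequilibrium (first-order haplotype Markov chain along
each chromosome), scanner-style covariates (age, sex, scan date, head
motion, head-size scaling, coil/head positions), and phenotypes from the
matrix-normal mixed model

    Y = G alpha + U + eps,   U ~ MN(0, K, B),   eps ~ MN(0, I_N, E),

with group-structured missingness.  Everything is deterministic under a
seed, and the drawn ground truth (B, E, sparse alpha) is recorded so that
downstream estimators can be validated against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import io as mio
from .containers import GenotypeSet, PhenotypeTable, dosage_maf
from .errors import ParameterError

__all__ = [
    "CovariateSet", "TruthSet", "simulate_genotypes", "simulate_covariates",
    "simulate_phenotypes", "make_block_kinship", "make_fixture",
    "random_truth", "psd_sqrt", "FIXTURE_PROFILES",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CovariateSet:
    """Per-sample acquisition covariates used to build the confound matrix."""

    samples: list[str]
    age: np.ndarray              # years
    sex: np.ndarray              # 0/1
    scan_date: np.ndarray        # days since study start
    motion_rest: np.ndarray      # mean framewise displacement, mm
    motion_task: np.ndarray      # mm
    head_size_scaling: np.ndarray  # unitless volumetric scaling factor
    position_vars: np.ndarray    # N x 4 table/coil/brain-centre positions

    def __post_init__(self) -> None:
        n = len(self.samples)
        for name in ("age", "sex", "scan_date", "motion_rest", "motion_task",
                     "head_size_scaling"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (n,):
                raise ParameterError(f"{name} must have one value per sample")
            if name in ("age", "sex") and np.isnan(v).any():
                raise ParameterError(f"{name} may not be missing")
            setattr(self, name, v)
        self.position_vars = np.asarray(self.position_vars, dtype=float)
        if self.position_vars.shape != (n, 4):
            raise ParameterError("position_vars must be N x 4")

    @property
    def motion(self) -> np.ndarray:
        return np.column_stack([self.motion_rest, self.motion_task])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "sample_id": self.samples, "age": self.age, "sex": self.sex,
            "scan_date": self.scan_date, "motion_rest": self.motion_rest,
            "motion_task": self.motion_task,
            "head_size_scaling": self.head_size_scaling,
        })
        for k in range(4):
            df[f"position_{k + 1}"] = self.position_vars[:, k]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CovariateSet":
        return cls(
            samples=df["sample_id"].astype(str).tolist(),
            age=df["age"].to_numpy(float), sex=df["sex"].to_numpy(float),
            scan_date=df["scan_date"].to_numpy(float),
            motion_rest=df["motion_rest"].to_numpy(float),
            motion_task=df["motion_task"].to_numpy(float),
            head_size_scaling=df["head_size_scaling"].to_numpy(float),
            position_vars=df[[f"position_{k + 1}" for k in range(4)]].to_numpy(float),
        )


@dataclass
class TruthSet:
    """Ground truth of a simulated cohort: trait covariances and SNP effects.

    ``causal_effects`` is a sparse list of (variant index, phenotype index,
    effect per dosage unit); ``seed`` reproduces the phenotype draw exactly.
    """

    B_true: np.ndarray
    E_true: np.ndarray
    causal_effects: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.B_true = _check_psd(np.asarray(self.B_true, dtype=float), "B_true")
        self.E_true = _check_psd(np.asarray(self.E_true, dtype=float), "E_true")
        if self.B_true.shape != self.E_true.shape:
            raise ParameterError("B_true and E_true must have the same shape")

    @property
    def n_phenotypes(self) -> int:
        return self.B_true.shape[0]


def _check_psd(m: np.ndarray, name: str, tol_factor: float = 1e-8) -> np.ndarray:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ParameterError(f"{name} must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ParameterError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(m)
    if w.min() < -tol_factor * max(w.max(), 1.0):
        raise ParameterError(f"{name} is not positive semidefinite (min eig {w.min():.3g})")
    return m


def psd_sqrt(m: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition; negative eigenvalues
    below 1e-10 x max are clipped to zero."""
    w, q = np.linalg.eigh(np.asarray(m, dtype=float))
    w = np.where(w < 1e-10 * max(w.max(), 1.0), 0.0, w)
    return (q * np.sqrt(w)) @ q.T


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _draw_freqs(maf_spectrum, m: int, rng: np.random.Generator) -> np.ndarray:
    if np.isscalar(maf_spectrum):
        f = np.full(m, float(maf_spectrum))
    elif isinstance(maf_spectrum, tuple) and len(maf_spectrum) == 2:
        lo, hi = map(float, maf_spectrum)
        if not (0 < lo <= hi <= 0.5):
            raise ParameterError("maf_spectrum bounds must satisfy 0 < low <= high <= 0.5")
        f = rng.uniform(lo, hi, size=m)
    else:
        f = np.asarray(maf_spectrum, dtype=float)
        if f.shape != (m,):
            raise ParameterError("maf_spectrum array must have one frequency per variant")
    if f.min() <= 0 or f.max() > 0.5:
        raise ParameterError("allele frequencies must lie in (0, 0.5]")
    return f


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    maf_spectrum=(0.01, 0.5),
    ld_decay: float = 2e-5,
    map_rate: float = 1.0,
    seed: int = 0,
    n_chromosomes: int = 2,
    bp_spacing: int = 1_000,
) -> GenotypeSet:
    """Simulate dosages as sums of two haplotypes with Markov-chain LD.

    Haplotype alleles come from a latent Gaussian AR(1) process thresholded
    at the allele-frequency quantile: adjacent variants at physical distance
    d bp have latent correlation exp(-ld_decay * d), so ``ld_decay=inf``
    gives independent variants.  cM positions follow a constant ``map_rate``
    cM/Mb map; imputation INFO scores are simulated attributes in (0.3, 1].
    """
    if n_samples < 1 or n_variants < 1:
        raise ParameterError("n_samples and n_variants must be >= 1")
    if n_chromosomes < 1 or n_chromosomes > n_variants:
        raise ParameterError("need 1 <= n_chromosomes <= n_variants")
    rng = np.random.default_rng(seed)
    freqs = _draw_freqs(maf_spectrum, n_variants, rng)
    thresholds = norm.ppf(freqs)

    # assign variants to chromosomes in contiguous blocks
    per_chrom = np.array_split(np.arange(n_variants), n_chromosomes)
    chrom = np.empty(n_variants, dtype=object)
    pos = np.empty(n_variants, dtype=int)
    for c, idx in enumerate(per_chrom, start=1):
        chrom[idx] = str(c)
        pos[idx] = 10_000 + bp_spacing * np.arange(len(idx))

    # latent AR(1) haplotypes: 2 per sample
    z = np.empty((2 * n_samples, n_variants))
    for idx in per_chrom:
        z[:, idx[0]] = rng.standard_normal(2 * n_samples)
        for j_prev, j in zip(idx[:-1], idx[1:]):
            d = pos[j] - pos[j_prev]
            rho = 0.0 if np.isinf(ld_decay) else float(np.exp(-ld_decay * d))
            z[:, j] = rho * z[:, j_prev] + np.sqrt(1.0 - rho * rho) * rng.standard_normal(2 * n_samples)
    alleles = (z < thresholds[None, :]).astype(np.int8)
    hard = alleles[0::2] + alleles[1::2]
    dosages = hard.astype(float)

    variants = pd.DataFrame({
        "id": [f"rs{j + 1}" for j in range(n_variants)],
        "chrom": chrom, "pos": pos,
        "ref": "A", "alt": "G",
        "cm": map_rate * pos / 1e6,
        "info": rng.uniform(0.35, 1.0, size=n_variants),
        "maf": dosage_maf(dosages),
    })
    return GenotypeSet(samples=[f"S{i + 1:05d}" for i in range(n_samples)],
                       dosages=dosages, variants=variants, hard_calls=hard)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def simulate_covariates(n_samples: int, seed: int = 0) -> CovariateSet:
    """Simulate acquisition covariates over plausible scanner-cohort ranges:
    ages 40-69, scan dates over a four-year window, correlated rest/task head
    motion, and four head/coil position variables."""
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    age = rng.integers(40, 70, size=n_samples).astype(float)
    sex = rng.integers(0, 2, size=n_samples).astype(float)
    scan_date = np.sort(rng.uniform(0, 4 * 365, size=n_samples)).astype(float)
    base = rng.lognormal(mean=np.log(0.12), sigma=0.4, size=n_samples)
    motion_rest = base * np.exp(rng.normal(0, 0.25, n_samples))
    motion_task = base * np.exp(rng.normal(0, 0.25, n_samples))
    head = rng.normal(1.0, 0.08, size=n_samples)
    position = rng.normal(0.0, 1.0, size=(n_samples, 4))
    return CovariateSet(
        samples=[f"S{i + 1:05d}" for i in range(n_samples)],
        age=age, sex=sex, scan_date=scan_date,
        motion_rest=motion_rest, motion_task=motion_task,
        head_size_scaling=head, position_vars=position,
    )


# ---------------------------------------------------------------------------
# Kinship helper and phenotypes
# ---------------------------------------------------------------------------

def make_block_kinship(n_samples: int, family_size: int = 10,
                       relatedness: float = 0.5) -> np.ndarray:
    """Exchangeable family-block kinship: 1 on the diagonal, ``relatedness``
    within families, 0 between.  Its eigenvalue spread (families give
    1 + relatedness*(s-1) vs 1 - relatedness) is what identifies genetic
    from residual covariance in the mixed model."""
    if not (0 <= relatedness < 1):
        raise ParameterError("relatedness must be in [0, 1)")
    K = np.zeros((n_samples, n_samples))
    for start in range(0, n_samples, family_size):
        stop = min(start + family_size, n_samples)
        K[start:stop, start:stop] = relatedness
    np.fill_diagonal(K, 1.0)
    return K


def simulate_phenotypes(
    G: GenotypeSet,
    K: np.ndarray,
    truth: TruthSet,
    group_missingness: dict[str, float] | None = None,
    groups: list[str] | None = None,
) -> PhenotypeTable:
    """Draw Y = G alpha + U + eps from the matrix-normal model.

    U = L_K Z L_B' and eps = Z' L_E' with L the PSD square roots and Z, Z'
    independent standard-normal matrices, so rows of U have covariance
    proportional to K and columns covariance B.  Missingness is applied per
    phenotype group: all phenotypes in a group share one missing-sample set.
    """
    n, p = G.n_samples, truth.n_phenotypes
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ParameterError(f"K must be {n} x {n}")
    _check_psd(K, "K")
    rng = np.random.default_rng(truth.seed)

    Y = np.zeros((n, p))
    for v_idx, p_idx, eff in truth.causal_effects:
        Y[:, p_idx] += eff * G.dosages[:, v_idx]
    L_K, L_B, L_E = psd_sqrt(K), psd_sqrt(truth.B_true), psd_sqrt(truth.E_true)
    Y += L_K @ rng.standard_normal((n, p)) @ L_B.T
    Y += rng.standard_normal((n, p)) @ L_E.T

    if groups is None:
        groups = ["all"] * p
    if len(groups) != p:
        raise ParameterError("one group label per phenotype required")
    if group_missingness:
        for g, rate in group_missingness.items():
            if not (0 <= rate < 1):
                raise ParameterError(f"missing rate for group {g!r} must be in [0, 1)")
            cols = [i for i, lab in enumerate(groups) if lab == g]
            if not cols:
                continue
            n_miss = int(round(rate * n))
            miss = rng.choice(n, size=n_miss, replace=False)
            Y[np.ix_(miss, cols)] = np.nan

    names = [f"pheno_{i + 1}" for i in range(p)]
    return PhenotypeTable(samples=list(G.samples), values=Y, names=names,
                          groups=list(groups))


def random_truth(n_phenotypes: int, n_variants: int, seed: int = 0,
                 n_causal: int = 3, h2_scale: float = 0.4,
                 effect_size: float = 0.25) -> TruthSet:
    """Draw a random PSD (B, E) pair with mean per-trait heritability near
    ``h2_scale`` and a sparse set of causal dosage effects."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n_phenotypes, n_phenotypes))
    B = A @ A.T / n_phenotypes * h2_scale
    C = rng.standard_normal((n_phenotypes, n_phenotypes))
    E = C @ C.T / n_phenotypes * (1.0 - h2_scale)
    causal = []
    for _ in range(min(n_causal, n_variants)):
        causal.append((int(rng.integers(n_variants)),
                       int(rng.integers(n_phenotypes)),
                       float(rng.choice([-1, 1]) * effect_size)))
    return TruthSet(B_true=B, E_true=E, causal_effects=causal, seed=seed)


# ---------------------------------------------------------------------------
# On-disk fixtures
# ---------------------------------------------------------------------------

FIXTURE_PROFILES = {
    "tiny": dict(n_samples=60, n_variants=120, n_phenotypes=3),
    "small": dict(n_samples=400, n_variants=800, n_phenotypes=4),
    "medium": dict(n_samples=2_000, n_variants=5_000, n_phenotypes=8),
}


def make_fixture(profile: str, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic bundle (VCF + map + covariate/phenotype TSVs
    + truth JSON) for a named size preset and return the file paths."""
    if profile not in FIXTURE_PROFILES:
        raise ParameterError(f"profile must be one of {sorted(FIXTURE_PROFILES)}")
    spec = FIXTURE_PROFILES[profile]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    G = simulate_genotypes(spec["n_samples"], spec["n_variants"], seed=seed)
    cov = simulate_covariates(spec["n_samples"], seed=seed + 1)
    truth = random_truth(spec["n_phenotypes"], spec["n_variants"], seed=seed + 2)
    K = make_block_kinship(spec["n_samples"])
    p = spec["n_phenotypes"]
    groups = ["grp1" if i < p // 2 else "grp2" for i in range(p)]
    Y = simulate_phenotypes(G, K, truth, groups=groups,
                            group_missingness={"grp2": 0.1})

    paths = {
        "vcf": mio.write_vcf_dosages(G, out / "genotypes.vcf"),
        "map": mio.write_map(G.variants, out / "genotypes.map"),
        "covariates": mio.write_table(cov.to_frame(), out / "covariates.tsv"),
        "phenotypes": mio.write_phenotypes(Y, out / "phenotypes.tsv",
                                           out / "phenotype_groups.tsv"),
        "groups": out / "phenotype_groups.tsv",
        "truth": mio.write_truth(truth, out / "truth.json"),
    }
    return paths
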