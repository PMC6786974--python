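"""Variant QC and mass univariate association.

Every variant is tested against every prepared phenotype with an additive
dosage model (simple linear regression of the residualized phenotype on
expected allele count).  The engine streams genotype blocks so each block is
read once for all phenotypes and peak memory depends on block size, not on
the number of variants.  Confounds are handled upstream by phenotype
residualization, so the per-pair regression is bivariate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeSet, PhenotypeTable

__all__ = ["QCReport", "variant_qc", "hwe_test", "run_mass_gwas",
           "iter_mass_gwas", "MAX_NEGLOG10P"]

#: cap for -log10 P when the fit is numerically exact (se ~ 0)
MAX_NEGLOG10P = 350.0

_LOG10 = np.log(10.0)


@dataclass
class QCReport:
    n_input: int
    n_fail_maf: int
    n_fail_info: int
    n_fail_hwe: int
    n_pass: int


def hwe_test(hard_calls: np.ndarray) -> np.ndarray:
    """One-degree-of-freedom chi-square Hardy-Weinberg P value per variant
    from integer genotype columns."""
    g = np.asarray(hard_calls)
    n = g.shape[0]
    n0 = (g == 0).sum(axis=0)
    n1 = (g == 1).sum(axis=0)
    n2 = (g == 2).sum(axis=0)
    p = (n1 + 2 * n2) / (2 * n)
    q = 1 - p
    exp = np.stack([q * q * n, 2 * p * q * n, p * p * n])
    obs = np.stack([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=0)
    pval = stats.chi2.sf(chi2, df=1)
    pval[(p == 0) | (p == 1)] = 1.0  # monomorphic: no HWE departure definable
    return pval


def variant_qc(G: GenotypeSet, maf_min: float = 0.001, info_min: float = 0.3,
               hwe_p_min: float = 1e-7) -> tuple[GenotypeSet, QCReport]:
    """Remove variants failing MAF, imputation-INFO or Hardy-Weinberg
    filters; HWE is computed on hard calls (recorded or rounded dosages)."""
    maf = G.variants["maf"].to_numpy(float)
    info = G.variants["info"].to_numpy(float)
    hwe_p = hwe_test(G.get_hard_calls())
    fail_maf = maf < maf_min
    fail_info = info < info_min
    fail_hwe = hwe_p < hwe_p_min
    keep = ~(fail_maf | fail_info | fail_hwe)
    report = QCReport(
        n_input=G.n_variants,
        n_fail_maf=int(fail_maf.sum()),
        n_fail_info=int(fail_info.sum()),
        n_fail_hwe=int(fail_hwe.sum()),
        n_pass=int(keep.sum()),
    )
    return G.subset_variants(keep), report


def _neglog10_p_from_t(t: np.ndarray, df: np.ndarray | int) -> np.ndarray:
    """Two-sided -log10 P from a t statistic, computed in log space."""
    logp = np.log(2.0) + stats.t.logsf(np.abs(t), df)
    out = -logp / _LOG10
    return np.minimum(np.where(np.isfinite(out), out, MAX_NEGLOG10P), MAX_NEGLOG10P)


def iter_mass_gwas(G: GenotypeSet, Y: PhenotypeTable,
                   block_size: int = 1024) -> Iterator[pd.DataFrame]:
    """Yield long-format association records one genotype block at a time.

    Phenotypes sharing a missingness group are regressed together with one
    sample intersection; per block the work is two matrix products per group.
    """
    groups: dict[str, list[int]] = {}
    for j, g in enumerate(Y.groups):
        groups.setdefault(g, []).append(j)
    masks = {g: Y.group_mask(g) for g in groups}

    v = G.variants
    for start in range(0, G.n_variants, block_size):
        stop = min(start + block_size, G.n_variants)
        X = G.dosages[:, start:stop]
        vb = v.iloc[start:stop]
        frames = []
        for gname, cols in groups.items():
            mask = masks[gname]
            n_used = int(mask.sum())
            Xg = X[mask]
            Yg = Y.values[np.ix_(mask, cols)]
            Xc = Xg - Xg.mean(axis=0, keepdims=True)
            Yc = Yg - Yg.mean(axis=0, keepdims=True)
            sx2 = (Xc * Xc).sum(axis=0)            # (m,)
            sy2 = (Yc * Yc).sum(axis=0)            # (p,)
            cross = Xc.T @ Yc                      # (m, p)
            with np.errstate(divide="ignore", invalid="ignore"):
                beta = cross / sx2[:, None]
                sse = np.maximum(sy2[None, :] - beta * cross, 0.0)
                df = n_used - 2
                se = np.sqrt(sse / df / sx2[:, None])
                t = beta / se
            neglog10_p = _neglog10_p_from_t(t, df)
            zero_var = sx2 == 0
            if zero_var.any():
                beta[zero_var] = np.nan
                se[zero_var] = np.nan
                t[zero_var] = np.nan
                neglog10_p[zero_var] = np.nan
            m, p = beta.shape
            frames.append(pd.DataFrame({
                "variant": np.repeat(vb["id"].values, p),
                "chrom": np.repeat(vb["chrom"].values, p),
                "pos": np.repeat(vb["pos"].values, p),
                "cm": np.repeat(vb["cm"].values, p),
                "maf": np.repeat(vb["maf"].values, p),
                "phenotype": np.tile(np.asarray(Y.names, dtype=object)[cols], m),
                "beta": beta.ravel(),
                "se": se.ravel(),
                "t": t.ravel(),
                "neglog10_p": neglog10_p.ravel(),
                "n_used": n_used,
                "zero_variance": np.repeat(zero_var, p),
            }))
        yield pd.concat(frames, ignore_index=True)


def run_mass_gwas(G: GenotypeSet, Y: PhenotypeTable,
                  block_size: int = 1024) -> pd.DataFrame:
    """All (variant, phenotype) association records as one long DataFrame."""
    frames = list(iter_mass_gwas(G, Y, block_size=block_size))
    if not frames:
        return pd.DataFrame(columns=["variant", "chrom", "pos", "cm", "maf",
                                     "phenotype", "beta", "se", "t",
                                     "neglog10_p", "n_used", "zero_variance"])
    return pd.concat(frames, ignore_index=True)
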