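"""Analysis-ready phenotypes: quantile-normalized and residualized on the
confound matrix plus genetic principal components, complete-case per
phenotype, with the input missingness pattern preserved."""

from __future__ import annotations

import logging

import numpy as np

from .confounds import ConfoundMatrix, quantile_normalize
from .containers import GenotypeSet, PhenotypeTable
from .errors import AlignmentError

logger = logging.getLogger(__name__)

__all__ = ["prepare_phenotypes", "genotype_pcs"]


def prepare_phenotypes(Y: PhenotypeTable, C: ConfoundMatrix,
                       pcs: np.ndarray | None = None,
                       min_extra_samples: int = 10) -> PhenotypeTable:
    """Quantile-normalize each phenotype and regress out the confound matrix
    together with the genetic principal components.

    Each phenotype is handled on its own non-missing sample set (no
    imputation of missing phenotypes); residuals are returned in the original
    sample order with missingness preserved.  A phenotype with fewer than
    n_design_columns + ``min_extra_samples`` non-missing values is skipped
    (left all-missing) with a logged warning.
    """
    if list(Y.samples) != list(C.samples):
        offenders = sorted(set(Y.samples) ^ set(C.samples))
        raise AlignmentError(f"phenotype/confound samples differ: {offenders[:10]}")
    design_parts = [C.values]
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        if pcs.shape[0] != Y.n_samples:
            raise AlignmentError("genetic PCs are not sample-aligned")
        design_parts.append(pcs)
    design_parts.append(np.ones((Y.n_samples, 1)))  # intercept for the complete-case subset
    X = np.column_stack(design_parts)

    out = np.full_like(Y.values, np.nan)
    for j in range(Y.n_phenotypes):
        y = Y.values[:, j]
        obs = ~np.isnan(y)
        if obs.sum() < X.shape[1] + min_extra_samples:
            logger.warning("phenotype %s skipped: %d non-missing < %d required",
                           Y.names[j], int(obs.sum()), X.shape[1] + min_extra_samples)
            continue
        yq = quantile_normalize(y)
        Xo = X[obs]
        beta, *_ = np.linalg.lstsq(Xo, yq[obs], rcond=None)
        out[obs, j] = yq[obs] - Xo @ beta
    return PhenotypeTable(samples=list(Y.samples), values=out,
                          names=list(Y.names), groups=list(Y.groups),
                          prepared=True)


def genotype_pcs(G: GenotypeSet, n_pcs: int = 40) -> np.ndarray:
    """Principal components of the column-standardized dosage matrix.

    Convenience for synthetic cohorts; in a real study the cohort-supplied
    genetic PCs are the intended input to :func:`prepare_phenotypes`.
    """
    X = np.asarray(G.dosages, dtype=float)
    p = X.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    X = X[:, keep]
    Xs = (X - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
    n_pcs = min(n_pcs, min(Xs.shape) - 1)
    u, s, _ = np.linalg.svd(Xs, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]
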