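"""Reduction of a large noisy phenotype block to a few reproducible features.

The block (e.g. functional-connectivity edges) is first compressed by SVD,
then rotated by ICA so that the component *weight vectors over phenotypes*
(not the subject scores) are maximally independent.  The SVD and ICA
dimensionalities are chosen by split-half reproducibility across subjects:
components whose weight vectors reappear (|r| above a threshold, 0.9 by
default) in independent halves of the cohort are considered real.

On the reference cohort this procedure selected 14 SVD eigenvectors and 6
ICA components; those values are the documented defaults (``DEFAULT_SVD_DIM``,
``DEFAULT_ICA_DIM``) but are re-selected from the data on any new cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import ParameterError

__all__ = [
    "IcaReduction", "fit_reduction", "split_half_reproducibility",
    "reproducibility_between", "ica_reduce",
    "DEFAULT_SVD_DIM", "DEFAULT_ICA_DIM",
]

DEFAULT_SVD_DIM = 14
DEFAULT_ICA_DIM = 6


@dataclass
class IcaReduction:
    """Fitted reduction: unit-norm weight vectors over input phenotypes,
    subject scores (the new phenotypes) and per-component split-half
    reproducibility."""

    svd_dim: int
    ica_dim: int
    weight_vectors: np.ndarray          # ica_dim x P, unit norm, canonical sign
    subject_scores: np.ndarray          # N x ica_dim
    reproducibility: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return self.weight_vectors.shape[0] == 0


def _canonicalize(weights: np.ndarray, scores: np.ndarray):
    """Unit-norm rows, sign so the largest-|.| weight is positive, ordered by
    subject-score variance."""
    w = weights.copy()
    sc = scores.copy()
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    sc = sc * norms.T
    w = w / norms
    for k in range(w.shape[0]):
        i = np.argmax(np.abs(w[k]))
        if w[k, i] < 0:
            w[k] = -w[k]
            sc[:, k] = -sc[:, k]
    order = np.argsort(-sc.var(axis=0), kind="stable")
    return w[order], sc[:, order]


def fit_reduction(Y: np.ndarray, svd_dim: int, ica_dim: int, seed: int = 0,
                  n_restarts: int = 5) -> IcaReduction:
    """SVD to ``svd_dim`` then FastICA over phenotype weights to ``ica_dim``.

    ICA is run on the svd_dim-dimensional representation of the P phenotype
    loadings, so independence is maximized between component weight vectors.
    Seeded, with restarts on non-convergence.
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    if ica_dim > svd_dim:
        raise ParameterError("ica_dim must not exceed svd_dim")
    if svd_dim > min(n, p):
        raise ParameterError("svd_dim exceeds the rank bound of the data")
    Yc = Y - Y.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Yc, full_matrices=False)
    # phenotype loadings in the retained subspace, variance-weighted
    loadings = (s[:svd_dim, None] * vt[:svd_dim]).T  # P x svd_dim

    rng = np.random.default_rng(seed)
    sources = None
    for attempt in range(n_restarts):
        ica = FastICA(n_components=ica_dim, whiten="unit-variance",
                      max_iter=1000, tol=1e-6,
                      random_state=int(rng.integers(2**31 - 1)))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            cand = ica.fit_transform(loadings)  # P x ica_dim
            if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
                sources = cand
                break
            sources = cand  # keep the last attempt even if not converged
    weights = sources.T  # ica_dim x P
    wn = weights / np.linalg.norm(weights, axis=1, keepdims=True)
    scores = Yc @ wn.T
    weights, scores = _canonicalize(wn, scores)
    return IcaReduction(svd_dim=svd_dim, ica_dim=ica_dim,
                        weight_vectors=weights, subject_scores=scores)


def _match_components(wa: np.ndarray, wb: np.ndarray) -> np.ndarray:
    """Greedy match of component weight vectors on |correlation|; returns the
    matched |r| values sorted descending."""
    k = wa.shape[0]
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            corr[i, j] = abs(np.corrcoef(wa[i], wb[j])[0, 1])
    matched = []
    avail_a, avail_b = set(range(k)), set(range(k))
    flat = sorted(((corr[i, j], i, j) for i in range(k) for j in range(k)),
                  reverse=True)
    for r, i, j in flat:
        if i in avail_a and j in avail_b:
            matched.append(r)
            avail_a.discard(i)
            avail_b.discard(j)
    return np.array(sorted(matched, reverse=True))


def reproducibility_between(Ya: np.ndarray, Yb: np.ndarray, svd_dim: int,
                            ica_dim: int, seed: int = 0) -> np.ndarray:
    """Matched |r| of component weight vectors between reductions fitted
    independently on two subject sets (descending).  Identical inputs give
    all-ones up to ICA convergence tolerance."""
    ra = fit_reduction(Ya, svd_dim, ica_dim, seed=seed)
    rb = fit_reduction(Yb, svd_dim, ica_dim, seed=seed + 1)
    return _match_components(ra.weight_vectors, rb.weight_vectors)


def split_half_reproducibility(Y: np.ndarray, svd_dim: int, ica_dim: int,
                               n_splits: int = 10, seed: int = 0) -> np.ndarray:
    """Mean matched |r| of component weight vectors across random subject
    halves; one value per component (descending)."""
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if ica_dim > svd_dim:
        raise ParameterError("ica_dim must not exceed svd_dim")
    if n < 4 * ica_dim:
        raise ParameterError("need at least 4 x ica_dim subjects")
    rng = np.random.default_rng(seed)
    acc = np.zeros(ica_dim)
    for _ in range(n_splits):
        perm = rng.permutation(n)
        half = n // 2
        acc += reproducibility_between(Y[perm[:half]], Y[perm[half:2 * half]],
                                       svd_dim, ica_dim,
                                       seed=int(rng.integers(2**31 - 1)))
    return acc / n_splits


def ica_reduce(Y: np.ndarray, candidate_svd_dims=None, candidate_ica_dims=None,
               r_threshold: float = 0.9, n_splits: int = 10,
               seed: int = 0) -> IcaReduction:
    """Select (svd_dim, ica_dim) by split-half reproducibility and refit on
    all subjects.

    The pair maximizing the number of components with reproducibility above
    ``r_threshold`` wins; ties go to the smaller dimensionalities.  When no
    component reaches the threshold an empty reduction is returned with the
    full reproducibility table in ``diagnostics``.
    """
    Y = np.asarray(Y, dtype=float)
    if candidate_svd_dims is None:
        candidate_svd_dims = [DEFAULT_SVD_DIM]
    if candidate_ica_dims is None:
        candidate_ica_dims = [DEFAULT_ICA_DIM]
    candidate_svd_dims = sorted(set(int(d) for d in candidate_svd_dims))
    candidate_ica_dims = sorted(set(int(d) for d in candidate_ica_dims))
    if not candidate_svd_dims or not candidate_ica_dims:
        raise ParameterError("candidate dimension lists must be non-empty")

    table = {}
    best = None  # (count, -ica, -svd) maximized
    for sd in candidate_svd_dims:
        if sd > min(Y.shape[0] // 2, Y.shape[1]):
            continue
        for id_ in candidate_ica_dims:
            if id_ > sd:
                continue
            rep = split_half_reproducibility(Y, sd, id_, n_splits=n_splits, seed=seed)
            table[(sd, id_)] = rep
            count = int((rep > r_threshold).sum())
            key = (count, -id_, -sd)
            if best is None or key > best[0]:
                best = (key, sd, id_, rep)

    diagnostics = {f"svd{sd}_ica{id_}": rep.tolist() for (sd, id_), rep in table.items()}
    if best is None or best[0][0] == 0:
        p = Y.shape[1]
        return IcaReduction(svd_dim=0, ica_dim=0,
                            weight_vectors=np.empty((0, p)),
                            subject_scores=np.empty((Y.shape[0], 0)),
                            reproducibility=None, diagnostics=diagnostics)
    _, sd, id_, rep = best
    fit = fit_reduction(Y, sd, id_, seed=seed)
    fit.reproducibility = rep
    fit.diagnostics = diagnostics
    return fit
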