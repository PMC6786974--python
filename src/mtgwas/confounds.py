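"""Imaging-confound construction.

Builds the full acquisition-confound design matrix from age, sex, head
motion, head-size scaling, coil/head position variables and data-driven
scanner-drift components, with the two per-variable treatments used
throughout: rank-based inverse-normal (quantile) normalization and
median/MAD outlier removal.  With 2 motion measures, 4 position variables
and 10 drift components the assembled matrix has 53 columns:

    [ s  a a2 a*s a2*s  ai ai2 ai*s ai2*s  mm mm2  hm  qm qm2  dm
      mi  hi  qi qi2  di ]

where subscript i marks quantile normalization, m marks median-outlier
removal, squares are taken on demeaned variables, and any remaining missing
value is set to zero after every column has been demeaned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy.stats import norm, rankdata

from .errors import AlignmentError, DegenerateInputError, ParameterError
from .simdata import CovariateSet

__all__ = [
    "ConfoundMatrix", "quantile_normalize", "median_outlier_filter",
    "drift_confounds", "assemble_confounds", "predicted_column_count",
]


@dataclass
class ConfoundMatrix:
    """Named confound design matrix with per-column provenance.

    provenance entries record (variable, transform, power, interaction)
    so the recipe behind each column can be serialized alongside it.
    """

    samples: list[str]
    names: list[str]
    values: np.ndarray
    provenance: list[dict]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.names)):
            raise ParameterError("values shape must be (n_samples, n_columns)")

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "sample_id", self.samples)
        return df


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def quantile_normalize(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform: non-missing values map to
    Gaussian quantiles Phi^-1(r/(n+1)) with average ranks for ties; missing
    values stay missing."""
    x = np.asarray(x, dtype=float)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 2:
        raise DegenerateInputError("quantile_normalize needs >= 2 non-missing values")
    vals = x[obs]
    if np.nanmax(vals) == np.nanmin(vals):
        raise DegenerateInputError("quantile_normalize on a constant vector")
    ranks = rankdata(vals, method="average")
    out = np.full_like(x, np.nan)
    out[obs] = norm.ppf(ranks / (n + 1))
    return out


def median_outlier_filter(x: np.ndarray, n_mads: float = 5.0) -> np.ndarray:
    """Set entries farther than ``n_mads`` median-absolute-deviations from
    the median to missing.  A zero MAD (degenerate scale) removes nothing and
    emits a warning."""
    x = np.asarray(x, dtype=float)
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        raise DegenerateInputError("median_outlier_filter needs >= 2 non-missing values")
    med = np.median(x[obs])
    mad = np.median(np.abs(x[obs] - med))
    out = x.copy()
    if mad == 0:
        warnings.warn("MAD is zero; no outliers removed", stacklevel=2)
        return out
    out[np.abs(x - med) > n_mads * mad] = np.nan
    return out


# ---------------------------------------------------------------------------
# Scanner-drift components
# ---------------------------------------------------------------------------

def _soft_impute(X: np.ndarray, threshold: float, tol: float = 1e-4,
                 max_iter: int = 200) -> np.ndarray:
    """Iterative SVD completion with soft-thresholded singular values."""
    miss = np.isnan(X)
    col_means = np.nanmean(X, axis=0)
    filled = np.where(miss, col_means[None, :], X)
    prev = filled.copy()
    for _ in range(max_iter):
        u, s, vt = np.linalg.svd(filled, full_matrices=False)
        s_shrunk = np.maximum(s - threshold, 0.0)
        low_rank = (u * s_shrunk) @ vt
        filled = np.where(miss, low_rank, X)
        delta = np.linalg.norm(filled - prev) / max(np.linalg.norm(prev), 1e-12)
        if delta < tol:
            break
        prev = filled.copy()
    return filled


def _impute_low_rank(X: np.ndarray, seed: int = 0) -> np.ndarray:
    """Complete a matrix by soft-impute, choosing the threshold (the (r+1)-th
    singular value, over candidate ranks r) by held-out reconstruction
    error."""
    miss = np.isnan(X)
    if not miss.any():
        return X.copy()
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(~miss)
    n_hold = max(1, int(0.1 * len(obs_idx)))
    hold = obs_idx[rng.choice(len(obs_idx), size=n_hold, replace=False)]
    X_train = X.copy()
    X_train[hold[:, 0], hold[:, 1]] = np.nan

    base = np.where(np.isnan(X_train), np.nanmean(X_train, axis=0)[None, :], X_train)
    s_full = np.linalg.svd(base, compute_uv=False)
    ranks = [r for r in (1, 2, 3, 5, 8, 10) if r < len(s_full)]
    best_rank, best_err = ranks[0], np.inf
    truth_vals = X[hold[:, 0], hold[:, 1]]
    for r in ranks:
        rec = _soft_impute(X_train, threshold=s_full[r])
        err = np.mean((rec[hold[:, 0], hold[:, 1]] - truth_vals) ** 2)
        if err < best_err:
            best_rank, best_err = r, err
    return _soft_impute(X, threshold=s_full[best_rank])


def _spline_smooth(y: np.ndarray, dates: np.ndarray, scale: float) -> np.ndarray:
    """Smooth a column as a function of scan date: least-squares cubic
    B-spline with interior knots spaced ``scale`` days, fitted to per-date
    means and evaluated at every sample's date."""
    order = np.argsort(dates, kind="stable")
    ds, ys = dates[order], y[order]
    uniq, inverse, counts = np.unique(ds, return_inverse=True, return_counts=True)
    means = np.bincount(inverse, weights=ys) / counts
    lo, hi = uniq[0], uniq[-1]
    knots = np.arange(lo + scale, hi - scale / 2, scale)
    # cubic needs > 4 + len(knots) points; drop knots if dates are sparse
    k = 3 if len(uniq) >= 8 else 1
    while len(knots) > 0 and len(uniq) < len(knots) + k + 1:
        knots = knots[::2]
    try:
        spl = interpolate.LSQUnivariateSpline(uniq, means, knots, w=np.sqrt(counts), k=k)
        return spl(dates)
    except ValueError:
        # fall back to the date-mean trend when the spline system is singular
        return means[inverse][np.argsort(order, kind="stable")]


def drift_confounds(idp_matrix: np.ndarray, scan_dates: np.ndarray,
                    n_components: int = 10, smoothing_scale: float = 90.0,
                    seed: int = 0) -> np.ndarray:
    """Data-driven slow-drift basis from a phenotype matrix.

    Pipeline: limit outliers per column (5xMAD), complete the matrix by
    low-rank soft-threshold imputation, smooth each column against scan date
    with a penalized spline at the given scale (days), then return the top
    ``n_components`` principal-component score columns, each normalized to
    unit length.
    """
    X = np.asarray(idp_matrix, dtype=float)
    dates = np.asarray(scan_dates, dtype=float)
    n, p = X.shape
    if dates.shape != (n,):
        raise ParameterError("one scan date per sample required")
    if n < n_components + 1:
        raise ParameterError(f"need at least {n_components + 1} samples")
    if dates.max() - dates.min() <= smoothing_scale:
        raise ParameterError("scan dates must span more than the smoothing scale")

    # operate in scan-date order so the result is equivariant to sample order
    order = np.argsort(dates, kind="stable")
    X = X[order]
    dates_sorted = dates[order]

    limited = np.column_stack([
        _safe_outlier_limit(X[:, j]) for j in range(p)
    ])
    completed = _impute_low_rank(limited, seed=seed)
    smoothed = np.column_stack([
        _spline_smooth(completed[:, j], dates_sorted, smoothing_scale)
        for j in range(p)
    ])
    smoothed -= smoothed.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(smoothed, full_matrices=False)
    scores = u[:, :n_components]
    # canonical sign: largest-magnitude entry positive
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    norms = np.linalg.norm(scores, axis=0)
    norms[norms == 0] = 1.0
    scores = scores / norms
    out = np.empty_like(scores)
    out[order] = scores  # back to the caller's sample order
    return out


def _safe_outlier_limit(col: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return median_outlier_filter(col)
        except DegenerateInputError:
            return col.copy()


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def predicted_column_count(n_motion: int = 2, n_position: int = 4,
                           n_drift: int = 10) -> int:
    """Deterministic column count of the assembled recipe."""
    return (1 + 8 + 2 * n_motion + 1 + 2 * n_position + n_drift
            + n_motion + 1 + 2 * n_position + n_drift)


def _demean(x: np.ndarray) -> np.ndarray:
    m = np.nanmean(x)
    return x - m


def _qn(x: np.ndarray) -> np.ndarray:
    return _demean(quantile_normalize(x))


def _mof(x: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _demean(median_outlier_filter(x))


def assemble_confounds(cov: CovariateSet, motion: np.ndarray | None = None,
                       drift: np.ndarray | None = None,
                       extra: dict[str, np.ndarray] | None = None) -> ConfoundMatrix:
    """Assemble the full confound design matrix from a covariate set,
    motion measures (N x n_motion; defaults to the covariate set's rest/task
    pair) and a drift basis (N x n_drift).

    Variables are demeaned before powers and sex interactions are formed;
    after assembly every column is demeaned again and missing values are set
    to zero, yielding a zero-mean, full-rank design (53 columns for the
    default 2 motion / 4 position / 10 drift layout).
    """
    n = len(cov.samples)
    motion = cov.motion if motion is None else np.asarray(motion, dtype=float)
    if motion.ndim == 1:
        motion = motion[:, None]
    if drift is None:
        drift = np.empty((n, 0))
    drift = np.asarray(drift, dtype=float)
    for name, arr in (("motion", motion), ("drift", drift)):
        if arr.shape[0] != n:
            raise AlignmentError(
                f"{name} has {arr.shape[0]} rows but the covariate set has {n} samples")

    cols: list[np.ndarray] = []
    names: list[str] = []
    prov: list[dict] = []

    def add(vec, name, variable, transform, power=1, interaction="none"):
        cols.append(np.asarray(vec, dtype=float))
        names.append(name)
        prov.append({"variable": variable, "transform": transform,
                     "power": power, "interaction": interaction})

    s = _demean(cov.sex)
    add(s, "sex", "sex", "raw")

    a = _demean(cov.age)
    ai = _qn(cov.age)
    for v, tag, tr in ((a, "age", "raw"), (ai, "age_i", "quantile")):
        add(v, tag, "age", tr)
        add(v * v, f"{tag}_sq", "age", tr, power=2)
        add(v * s, f"{tag}_x_sex", "age", tr, interaction="xsex")
        add(v * v * s, f"{tag}_sq_x_sex", "age", tr, power=2, interaction="xsex")

    n_motion = motion.shape[1]
    for j in range(n_motion):
        mm = _mof(motion[:, j])
        add(mm, f"motion{j + 1}_m", f"motion{j + 1}", "median-outlier")
        add(mm * mm, f"motion{j + 1}_m_sq", f"motion{j + 1}", "median-outlier", power=2)

    hm = _mof(cov.head_size_scaling)
    add(hm, "head_m", "head_size_scaling", "median-outlier")

    n_position = cov.position_vars.shape[1]
    for j in range(n_position):
        qm = _mof(cov.position_vars[:, j])
        add(qm, f"pos{j + 1}_m", f"position{j + 1}", "median-outlier")
        add(qm * qm, f"pos{j + 1}_m_sq", f"position{j + 1}", "median-outlier", power=2)

    n_drift = drift.shape[1]
    for j in range(n_drift):
        add(_mof(drift[:, j]), f"drift{j + 1}_m", f"drift{j + 1}", "median-outlier")

    for j in range(n_motion):
        add(_qn(motion[:, j]), f"motion{j + 1}_i", f"motion{j + 1}", "quantile")

    add(_qn(cov.head_size_scaling), "head_i", "head_size_scaling", "quantile")

    for j in range(n_position):
        qi = _qn(cov.position_vars[:, j])
        add(qi, f"pos{j + 1}_i", f"position{j + 1}", "quantile")
        add(qi * qi, f"pos{j + 1}_i_sq", f"position{j + 1}", "quantile", power=2)

    for j in range(n_drift):
        add(_qn(drift[:, j]), f"drift{j + 1}_i", f"drift{j + 1}", "quantile")

    if extra:
        for name, vec in extra.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape[0] != n:
                raise AlignmentError(f"extra column {name!r} has wrong length")
            add(_demean(vec), name, name, "raw")

    X = np.column_stack(cols)
    X = X - np.nanmean(X, axis=0, keepdims=True)
    X = np.where(np.isnan(X), 0.0, X)

    expected = predicted_column_count(n_motion, n_position, n_drift) + (len(extra) if extra else 0)
    assert X.shape[1] == expected, f"recipe produced {X.shape[1]} columns, expected {expected}"
    return ConfoundMatrix(samples=list(cov.samples), names=names, values=X,
                          provenance=prov)
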