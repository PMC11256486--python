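"""Peptide-matrix preprocessing: missingness filter, iterative-PCA
imputation, quantile normalization, batch correction and protein roll-up."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import ConfigurationError, FeatureMatrix, experimental_samples

log = logging.getLogger(__name__)


def filter_missing(pep: FeatureMatrix, meta: pd.DataFrame,
                   threshold: float = 0.36) -> FeatureMatrix:
    """Remove peptides exceeding the per-group missingness threshold.

    A peptide is retained iff its missing fraction is <= ``threshold`` within
    *every* treatment group (the stricter of the two readings of a per-group
    rule; configurable via the threshold).
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    exp = experimental_samples(meta)
    keep = pd.Series(True, index=pep.feature_ids)
    for group, block in exp.groupby("group"):
        cols = [s for s in block["sample_id"] if s in pep.sample_ids]
        if not cols:
            raise ConfigurationError(f"treatment group {group!r} has no samples")
        frac = pep.values[cols].isna().mean(axis=1)
        keep &= frac <= threshold
    log.info("missingness filter (<= %.0f%% per group): %d -> %d peptides",
             100 * threshold, pep.values.shape[0], int(keep.sum()))
    return pep.select(keep)


def impute_ipca(pep: FeatureMatrix, n_components: int = 2,
                tol: float = 1e-5, max_iter: int = 200) -> FeatureMatrix:
    """Fill missing cells by iterative principal component analysis.

    Missing cells are initialised with the feature (row) mean, then the loop
    {column-centre -> rank-k SVD reconstruction -> re-fill missing cells}
    repeats until the largest absolute change in any imputed cell drops
    below ``tol`` or ``max_iter`` is reached.  Observed cells are never
    altered; the procedure is deterministic (mean initialisation, exact SVD).
    """
    X = pep.values.to_numpy(float).copy()
    mask = np.isnan(X)  # True where missing
    if not mask.any():
        return pep.copy()
    if mask.all(axis=1).any() or mask.all(axis=0).any():
        raise ValueError("matrix has an all-missing row or column; "
                         "imputation requires >= 1 observed value per row and column")
    if n_components >= min(X.shape):
        raise ValueError("n_components must be smaller than both matrix dimensions")

    row_means = np.nanmean(X, axis=1, keepdims=True)
    filled = np.where(mask, np.broadcast_to(row_means, X.shape), X)
    delta = np.inf
    for it in range(max_iter):
        col_means = filled.mean(axis=0, keepdims=True)
        centred = filled - col_means
        U, s, Vt = np.linalg.svd(centred, full_matrices=False)
        recon = (U[:, :n_components] * s[:n_components]) @ Vt[:n_components] + col_means
        new_imputed = recon[mask]
        delta = np.max(np.abs(new_imputed - filled[mask]))
        filled[mask] = new_imputed
        if delta < tol:
            break
    else:
        log.warning("iPCA imputation did not converge in %d iterations "
                    "(final delta %.3g)", max_iter, delta)
    out = pep.copy()
    out.values.iloc[:, :] = filled
    return out


def quantile_normalize(pep: FeatureMatrix) -> FeatureMatrix:
    """Force every sample (column) onto the common reference distribution.

    The reference is the row-wise mean of the column order statistics; each
    value maps to the reference quantile of its within-column rank, with ties
    resolved by averaging tied ranks (mid-rank).  Idempotent up to ties.
    """
    X = pep.values.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("quantile normalization requires a complete matrix")
    n = X.shape[0]
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    positions = np.arange(1, n + 1)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, ref)
    res = pep.copy()
    res.values.iloc[:, :] = out
    return res


def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    """Treatment-coded dummies, first level as reference, constant levels dropped."""
    levels = sorted(series.astype(str).unique())
    cols = {}
    for lv in levels[1:]:
        cols[f"{prefix}[{lv}]"] = (series.astype(str) == lv).astype(float).to_numpy()
    return pd.DataFrame(cols, index=series.index)


def remove_batch(pep: FeatureMatrix, meta: pd.DataFrame,
                 batch_factors: tuple[str, ...] = ("plex", "centre"),
                 protect: tuple[str, ...] = ("group",)) -> FeatureMatrix:
    """Regress out batch effects while protecting the biological contrast.

    Per feature, ordinary least squares is fit on the combined design
    [intercept | protected factors | batch dummies] and only the fitted batch
    contribution is subtracted, leaving group-related variation untouched.
    With a single batch level the corresponding dummies vanish and the matrix
    is returned unchanged.
    """
    exp = experimental_samples(meta).loc[list(pep.sample_ids)]
    protected = [pd.DataFrame({"intercept": np.ones(len(exp))}, index=exp.index)]
    for f in protect:
        protected.append(_dummies(exp[f], f))
    Xp = pd.concat(protected, axis=1)
    Xb = pd.concat([_dummies(exp[f], f) for f in batch_factors], axis=1)
    if Xb.shape[1] == 0:
        return pep.copy()
    X = pd.concat([Xp, Xb], axis=1)
    A = X.to_numpy(float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify aliased columns by incremental rank
        aliased, cur = [], np.empty((A.shape[0], 0))
        for name, col in zip(X.columns, A.T):
            trial = np.column_stack([cur, col])
            if np.linalg.matrix_rank(trial) == cur.shape[1]:
                aliased.append(name)
            else:
                cur = trial
        raise ConfigurationError(
            f"batch design is rank deficient; aliased column(s): {aliased} "
            "(batch factors perfectly confounded with the protected design)"
        )
    Y = pep.values.to_numpy(float)
    beta, *_ = np.linalg.lstsq(A, Y.T, rcond=None)
    batch_part = A[:, Xp.shape[1]:] @ beta[Xp.shape[1]:]
    res = pep.copy()
    res.values.iloc[:, :] = Y - batch_part.T
    return res


def filter_unique_groups(pep: FeatureMatrix) -> FeatureMatrix:
    """Keep peptides whose accession set names exactly one protein group."""
    keep = pep.group_unique
    if not keep.any():
        log.warning("no peptide maps to a unique protein group; result is empty")
    log.info("unique-group filter: %d -> %d peptides",
             pep.values.shape[0], int(keep.sum()))
    return pep.select(keep)


def _trimmed_mean(values: np.ndarray, trim: float) -> np.ndarray:
    """Column-wise symmetric trimmed mean; plain mean below 3 rows."""
    m = values.shape[0]
    k = int(np.floor(trim * m)) if m >= 3 else 0
    if k == 0:
        return values.mean(axis=0)
    s = np.sort(values, axis=0)
    return s[k:m - k].mean(axis=0)


def rollup_proteins(pep: FeatureMatrix, trim_fraction: float = 0.20) -> FeatureMatrix:
    """Summarise uniquely-mapped peptides into protein values by trimmed mean.

    ``trim_fraction`` is removed from each tail (count floored); proteins
    with fewer than three peptides fall back to the plain mean.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    if not pep.group_unique.all():
        raise ValueError("protein roll-up requires uniquely mapped peptides "
                         "(run filter_unique_groups first)")
    accession = pep.groups.map(lambda s: next(iter(s)))
    rows, index = [], []
    for acc, block_idx in pep.values.groupby(accession, sort=True).groups.items():
        vals = pep.values.loc[block_idx].to_numpy(float)
        rows.append(_trimmed_mean(vals, trim_fraction))
        index.append(acc)
    values = pd.DataFrame(rows, index=pd.Index(index, name="protein"),
                          columns=pep.sample_ids)
    groups = pd.Series({acc: frozenset([acc]) for acc in index})
    log.info("protein roll-up (trim %.0f%%): %d peptides -> %d proteins",
             100 * trim_fraction, pep.values.shape[0], len(index))
    return FeatureMatrix(values, groups)
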