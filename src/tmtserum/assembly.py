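"""PSM-level data assembly: filtering, impurity correction, median scaling,
reference ratios, and roll-up to a peptide matrix.

The stages mirror the standard TMT 11-plex reporter-ion workflow: keep only
rank-1 PSMs that carry a protein-group accession and acceptable isolation
interference, invert the label isotope-impurity mixing, equalise channel
medians within each plex, express every experimental channel as a log2 ratio
to the plex's pooled-reference channel, and summarise PSMs of the same
peptide sequence by their median.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import (
    CHANNELS,
    ConfigurationError,
    FeatureMatrix,
    FormatError,
    experimental_samples,
    reference_channels,
    split_groups,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Impurity matrix
# ---------------------------------------------------------------------------

def identity_impurity() -> pd.DataFrame:
    """11x11 identity impurity matrix (correction becomes a no-op).

    Reagent-lot impurity values are vendor-certificate data; when no
    certificate is supplied the correction is the identity.
    """
    return pd.DataFrame(np.eye(len(CHANNELS)), index=CHANNELS, columns=CHANNELS)


def read_impurity_matrix(path) -> pd.DataFrame:
    """Read an 11x11 impurity matrix TSV (rows = observed, cols = true channel)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    validate_impurity_matrix(mat)
    return mat.loc[list(CHANNELS), list(CHANNELS)]


def validate_impurity_matrix(mat: pd.DataFrame) -> None:
    if set(mat.index) != set(CHANNELS) or set(mat.columns) != set(CHANNELS):
        raise FormatError("impurity matrix must have the 11 channel labels "
                          "as both rows and columns")
    arr = mat.loc[list(CHANNELS), list(CHANNELS)].to_numpy(float)
    if (arr < 0).any():
        raise FormatError("impurity coefficients must be non-negative")
    if (arr.sum(axis=0) > 1.0 + 1e-6).any():
        raise FormatError("impurity matrix columns must sum to <= 1")


# ---------------------------------------------------------------------------
# (i)-(ii) PSM filtering
# ---------------------------------------------------------------------------

def filter_psms(psm: pd.DataFrame, interference_threshold: float = 45.0) -> pd.DataFrame:
    """Keep rank-1 PSMs with an accession and tolerable isolation interference.

    A record is retained when its protein-group field is non-empty, its
    confidence rank is 1 (redundant matches removed upstream at 1 % FDR are
    trusted, not recomputed), and its isolation interference is at or below
    the threshold.  Records with *missing* interference are retained; the
    boundary value itself (e.g. exactly 45 %) is retained.
    """
    if not 0 <= interference_threshold <= 100:
        raise ValueError("interference threshold must be in [0, 100]")
    has_acc = psm["protein_groups"].astype(str).str.strip() != ""
    rank1 = psm["rank"].fillna(1) == 1
    interf_ok = psm["interference"].isna() | (
        psm["interference"] <= interference_threshold
    )
    keep = has_acc & rank1 & interf_ok
    log.info(
        "PSM filter: %d in, %d out (no accession: %d, redundant: %d, "
        "interference > %g%%: %d)",
        len(psm), int(keep.sum()), int((~has_acc).sum()), int((~rank1).sum()),
        int((~interf_ok).sum()), interference_threshold,
    )
    if keep.sum() == 0:
        log.warning("PSM filter removed every record")
    return psm.loc[keep].copy()


# ---------------------------------------------------------------------------
# (iii) isotope impurity correction
# ---------------------------------------------------------------------------

def correct_impurities(psm: pd.DataFrame, impurity: pd.DataFrame) -> pd.DataFrame:
    """Invert reporter-channel isotope cross-contamination.

    The observed intensity vector o of each PSM satisfies o = M x where M is
    the impurity matrix (rows = observed channel, columns = true channel) and
    x the true intensities.  Missing channels are excluded from the solve by
    deleting their row and column; negative solution components are clamped
    to zero.  Rows are grouped by missingness pattern so each distinct
    sub-matrix is factorised once.
    """
    validate_impurity_matrix(impurity)
    M = impurity.loc[list(CHANNELS), list(CHANNELS)].to_numpy(float)
    if abs(np.linalg.det(M)) < 1e-12:
        raise np.linalg.LinAlgError("impurity matrix is singular")
    out = psm.copy()
    if np.allclose(M, np.eye(len(CHANNELS))):
        return out
    inten = out[list(CHANNELS)].to_numpy(float)
    obs = ~np.isnan(inten)
    patterns = {}
    for i, row in enumerate(map(tuple, obs)):
        patterns.setdefault(row, []).append(i)
    for pattern, rows in patterns.items():
        idx = np.flatnonzero(pattern)
        if idx.size == 0:
            continue
        sub = M[np.ix_(idx, idx)]
        y = inten[np.ix_(rows, idx)]
        x = np.linalg.solve(sub, y.T).T
        inten[np.ix_(rows, idx)] = np.clip(x, 0.0, None)
    out[list(CHANNELS)] = inten
    return out


# ---------------------------------------------------------------------------
# (iv) median scaling and reference ratios
# ---------------------------------------------------------------------------

def median_scale(psm: pd.DataFrame) -> pd.DataFrame:
    """Equalise reporter-channel medians within each plex.

    Each channel's intensities are multiplied by (grand median of the plex's
    channel medians) / (that channel's median), after which all channel
    medians within a plex coincide — the operation is idempotent.  Channels
    with no observed intensity in a plex are left unscaled with a warning.
    """
    out = psm.copy()
    for plex, block_idx in out.groupby("plex").groups.items():
        block = out.loc[block_idx, list(CHANNELS)]
        medians = block.median(axis=0, skipna=True)
        if medians.isna().any():
            empty = list(medians.index[medians.isna()])
            log.warning("plex %s: channel(s) %s have no observed intensities; "
                        "left unscaled", plex, empty)
        grand = medians.median(skipna=True)
        factors = grand / medians
        factors = factors.fillna(1.0)
        out.loc[block_idx, list(CHANNELS)] = block.to_numpy() * factors.to_numpy()
    return out


def compute_ratios(psm: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Log2 ratios of experimental channels to the plex reference pool.

    Returns a table with columns ``peptide``, ``protein_groups``, ``plex``
    and one column per experimental sample id; cells for samples outside a
    PSM's plex are missing, as are ratios whose numerator or denominator is
    missing or zero (log of zero is undefined — zeros propagate to missing
    here by design).  The reference channel itself is dropped.
    """
    refs = reference_channels(meta)
    exp = experimental_samples(meta)
    plexes = psm["plex"].astype(str).unique()
    missing_ref = [p for p in plexes if p not in {str(k) for k in refs}]
    if missing_ref:
        raise ConfigurationError(f"plex(es) without a reference_pool channel: {missing_ref}")
    orphans = [
        (p, ch) for p in plexes for ch in CHANNELS
        if ch != refs[p] and not (
            (exp["plex"].astype(str) == p) & (exp["channel"] == ch)
        ).any()
    ]
    if orphans:
        log.info("channels without experimental sample (ignored): %s", orphans)

    sample_cols = list(exp["sample_id"])
    out = psm[["peptide", "protein_groups", "plex"]].copy()
    ratio = pd.DataFrame(np.nan, index=psm.index, columns=sample_cols)
    for plex, block_idx in psm.groupby("plex").groups.items():
        ref_ch = refs[str(plex)]
        denom = psm.loc[block_idx, ref_ch].to_numpy(float)
        denom = np.where(denom > 0, denom, np.nan)
        in_plex = exp[exp["plex"].astype(str) == str(plex)]
        for _, srow in in_plex.iterrows():
            num = psm.loc[block_idx, srow["channel"]].to_numpy(float)
            num = np.where(num > 0, num, np.nan)
            ratio.loc[block_idx, srow["sample_id"]] = np.log2(num / denom)
    return pd.concat([out, ratio], axis=1)


# ---------------------------------------------------------------------------
# (v) peptide roll-up
# ---------------------------------------------------------------------------

def rollup_peptides(psm_ratios: pd.DataFrame) -> FeatureMatrix:
    """Median of PSM log2 ratios per peptide sequence and sample.

    The median is taken over observed values only; a cell with no observed
    PSM stays missing.  Each peptide's protein-group set is the union over
    its contributing PSMs, so shared peptides can be recognised downstream.
    """
    sample_cols = [c for c in psm_ratios.columns
                   if c not in ("peptide", "protein_groups", "plex")]
    grouped = psm_ratios.groupby("peptide", sort=True)
    values = grouped[sample_cols].median()
    groups = grouped["protein_groups"].agg(
        lambda col: frozenset().union(*(split_groups(a) for a in col))
    )
    log.info("peptide roll-up: %d PSMs -> %d peptides x %d samples",
             len(psm_ratios), values.shape[0], values.shape[1])
    return FeatureMatrix(values, groups)
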