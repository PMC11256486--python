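"""Covariate-adjusted differential abundance with empirical-Bayes moderated
t-statistics, the variance-adaptive fold-change threshold and significance
classification.

Per feature a linear model is fit with recovery group (NR vs SR) as the
contrast of interest and the clinical covariates adjusted for; residual
variances are then shrunk toward a pooled prior estimated by moment matching
on the log scale (digamma/trigamma inversion), yielding moderated t
statistics with d0 + d_g degrees of freedom.  The fold-change threshold is
data-adaptive: log2(FCT) = multiplier x median per-feature SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .datamodel import FeatureMatrix, experimental_samples

#: Reference levels for treatment coding (the contrast coefficient is then
#: NR minus SR: positive logFC = higher in NR).
REFERENCE_LEVELS = {
    "group": "SR",
    "injury_level": "paraplegia",
    "centre": "Toledo",
    "sex": "female",
    "ais_grade": "A",
}

# TMT plex appears both in the batch-correction stage and here: retaining it
# in the model accounts for the degrees of freedom the correction consumed,
# which keeps the null distribution of the moderated t calibrated (centre is
# likewise used in both stages).
PEPTIDE_COVARIATES = ("injury_level", "centre", "plex", "sex", "age",
                      "storage_days")
PROTEIN_COVARIATES = PEPTIDE_COVARIATES + ("ais_grade",)


@dataclass
class DesignSpec:
    """Model specification: NR-vs-SR contrast plus adjustment covariates."""

    covariates: tuple[str, ...] = PEPTIDE_COVARIATES
    contrast: str = "group"

    def build(self, meta: pd.DataFrame, sample_ids) -> pd.DataFrame:
        """Design matrix (samples x terms) with treatment coding.

        Categorical covariates use the reference levels in
        :data:`REFERENCE_LEVELS`; continuous covariates (age, storage time)
        are mean-centred so the intercept stays interpretable.
        """
        exp = experimental_samples(meta).loc[list(sample_ids)]
        cols = {"intercept": np.ones(len(exp))}
        lv = sorted(set(exp[self.contrast].astype(str)))
        ref = REFERENCE_LEVELS.get(self.contrast)
        for level in [x for x in lv if x != ref]:
            cols[f"{self.contrast}[{level}]"] = (
                exp[self.contrast].astype(str) == level
            ).astype(float).to_numpy()
        for cov in self.covariates:
            vals = exp[cov]
            if pd.api.types.is_numeric_dtype(vals):
                cols[cov] = (vals - vals.mean()).to_numpy(float)
            else:
                ref = REFERENCE_LEVELS.get(cov)
                levels = sorted(set(vals.astype(str)))
                if ref not in levels:
                    ref = levels[0]
                for level in [x for x in levels if x != ref]:
                    cols[f"{cov}[{level}]"] = (
                        vals.astype(str) == level
                    ).astype(float).to_numpy()
        return pd.DataFrame(cols, index=exp.index)

    @property
    def contrast_column(self) -> str:
        return f"{self.contrast}[NR]"


@dataclass
class LinearFits:
    """Per-feature ordinary least-squares results for one contrast."""

    feature_ids: pd.Index
    logfc: np.ndarray          # contrast coefficient (NR vs SR, log2)
    sigma2: np.ndarray         # residual variance s^2
    df_resid: float            # residual degrees of freedom n - rank(X)
    stdev_unscaled: float      # u: SE of the contrast per unit residual SD


def fit_models(mat: FeatureMatrix, meta: pd.DataFrame,
               design: DesignSpec | None = None) -> LinearFits:
    """Fit the covariate-adjusted linear model to every feature.

    The matrix must be complete.  Returns the NR-vs-SR coefficient (logFC),
    residual variance and degrees of freedom per feature, plus the unscaled
    standard error of the contrast (identical across features since the
    design is shared).
    """
    design = design or DesignSpec()
    X = design.build(meta, mat.sample_ids)
    A = X.to_numpy(float)
    n, p = A.shape
    rank = np.linalg.matrix_rank(A)
    if rank < p:
        aliased, cur = [], np.empty((n, 0))
        for name, col in zip(X.columns, A.T):
            if np.linalg.matrix_rank(np.column_stack([cur, col])) == cur.shape[1]:
                aliased.append(name)
            else:
                cur = np.column_stack([cur, col])
        raise ValueError(f"design matrix is rank deficient; aliased term(s): {aliased}")
    Y = mat.values.to_numpy(float)
    if np.isnan(Y).any():
        raise ValueError("fit_models requires a complete (imputed) matrix")
    XtX_inv = np.linalg.inv(A.T @ A)
    B = Y @ A @ XtX_inv.T          # features x p
    resid = Y - B @ A.T
    df_resid = n - rank
    sigma2 = (resid ** 2).sum(axis=1) / df_resid
    j = list(X.columns).index(design.contrast_column)
    return LinearFits(
        feature_ids=mat.feature_ids,
        logfc=B[:, j],
        sigma2=sigma2,
        df_resid=float(df_resid),
        stdev_unscaled=float(np.sqrt(XtX_inv[j, j])),
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation
# ---------------------------------------------------------------------------

def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


@dataclass
class ModeratedFit:
    """Moderated-t results: shrunken variances and per-feature inference."""

    feature_ids: pd.Index
    logfc: np.ndarray
    prior_df: float            # d0
    prior_var: float           # s0^2
    post_var: np.ndarray       # s~^2 = (d0 s0^2 + d s^2) / (d0 + d)
    df_total: float            # d0 + d_g
    t: np.ndarray
    p: np.ndarray
    adj_p: np.ndarray = field(default=None)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "logFC": self.logfc,
            "t": self.t,
            "p": self.p,
            "adj_p": self.adj_p,
        }, index=self.feature_ids)


def moderate(fits: LinearFits, prior_df: float | None = None) -> ModeratedFit:
    """Shrink residual variances and compute moderated t and p values.

    The prior (d0, s0^2) is estimated by moment matching the theoretical
    distribution of log s^2 (digamma mean correction, trigamma inversion for
    the excess dispersion).  When the observed log-variances show no excess
    dispersion the prior df is infinite and every posterior variance equals
    the pooled value.  ``prior_df`` overrides the estimate (0 disables
    moderation, ``numpy.inf`` forces full pooling).
    """
    s2 = np.asarray(fits.sigma2, float)
    d = fits.df_resid
    positive = s2 > 0
    if positive.sum() == 0:
        raise ValueError("all residual variances are zero; moderation undefined")

    z = np.log(s2[positive])
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    if prior_df is None:
        evar = z.var(ddof=1) - polygamma(1, d / 2.0) if z.size > 1 else -1.0
        if evar > 0:
            d0 = 2.0 * trigamma_inverse(evar)
            s02 = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            # no excess dispersion: infinite prior df, geometric-mean prior
            d0 = np.inf
            s02 = float(np.exp(z.mean()))
    else:
        d0 = float(prior_df)
        if d0 == 0:
            s02 = float(np.exp(z.mean()))
        elif np.isinf(d0):
            s02 = float(np.exp(z.mean()))
        else:
            s02 = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))

    if np.isinf(d0):
        post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        post = s2.copy()
        df_total = d
    else:
        post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits.logfc / (fits.stdev_unscaled * np.sqrt(post))
    if np.isinf(df_total):
        from scipy.stats import norm
        p = 2.0 * norm.sf(np.abs(t))
    else:
        p = 2.0 * t_dist.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return ModeratedFit(
        feature_ids=fits.feature_ids, logfc=fits.logfc,
        prior_df=float(d0), prior_var=s02, post_var=post,
        df_total=float(df_total), t=t, p=p, adj_p=bh_adjust(p),
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Variance-adaptive fold-change threshold and classification
# ---------------------------------------------------------------------------

@dataclass
class DEThresholds:
    """Significance thresholds: alpha, data-adaptive FCT, optional FDR cut."""

    median_sd: float
    fct_multiplier: float
    fct: float
    alpha: float
    fdr: float | None = None

    @property
    def fct_rounded(self) -> float:
        return float(np.round(self.fct, 1))

    @property
    def log2_fct(self) -> float:
        return self.fct_multiplier * self.median_sd


def compute_fct(mat: FeatureMatrix | pd.DataFrame | np.ndarray,
                multiplier: float = 1.47, alpha: float = 0.05,
                fdr: float | None = None) -> DEThresholds:
    """Fold-change threshold adapted to the data's median variability.

    median_sd is the median over features of the per-feature sample standard
    deviation; the threshold is FCT = 2^(multiplier x median_sd) — e.g. a
    median SD of 0.4375 gives 2^0.643 = 1.56, reported rounded to 1.6.
    """
    if isinstance(mat, FeatureMatrix):
        values = mat.values.to_numpy(float)
    else:
        values = np.asarray(getattr(mat, "values", mat), float)
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples per feature to compute SDs")
    sds = np.nanstd(values, axis=1, ddof=1)
    median_sd = float(np.nanmedian(sds))
    return DEThresholds(median_sd=median_sd, fct_multiplier=multiplier,
                        fct=float(2.0 ** (multiplier * median_sd)),
                        alpha=alpha, fdr=fdr)


def fct_from_median_sd(median_sd: float, multiplier: float = 1.47) -> float:
    """FCT = 2^(multiplier x median SD) for an externally supplied SD."""
    return float(2.0 ** (multiplier * median_sd))


CLASS_LABELS = ("significant_and_fc", "significant_only", "fc_only", "neither")


def classify(fit: ModeratedFit, thr: DEThresholds) -> pd.DataFrame:
    """Four-way significance classes plus direction and fold enrichment.

    ``significant_and_fc`` requires p <= alpha and |logFC| >= log2(FCT);
    positive logFC counts as NR-enriched, negative as SR-enriched.  When the
    thresholds carry an FDR level, ``passes_fdr`` additionally marks the
    BH-adjusted subset.
    """
    logfc = np.asarray(fit.logfc, float)
    sig = fit.p <= thr.alpha
    fc = np.abs(logfc) >= np.log2(thr.fct)
    cls = np.where(sig & fc, "significant_and_fc",
                   np.where(sig, "significant_only",
                            np.where(fc, "fc_only", "neither")))
    out = pd.DataFrame({
        "logFC": logfc,
        "fold": [logfc_to_fold(x) for x in logfc],
        "direction": np.where(logfc > 0, "NR", np.where(logfc < 0, "SR", "none")),
        "t": fit.t,
        "p": fit.p,
        "adj_p": fit.adj_p,
        "class": cls,
    }, index=fit.feature_ids)
    if thr.fdr is not None:
        out["passes_fdr"] = (out["class"] == "significant_and_fc") & \
            (out["adj_p"] <= thr.fdr)
    return out


def summarize_classes(classified: pd.DataFrame) -> dict:
    """Counts per class and per direction among the regulated set."""
    reg = classified[classified["class"] == "significant_and_fc"]
    counts = {c: int((classified["class"] == c).sum()) for c in CLASS_LABELS}
    counts["regulated_NR"] = int((reg["direction"] == "NR").sum())
    counts["regulated_SR"] = int((reg["direction"] == "SR").sum())
    if "passes_fdr" in classified:
        counts["passes_fdr"] = int(classified["passes_fdr"].sum())
    return counts


def logfc_to_fold(logfc: float) -> float:
    """Absolute fold change 2^|logFC|, rounded half-even to 2 decimals."""
    return float(np.round(2.0 ** abs(float(logfc)), 2))
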