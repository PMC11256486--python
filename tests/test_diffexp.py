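import numpy as np
import pandas as pd
import pytest

from tmtserum import (
    DesignSpec,
    bh_adjust,
    classify,
    compute_fct,
    fct_from_median_sd,
    fit_models,
    logfc_to_fold,
    moderate,
)
from tmtserum.datamodel import FeatureMatrix
from tmtserum.diffexp import LinearFits, trigamma_inverse
from scipy.special import polygamma

from test_preprocess import fm, group_meta

#: Published serum proteins regulated between recovery groups:
#: (gene, log2 fold change NR vs SR, printed absolute fold).  The printed
#: fold column was derived from unrounded logFC, so recomputation from the
#: printed logFC agrees to ~0.011 (rounding of both columns).
TABLE2 = [
    ("CALU", -1.047, 2.07), ("SERPINE1", -1.144, 2.21), ("CTSW", -0.735, 1.66),
    ("RAP1B/RAP1A", -0.700, 1.62), ("ANGPT1", -0.748, 1.68),
    ("ARHGAP35", -1.587, 3.0), ("FKBP4", -0.945, 1.92), ("FHOD1", -0.794, 1.73),
    ("B4GALT7", -0.979, 1.97), ("CNDP1", -0.713, 1.64), ("PIN1", -1.158, 2.23),
    ("TCN2", -0.700, 1.62), ("AGER", 0.968, 1.96), ("DEFA1/DEFA3", 1.147, 2.21),
    ("ITPA", 0.826, 1.77), ("BPIFB2", 1.419, 2.67), ("UPB1", 0.806, 1.75),
    ("ADM", 0.689, 1.61), ("RACK1", 1.067, 2.09), ("STXBP5", 0.897, 1.86),
    ("LSM1", 0.922, 1.89), ("OLR1", 1.125, 2.18), ("CTSG", 0.973, 1.96),
    ("CD300A", 0.900, 1.86),
]


# ---------------------------------------------------------------------------
# Linear models
# ---------------------------------------------------------------------------

def test_two_group_exact_fit_logfc_and_zero_variance():
    meta = group_meta(2, 2)
    mat = fm([[1.0, 1.0, 0.0, 0.0]], samples=["S1", "S2", "S3", "S4"])
    fits = fit_models(mat, meta, DesignSpec(covariates=()))
    assert fits.logfc[0] == pytest.approx(1.0)
    assert fits.sigma2[0] == pytest.approx(0.0, abs=1e-20)


def test_covariate_orthogonal_to_group_leaves_logfc_unchanged():
    meta = group_meta(4, 4)
    # age varies orthogonally to group: same values in both groups
    meta.loc[meta.role == "experimental", "age"] = [30, 40, 50, 60] * 2
    rng = np.random.default_rng(0)
    mat = fm(rng.normal(size=(10, 8)))
    plain = fit_models(mat, meta, DesignSpec(covariates=()))
    with_cov = fit_models(mat, meta, DesignSpec(covariates=("age",)))
    np.testing.assert_allclose(plain.logfc, with_cov.logfc, atol=1e-10)


def test_fit_models_matches_normal_equations_oracle():
    meta = group_meta(10, 6, plexes=2)
    rng = np.random.default_rng(7)
    mat = fm(rng.normal(size=(25, 16)))
    spec = DesignSpec(covariates=("injury_level", "centre", "sex", "age",
                                  "storage_days"))
    fits = fit_models(mat, meta, spec)
    X = spec.build(meta, mat.sample_ids).to_numpy()
    j = list(spec.build(meta, mat.sample_ids).columns).index("group[NR]")
    for g in range(25):
        y = mat.values.iloc[g].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (X.shape[0] - X.shape[1])
        assert abs(beta[j] - fits.logfc[g]) < 1e-10
        assert abs(s2 - fits.sigma2[g]) < 1e-10


def test_fit_models_rejects_rank_deficient_design():
    meta = group_meta(4, 4)
    meta.loc[meta.role == "experimental", "injury_level"] = np.where(
        meta.loc[meta.role == "experimental", "group"] == "NR",
        "tetraplegia", "paraplegia")  # aliased with group
    mat = fm(np.zeros((3, 8)))
    with pytest.raises(ValueError, match="aliased"):
        fit_models(mat, meta, DesignSpec(covariates=("injury_level",)))


# ---------------------------------------------------------------------------
# Moderation
# ---------------------------------------------------------------------------

def _fits(s2, logfc=None, df=10.0, u=0.5):
    s2 = np.asarray(s2, float)
    return LinearFits(pd.Index([f"F{i}" for i in range(s2.size)]),
                      logfc if logfc is not None else np.ones_like(s2),
                      s2, df, u)


def test_identical_variances_give_no_shrinkage():
    fits = _fits([0.25] * 50)
    mod = moderate(fits)
    assert mod.prior_var == pytest.approx(0.25)
    ordinary_t = fits.logfc / (0.5 * np.sqrt(0.25))
    np.testing.assert_allclose(mod.t, ordinary_t, rtol=1e-12)


def test_zero_prior_df_limit_equals_ordinary_t():
    rng = np.random.default_rng(2)
    fits = _fits(rng.chisquare(10, 40) / 10 * 0.04)
    mod = moderate(fits, prior_df=0.0)
    ordinary_t = fits.logfc / (fits.stdev_unscaled * np.sqrt(fits.sigma2))
    np.testing.assert_allclose(mod.t, ordinary_t, rtol=1e-12)
    assert mod.df_total == fits.df_resid


def test_shrinkage_ordering():
    rng = np.random.default_rng(3)
    s2 = 0.04 * 4 / rng.chisquare(4, 200)
    mod = moderate(_fits(s2))
    below = s2 < mod.prior_var
    assert (mod.post_var[below] > s2[below]).all()
    assert (mod.post_var[~below] < s2[~below]).all()
    assert np.all(mod.post_var <= np.maximum(s2, mod.prior_var) + 1e-15)
    assert np.all(mod.post_var >= np.minimum(s2, mod.prior_var) - 1e-15)


def test_prior_recovery_from_simulated_variances():
    # variances drawn from the scaled inverse-chi-square model with known
    # hyper-parameters; the moment-matching estimator must recover them
    d0_true, s02_true, d = 4.0, 0.04, 21.0
    d0_est, s02_est = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        sigma2 = s02_true * d0_true / rng.chisquare(d0_true, 200)
        s2 = sigma2 * rng.chisquare(d, 200) / d
        mod = moderate(_fits(s2, df=d))
        d0_est.append(mod.prior_df)
        s02_est.append(mod.prior_var)
    assert abs(np.median(d0_est) - d0_true) / d0_true < 0.30
    assert abs(np.median(s02_est) - s02_true) / s02_true < 0.15


def test_moderate_rejects_all_zero_variances():
    with pytest.raises(ValueError, match="zero"):
        moderate(_fits([0.0] * 20))


def test_trigamma_inverse_roundtrip():
    for y in (0.1, 1.0, 5.0, 40.0):
        assert trigamma_inverse(float(polygamma(1, y))) == pytest.approx(y, rel=1e-6)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_step_up_arithmetic():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                               [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([0.5, 0.5, 0.5]), [0.5, 0.5, 0.5])
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
    adj = bh_adjust(np.linspace(0.001, 1.0, 50))
    assert (np.diff(adj[np.argsort(np.linspace(0.001, 1.0, 50))]) >= -1e-15).all()
    with pytest.raises(ValueError):
        bh_adjust([0.0, 0.5])


# ---------------------------------------------------------------------------
# Fold-change threshold
# ---------------------------------------------------------------------------

def test_fct_from_published_median_sd_rounds_to_protein_threshold():
    assert fct_from_median_sd(0.4375) == pytest.approx(2 ** (1.47 * 0.4375))
    # features constructed so each sample SD is exactly 0.4375
    vals = np.zeros((5, 2))
    vals[:, 1] = 0.4375 * np.sqrt(2)
    thr = compute_fct(vals, multiplier=1.47)
    assert thr.median_sd == pytest.approx(0.4375)
    assert thr.fct_rounded == 1.6


def test_fct_zero_variance_and_inverse():
    assert fct_from_median_sd(0.0) == 1.0
    # FCT = 1.8 corresponds to median SD log2(1.8)/1.47
    sd = np.log2(1.8) / 1.47
    assert fct_from_median_sd(sd) == pytest.approx(1.8)
    assert sd == pytest.approx(0.577, abs=1e-3)


# ---------------------------------------------------------------------------
# Classification and fold conversion
# ---------------------------------------------------------------------------

def _mod(logfc, p):
    logfc = np.asarray(logfc, float)
    p = np.asarray(p, float)
    return type("M", (), {
        "feature_ids": pd.Index([f"F{i}" for i in range(p.size)]),
        "logfc": logfc, "p": p, "adj_p": bh_adjust(p), "t": logfc,
    })()


def test_classify_rules_and_directions():
    from tmtserum.diffexp import DEThresholds
    thr = DEThresholds(median_sd=0.4375, fct_multiplier=1.47,
                       fct=1.6, alpha=0.05, fdr=0.1)
    res = classify(_mod([1.2, 0.0, 0.9, 0.1], [0.001, 0.20, 0.30, 0.01]), thr)
    assert res.loc["F0", "class"] == "significant_and_fc"
    assert res.loc["F0", "direction"] == "NR"
    assert res.loc["F1", "class"] == "neither"
    assert res.loc["F2", "class"] == "fc_only"
    assert res.loc["F3", "class"] == "significant_only"
    assert (res[res["passes_fdr"]]["class"] == "significant_and_fc").all()


def test_classify_counts_invariant_to_feature_order():
    from tmtserum.diffexp import DEThresholds, summarize_classes
    rng = np.random.default_rng(1)
    logfc, p = rng.normal(size=200), rng.uniform(0.001, 1, 200)
    thr = DEThresholds(0.4, 1.47, 1.5, 0.05, 0.1)
    a = summarize_classes(classify(_mod(logfc, p), thr))
    perm = rng.permutation(200)
    b = summarize_classes(classify(_mod(logfc[perm], p[perm]), thr))
    assert a == b


@pytest.mark.parametrize("logfc,fold", [(1.58, 2.99), (0.0, 1.00), (-1.047, 2.07)])
def test_logfc_to_fold_spot_values(logfc, fold):
    assert logfc_to_fold(logfc) == fold


def test_published_table_folds_recompute_from_logfc():
    for gene, logfc, fold in TABLE2:
        recomputed = 2.0 ** abs(logfc)
        assert abs(recomputed - fold) <= 0.011, (gene, recomputed, fold)
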