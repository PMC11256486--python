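"""ELISA plate reduction: standard-curve fitting (5PL or linear, chosen by
r^2), interpolation with dilution factors, CLSI-style detection limits,
duplicate-CV quality control and Shapiro-gated group comparisons.

The five-parameter logistic calibration model is

    OD(x) = d + (a - d) / (1 + (x / c)^b)^g

with a the zero-concentration (lower) asymptote, d the upper asymptote,
c the inflection-scale concentration, b the slope and g the asymmetry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import mannwhitneyu, shapiro, ttest_ind

log = logging.getLogger(__name__)

PLATE_COLUMNS = ("well", "role", "analyte", "nominal_conc", "od",
                 "replicate", "dilution", "group")


def read_plate(path) -> pd.DataFrame:
    plate = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("nominal_conc", "od", "dilution"):
        plate[col] = pd.to_numeric(plate[col].replace("", np.nan),
                                   errors="coerce")
    validate_plate(plate)
    return plate


def write_plate(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, sep="\t", index=False, na_rep="")


def validate_plate(plate: pd.DataFrame) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate missing column(s): {', '.join(missing)}")
    samples = plate[plate["role"] == "sample"]
    if len(samples):
        reps = samples.groupby("well").size()
        if (reps < 2).any():
            bad = list(reps.index[reps < 2])
            raise ValueError(f"sample(s) without duplicate wells: {bad}")
    stds = plate[plate["role"] == "standard"]
    if len(stds) and stds["nominal_conc"].nunique() < 4:
        raise ValueError("standards must span >= 4 concentrations")


# ---------------------------------------------------------------------------
# Calibration curve
# ---------------------------------------------------------------------------

def five_pl(x, a, d, c, b, g):
    """5PL response: d + (a - d) / (1 + (x/c)^b)^g."""
    x = np.asarray(x, float)
    return d + (a - d) / (1.0 + (x / c) ** b) ** g


def five_pl_inverse(od, a, d, c, b, g):
    """Concentration at a given OD (defined strictly between the asymptotes)."""
    lo, hi = min(a, d), max(a, d)
    if not lo < od < hi:
        raise ValueError(f"OD {od} outside the invertible range ({lo}, {hi})")
    return c * (((a - d) / (od - d)) ** (1.0 / g) - 1.0) ** (1.0 / b)


@dataclass
class CalibrationCurve:
    """Fitted standard curve; the higher-r^2 of 5PL and linear is selected."""

    model: str                      # "5PL" | "linear"
    params: tuple                   # (a, d, c, b, g) or (slope, intercept)
    r2: float
    r2_5pl: float | None
    r2_linear: float
    conc_range: tuple[float, float]  # [lowest, highest standard]

    @property
    def meets_acceptance(self) -> bool:
        """Acceptance rule r^2 > 0.99 for the selected model."""
        return self.r2 > 0.99

    def predict(self, conc):
        if self.model == "5PL":
            return five_pl(conc, *self.params)
        slope, intercept = self.params
        return slope * np.asarray(conc, float) + intercept

    def inverse(self, od: float) -> float:
        if self.model == "5PL":
            return float(five_pl_inverse(od, *self.params))
        slope, intercept = self.params
        if slope == 0:
            raise ValueError("flat linear curve is not invertible")
        return float((od - intercept) / slope)


def _r2(observed, fitted) -> float:
    observed = np.asarray(observed, float)
    ss_res = float(((observed - fitted) ** 2).sum())
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def fit_curve(concentrations, ods) -> CalibrationCurve:
    """Fit both 5PL and simple linear models, return the higher-r^2 one.

    Requires >= 5 positive standard concentrations for the 5PL branch; on
    5PL non-convergence the linear fit is returned with a warning.
    """
    x = np.asarray(concentrations, float)
    y = np.asarray(ods, float)
    if np.any(x <= 0):
        raise ValueError("standard concentrations must be positive")
    order = np.argsort(x)
    x, y = x[order], y[order]

    slope, intercept = np.polyfit(x, y, 1)
    r2_lin = _r2(y, slope * x + intercept)

    r2_5pl, params5 = None, None
    if x.size >= 5:
        a0, d0 = float(y[0]), float(y[-1])
        if abs(a0 - d0) < 1e-12:
            d0 = a0 + 1.0
        c0 = float(np.exp(np.mean(np.log(x))))
        try:
            params5, _ = optimize.curve_fit(
                five_pl, x, y, p0=[a0, d0, c0, 1.0, 1.0],
                maxfev=20000,
            )
            r2_5pl = _r2(y, five_pl(x, *params5))
        except (RuntimeError, ValueError) as err:
            log.warning("5PL fit did not converge (%s); falling back to linear", err)

    if r2_5pl is not None and r2_5pl >= r2_lin:
        curve = CalibrationCurve("5PL", tuple(float(p) for p in params5),
                                 r2_5pl, r2_5pl, r2_lin,
                                 (float(x.min()), float(x.max())))
    else:
        curve = CalibrationCurve("linear", (float(slope), float(intercept)),
                                 r2_lin, r2_5pl, r2_lin,
                                 (float(x.min()), float(x.max())))
    if not curve.meets_acceptance:
        log.warning("calibration r^2 = %.4f fails the r^2 > 0.99 acceptance rule",
                    curve.r2)
    return curve


def interpolate(curve: CalibrationCurve, od: float,
                dilution_factor: float = 1.0) -> dict:
    """Back-calculate a sample concentration from its OD.

    Returns the concentration (curve inverse x dilution factor) together
    with range flags: ODs outside the 5PL asymptotes are non-invertible,
    concentrations outside [lowest, highest standard] are flagged
    out-of-range.
    """
    try:
        neat = curve.inverse(float(od))
    except ValueError:
        return {"concentration": np.nan, "flag": "non_invertible"}
    conc = neat * dilution_factor
    lo, hi = curve.conc_range
    flag = "ok"
    if neat < lo:
        flag = "below_lowest_standard"
    elif neat > hi:
        flag = "above_highest_standard"
    return {"concentration": float(conc), "flag": flag}


# ---------------------------------------------------------------------------
# Detection limits (CLSI-style, on the OD scale)
# ---------------------------------------------------------------------------

@dataclass
class DetectionLimits:
    lob: float   # mean_blank + 1.645 sd_blank
    lod: float   # lob + 1.645 sd_lowest_standard

    def flag_below_lod(self, ods) -> np.ndarray:
        """True where a sample OD falls below the LoD (re-assay concentrated)."""
        return np.asarray(ods, float) < self.lod


def detection_limits(blank_ods, lowest_standard_ods) -> DetectionLimits:
    """LoB = mean_blank + 1.645 SD_blank; LoD = LoB + 1.645 SD_lowest_standard."""
    blanks = np.asarray(blank_ods, float)
    lowest = np.asarray(lowest_standard_ods, float)
    if blanks.size < 2 or lowest.size < 2:
        raise ValueError("need >= 2 blank and >= 2 lowest-standard replicates")
    lob = float(blanks.mean() + 1.645 * blanks.std(ddof=1))
    lod = float(lob + 1.645 * lowest.std(ddof=1))
    return DetectionLimits(lob=lob, lod=lod)


# ---------------------------------------------------------------------------
# Duplicate CV QC
# ---------------------------------------------------------------------------

def qc_cv(plate: pd.DataFrame) -> tuple[pd.Series, float]:
    """Coefficient of variation (SD/mean of replicate ODs) per sample well group.

    Returns the per-sample CVs and their plate mean.  Samples with a single
    replicate get NaN and a warning (CV undefined).
    """
    samples = plate[plate["role"] == "sample"]
    cvs = {}
    for sid, block in samples.groupby("well"):
        ods = block["od"].to_numpy(float)
        if ods.size < 2:
            log.warning("sample %s has a single replicate; CV undefined", sid)
            cvs[sid] = np.nan
            continue
        cvs[sid] = float(ods.std(ddof=1) / ods.mean())
    series = pd.Series(cvs, name="cv")
    return series, float(series.dropna().mean()) if series.notna().any() else np.nan


# ---------------------------------------------------------------------------
# Shapiro-gated two-group comparison
# ---------------------------------------------------------------------------

def compare_groups(x, y, shapiro_alpha: float = 0.05,
                   force: str | None = None) -> dict:
    """Two-group comparison with a normality gate.

    Shapiro-Wilk runs per group at alpha 0.05; if either group rejects (or
    is degenerate/constant, where normality cannot be assessed) the groups
    are compared with a two-sided Mann-Whitney test (exact for small
    tie-free samples), otherwise with Student's t-test.  ``force`` overrides
    the gate ("student_t" or "mann_whitney").  Returns the test name,
    statistic and p-value plus the gate details.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need >= 3 values per group")

    def _shapiro_p(v):
        if np.ptp(v) == 0:
            return 0.0  # constant: normality not assumable
        return float(shapiro(v).pvalue)

    px, py = _shapiro_p(x), _shapiro_p(y)
    normal = px >= shapiro_alpha and py >= shapiro_alpha
    if force is not None and force not in ("student_t", "mann_whitney"):
        raise ValueError("force must be 'student_t' or 'mann_whitney'")
    use_t = normal if force is None else force == "student_t"
    if use_t:
        res = ttest_ind(x, y)
        name = "student_t"
    else:
        small = x.size <= 25 and y.size <= 25
        ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        method = "exact" if (small and not ties) else "asymptotic"
        res = mannwhitneyu(x, y, alternative="two-sided", method=method)
        name = "mann_whitney"
    return {
        "test": name,
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "shapiro_p": (px, py),
        "normal": normal,
    }
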