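"""FDR-controlled power and sample-size computation for two-sample designs.

Implements the fixed-point construction of Liu-et-al.-style sample-size
calculation under false-discovery-rate control: find the per-comparison
significance level alpha_c at which the expected mix of true-null and
true-alternative rejections attains the target FDR,

    pi0 * alpha_c / ((1 - pi0) * P(alpha_c)) = f / (1 - f),

where P(alpha) is the average power of a two-sided two-sample t-test with
df = 2(n-1) and noncentrality Delta / (sigma * sqrt(2/n)).  The module also
provides a qvalue-style spline estimator of pi0, the proportion of true
nulls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import nct
from scipy.stats import t as t_dist


@dataclass
class PowerSpec:
    """Inputs of the FDR-controlled power computation.

    effect_size is the true group difference on the log2 scale, sigma the
    common within-group SD, pi0 the proportion of true nulls among all
    features, fdr the target false discovery rate and n the per-group sample
    size (equal group sizes assumed).
    """

    effect_size: float = 0.68
    sigma: float = 0.4375
    pi0: float = 0.66
    fdr: float = 0.10
    n: int = 10

    def __post_init__(self):
        if not 0 < self.pi0 < 1:
            raise ValueError("pi0 must be in (0, 1)")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def df(self) -> int:
        return 2 * (self.n - 1)

    @property
    def ncp(self) -> float:
        return self.effect_size / (self.sigma * np.sqrt(2.0 / self.n))


@dataclass
class PowerResult:
    alpha_c: float   # per-comparison significance level solving the constraint
    power: float     # average power at alpha_c
    df: int
    ncp: float
    converged: bool = True


def _power_two_sided(alpha: float, df: int, ncp: float) -> float:
    """P(|T| > t_{1-alpha/2, df}) under the noncentral t.

    Extreme tail quantiles can make the noncentral-t CDF return NaN or
    underflow; those are floored at a tiny positive value so the bisection
    objective stays finite.
    """
    tc = t_dist.ppf(1.0 - alpha / 2.0, df)
    p = nct.sf(tc, df, ncp) + nct.cdf(-tc, df, ncp)
    if not np.isfinite(p) or p <= 0.0:
        return np.nan  # numerical failure in the extreme tail
    return float(min(p, 1.0))


def fdr_power(spec: PowerSpec) -> PowerResult:
    """Average power of the FDR-controlled two-sample test.

    Solves the fixed point for alpha_c by bisection (bracket (1e-12, 0.5),
    tolerance 1e-10) and returns the noncentral-t power at the solution.
    When no root exists in the bracket (pi0 too high for the target FDR) the
    result reports power 0 with ``converged=False``.
    """
    df, ncp = spec.df, spec.ncp
    target = spec.fdr / (1.0 - spec.fdr)
    ratio = spec.pi0 / (1.0 - spec.pi0)

    def g(alpha: float) -> float:
        p = _power_two_sided(alpha, df, ncp)
        if np.isnan(p):
            p = max(alpha, 1e-300)  # conservative: power >= size
        return ratio * alpha / p - target

    lo, hi = 1e-12, 0.5
    # step past the region where the extreme noncentral-t tail is unevaluable
    while np.isnan(_power_two_sided(lo, df, ncp)) and lo < 1e-4:
        lo *= 10.0
    if g(hi) < 0:
        # so few true nulls that the target FDR is met even at the bracket
        # top: the constraint does not bind, alpha_c is the unconstrained cap
        return PowerResult(alpha_c=hi, power=_power_two_sided(hi, df, ncp),
                           df=df, ncp=ncp)
    if g(lo) > 0:
        warnings.warn("no per-comparison alpha in (1e-12, 0.5) satisfies the "
                      "FDR constraint for this spec", stacklevel=2)
        return PowerResult(alpha_c=np.nan, power=0.0, df=df, ncp=ncp,
                           converged=False)
    alpha = optimize.brentq(g, lo, hi, xtol=1e-10)
    return PowerResult(alpha_c=float(alpha),
                       power=_power_two_sided(alpha, df, ncp),
                       df=df, ncp=ncp)


def min_n_for_power(spec: PowerSpec, target_power: float,
                    n_max: int = 1000) -> int:
    """Smallest per-group n whose FDR-controlled power reaches the target."""
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0, 1)")
    base = {k: getattr(spec, k) for k in
            ("effect_size", "sigma", "pi0", "fdr")}
    for n in range(2, n_max + 1):
        with warnings.catch_warnings():
            # tiny n can make the constraint infeasible; that's expected
            # mid-search and simply means "keep increasing n"
            warnings.simplefilter("ignore")
            res = fdr_power(PowerSpec(n=n, **base))
        if res.converged and res.power >= target_power:
            return n
    raise RuntimeError(f"target power {target_power} not reached by n = {n_max}")


def power_table(spec: PowerSpec, n_values) -> "list[tuple[int, float]]":
    """(n, power) pairs over a range of per-group sizes."""
    base = {k: getattr(spec, k) for k in ("effect_size", "sigma", "pi0", "fdr")}
    return [(int(n), fdr_power(PowerSpec(n=int(n), **base)).power)
            for n in n_values]


# ---------------------------------------------------------------------------
# pi0 estimation (qvalue-style smoother)
# ---------------------------------------------------------------------------

def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond boundary knots).

    With K knots the basis has K-1 columns (excluding the intercept), so
    K = 4 knots give the 3-df fit used by the pi0 smoother.
    """
    K = len(knots)
    xi = knots

    def d(k, v):
        return (np.clip(v - xi[k], 0, None) ** 3
                - np.clip(v - xi[K - 1], 0, None) ** 3) / (xi[K - 1] - xi[k])

    cols = [x]
    for k in range(K - 2):
        cols.append(d(k, x) - d(K - 2, x))
    return np.column_stack(cols)


def estimate_pi0(p, lambda_grid=None) -> float:
    """Estimate the proportion of true nulls from a p-value vector.

    Computes pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over the grid
    lambda = 0.05, 0.10, ..., 0.95, fits a 3-df natural cubic spline and
    takes its value at the largest lambda, clipped to (0, 1].  Warns below
    100 p-values, where the estimate is unstable.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size < 100:
        warnings.warn("fewer than 100 p-values; pi0 estimate is unstable",
                      stacklevel=2)
    lam = (np.arange(0.05, 0.96, 0.05) if lambda_grid is None
           else np.asarray(lambda_grid, float))
    m = p.size
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    knots = np.quantile(lam, [0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
    B = np.column_stack([np.ones_like(lam), _natural_spline_basis(lam, knots)])
    coef, *_ = np.linalg.lstsq(B, pi0_lam, rcond=None)
    at_max = np.column_stack([
        np.ones(1), _natural_spline_basis(np.array([lam.max()]), knots)
    ]) @ coef
    return float(np.clip(at_max[0], np.nextafter(0, 1), 1.0))
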