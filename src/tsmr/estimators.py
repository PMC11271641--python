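"""Causal-effect estimators for two-sample Mendelian randomization.

All three estimators operate on per-SNP Wald ratios theta_j = beta_out_j /
beta_exp_j with first-order standard errors se_out_j / |beta_exp_j|:

* IVW — the inverse-variance-weighted mean of the ratios, equivalent to a
  weighted regression of outcome on exposure effects through the origin.
  The fixed-effect SE is 1/sqrt(sum of weights); the multiplicative
  random-effects model scales it by sqrt(Q/(k-1)) when Cochran's Q exceeds
  its degrees of freedom.
* MR-Egger — weighted regression WITH an intercept after orienting each SNP
  to a positive exposure effect; the intercept estimates average directional
  pleiotropy, the slope is the causal estimate under the InSIDE assumption.
* Weighted median — the interpolated 50th percentile of the weighted
  empirical ratio distribution; consistent while valid instruments carry
  more than half the weight.  Its SE comes from a seeded parametric
  bootstrap.

Estimates are reported on the log odds-ratio scale with OR and 95% CI by
exponentiation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import AnalysisError, ConfigurationError, InsufficientInstrumentsError
from .summary_io import HarmonizedSet

logger = logging.getLogger(__name__)

#: 97.5th percentile of the standard normal, fixed for reproducible CIs
Z_975 = 1.959964

METHOD_WALD = "wald"
METHOD_IVW_FIXED = "ivw_fixed"
METHOD_IVW_RANDOM = "ivw_random"
METHOD_EGGER = "egger"
METHOD_WEIGHTED_MEDIAN = "weighted_median"


@dataclass
class MREstimate:
    """A causal-effect estimate on the log odds-ratio scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    or_: float
    ci_low: float
    ci_high: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None
    overdispersion_scale: float | None = None

    def sign_category(self) -> int:
        """+1 when the 95% CI sits above the null, -1 below, 0 when it spans it."""
        if self.beta - Z_975 * self.se > 0:
            return 1
        if self.beta + Z_975 * self.se < 0:
            return -1
        return 0


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """(OR, CI low, CI high): exp(beta) with normal-quantile 95% limits."""
    if se < 0:
        raise ConfigurationError("se must be non-negative")
    return math.exp(beta), math.exp(beta - Z_975 * se), math.exp(beta + Z_975 * se)


def wald_ratio(beta_exp: float, beta_out: float, se_out: float) -> tuple[float, float]:
    """Per-SNP causal estimate beta_out/beta_exp with first-order SE se_out/|beta_exp|."""
    if beta_exp == 0:
        raise AnalysisError("Wald ratio undefined for beta_exp = 0")
    if se_out <= 0:
        raise ConfigurationError("se_out must be positive")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def ratio_arrays(hset: HarmonizedSet) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(snp_ids, ratios, ratio SEs) over the kept SNPs with nonzero exposure effect."""
    ids, bx, _, by, sy = hset.arrays()
    nonzero = bx != 0
    if not nonzero.all():
        skipped = [i for i, ok in zip(ids, nonzero) if not ok]
        logger.warning("skipping SNPs with beta_exp = 0: %s", skipped)
    ids = [i for i, ok in zip(ids, nonzero) if ok]
    if not ids:
        raise AnalysisError("no valid Wald ratios: all exposure effects are zero")
    bx, by, sy = bx[nonzero], by[nonzero], sy[nonzero]
    return ids, by / bx, sy / np.abs(bx)


def _normal_pvalue(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _finish(method: str, beta: float, se: float, n_snps: int, **extra) -> MREstimate:
    or_, lo, hi = to_odds_ratio(beta, se)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        pvalue=_normal_pvalue(beta, se),
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        n_snps=n_snps,
        **extra,
    )


def cochran_q_from_ratios(theta: np.ndarray, se_theta: np.ndarray) -> tuple[float, int, float]:
    """Cochran's Q about the fixed-effect IVW mean, with df = k-1 and chi2 p."""
    w = 1.0 / se_theta**2
    beta = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - beta) ** 2))
    df = len(theta) - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw(hset: HarmonizedSet, model: str = "auto") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the per-SNP Wald ratios.

    ``model`` is ``fixed``, ``random`` (multiplicative overdispersion, scale
    floored at 1) or ``auto``: fixed when Cochran's Q p > 0.05, random
    otherwise — the heterogeneity-driven switch used in practice.  A single
    SNP degenerates to its Wald ratio (method ``wald``).
    """
    if model not in ("fixed", "random", "auto"):
        raise ConfigurationError(f"unknown IVW model {model!r}")
    ids, theta, se_theta = ratio_arrays(hset)
    k = len(ids)
    if k == 1:
        return _finish(METHOD_WALD, theta[0], se_theta[0], 1)
    w = 1.0 / se_theta**2
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    q, df, q_p = cochran_q_from_ratios(theta, se_theta)
    scale = math.sqrt(max(1.0, q / df))
    chosen = model if model != "auto" else ("fixed" if q_p > 0.05 else "random")
    if chosen == "fixed":
        return _finish(METHOD_IVW_FIXED, beta, se_fixed, k)
    return _finish(METHOD_IVW_RANDOM, beta, se_fixed * scale, k, overdispersion_scale=scale)


def mr_egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure effects with intercept.

    SNPs are oriented so beta_exp >= 0 before the fit (the intercept is only
    meaningful under a common orientation).  Weights are 1/se_out^2; standard
    errors use multiplicative overdispersion with the scale floored at 1, and
    p-values come from the t distribution with k-2 degrees of freedom.  CIs
    use the normal quantile, as elsewhere.
    """
    ids, bx, _, by, sy = hset.arrays()
    k = len(ids)
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 SNPs, got {k}")
    orient = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * orient, by * orient
    w = 1.0 / sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    # multiplicative overdispersion, floored at 1 (never deflate below homoskedastic)
    scale = max(1.0, float(fit.scale))
    cov = np.asarray(fit.normalized_cov_params) * scale
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    dof = k - 2
    p_slope = float(2.0 * stats.t.sf(abs(slope) / se_slope, dof)) if se_slope > 0 else (1.0 if slope == 0 else 0.0)
    p_int = float(2.0 * stats.t.sf(abs(intercept) / se_int, dof)) if se_int > 0 else (1.0 if intercept == 0 else 0.0)
    or_, lo, hi = to_odds_ratio(slope, se_slope)
    return MREstimate(
        method=METHOD_EGGER,
        beta=slope,
        se=se_slope,
        pvalue=p_slope,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        n_snps=k,
        intercept=intercept,
        intercept_se=se_int,
        intercept_pvalue=p_int,
        overdispersion_scale=math.sqrt(scale),
    )


def _weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(theta)
    t, w = theta[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w)
    p_mid = s - w / 2.0  # cumulative midpoint positions
    return float(np.interp(0.5, p_mid, t))


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate interpolates the weighted empirical ratio distribution
    at probability 0.5 under inverse-variance weights.  The SE is the standard
    deviation of the estimate over ``n_boot`` resamples of (beta_exp,
    beta_out) from normal distributions centred at the observed values with
    the observed SEs; the p-value is normal.  Fully deterministic given
    ``seed``.
    """
    if n_boot < 1:
        raise ConfigurationError("n_boot must be positive")
    if n_boot < 100:
        logger.warning("n_boot = %d is small; bootstrap SE will be noisy", n_boot)
    ids, bx, sx, by, sy = hset.arrays()
    k = len(ids)
    if k < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 SNPs, got {k}")
    if (bx == 0).any():
        raise AnalysisError("weighted median undefined with beta_exp = 0 instruments")
    theta = by / bx
    w = (bx / sy) ** 2  # 1/se_ratio^2
    point = _weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    ests = np.empty(n_boot)
    for i in range(n_boot):
        bxi = bx_b[i]
        bxi = np.where(bxi == 0, np.finfo(float).tiny, bxi)
        ests[i] = _weighted_median_point(by_b[i] / bxi, (bxi / sy) ** 2)
    se = float(np.std(ests, ddof=1))
    return _finish(METHOD_WEIGHTED_MEDIAN, point, se, k)
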