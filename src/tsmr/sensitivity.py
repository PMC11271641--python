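"""Heterogeneity, pleiotropy and robustness diagnostics.

Covers Cochran's Q across per-SNP ratios, the MR-Egger intercept test,
leave-one-out re-estimation, funnel-plot data with a weighted asymmetry
summary, and an MR-PRESSO-style residual-sum-of-squares global/outlier test
driven by seeded parametric simulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import (
    MREstimate,
    cochran_q_from_ratios,
    ivw,
    mr_egger,
    ratio_arrays,
)
from .exceptions import ConfigurationError, InsufficientInstrumentsError
from .summary_io import HarmonizedSet

logger = logging.getLogger(__name__)


@dataclass
class LooEntry:
    snp_id: str
    estimate: MREstimate
    flagged: bool


@dataclass
class FunnelPoint:
    snp_id: str
    ratio: float
    precision: float


@dataclass
class FunnelData:
    points: list[FunnelPoint]
    asymmetry: float  # weighted skewness of ratios about the IVW estimate


@dataclass
class PressoResult:
    global_rss: float
    global_pvalue: float
    outlier_pvalues: dict[str, float]  # Bonferroni-adjusted
    outliers: list[str]
    estimate_before: MREstimate
    estimate_after: MREstimate
    distortion_pvalue: float | None = None


@dataclass
class SensitivityReport:
    """All diagnostics for one exposure-outcome pair."""

    q_stat: float
    q_df: int
    q_pvalue: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pvalue: float | None = None
    loo: list[LooEntry] = field(default_factory=list)
    funnel: FunnelData | None = None
    presso: PressoResult | None = None


def cochran_q(hset: HarmonizedSet) -> tuple[float, int, float]:
    """Heterogeneity of the per-SNP Wald ratios about the fixed-effect IVW mean.

    Returns (Q, df = k-1, chi-square upper-tail p).  Q near its df indicates
    homogeneous instruments; p < 0.05 motivates the random-effects IVW.
    """
    ids, theta, se_theta = ratio_arrays(hset)
    if len(ids) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 SNPs")
    return cochran_q_from_ratios(theta, se_theta)


def leave_one_out(hset: HarmonizedSet, estimator: str = "ivw", model: str = "auto") -> list[LooEntry]:
    """Re-estimate after excluding each SNP in turn.

    An entry is flagged when its estimate's 95% CI reaches a different
    conclusion about the direction of effect than the all-SNP estimate
    (e.g. the full set excludes the null but the reduced set does not).
    """
    if estimator != "ivw":
        raise ConfigurationError(f"unsupported leave-one-out estimator {estimator!r}")
    kept = hset.kept_records
    if len(kept) < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 SNPs")
    full = ivw(hset, model=model)
    full_cat = full.sign_category()
    out: list[LooEntry] = []
    for rec in kept:
        est = ivw(hset.drop([rec.snp_id]), model=model)
        out.append(LooEntry(rec.snp_id, est, est.sign_category() != full_cat))
    return out


def funnel_data(hset: HarmonizedSet) -> FunnelData:
    """Per-SNP ratio vs precision (1/SE), plus a weighted-skewness asymmetry summary.

    Under no directional pleiotropy or selection, ratios scatter symmetrically
    about the IVW estimate and the asymmetry statistic is near zero.
    """
    ids, theta, se_theta = ratio_arrays(hset)
    points = [FunnelPoint(i, float(t), float(1.0 / s)) for i, t, s in zip(ids, theta, se_theta)]
    if len(ids) < 2:
        return FunnelData(points, 0.0)
    w = 1.0 / se_theta**2
    center = float(np.sum(w * theta) / np.sum(w))
    m2 = float(np.sum(w * (theta - center) ** 2) / np.sum(w))
    m3 = float(np.sum(w * (theta - center) ** 3) / np.sum(w))
    asym = 0.0 if m2 == 0 else m3 / m2**1.5
    return FunnelData(points, asym)


def _loo_ivw_predictions(bx: np.ndarray, theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slope for each SNP, times its beta_exp."""
    sw, swt = np.sum(w), np.sum(w * theta)
    b_loo = (swt - w * theta) / (sw - w)
    return b_loo * bx


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_significance: float = 0.05,
) -> PressoResult:
    """Residual-sum-of-squares pleiotropy test with per-SNP outlier detection.

    The observed global statistic sums, over SNPs, the variance-standardized
    squared difference between each beta_out and its leave-one-out IVW
    prediction.  A null distribution is built from ``n_sim`` seeded parametric
    simulations of beta_out under the no-pleiotropy model; the global p-value
    is the Monte-Carlo tail (1 + exceedances)/(n_sim + 1).  Each SNP's observed
    residual contribution is compared to its simulated distribution and
    Bonferroni-adjusted over k; SNPs below ``outlier_significance`` are
    outliers.  When outliers exist, a distortion p-value compares the change
    in the IVW estimate after their removal to random removals of the same
    size.
    """
    if n_sim < 100:
        raise ConfigurationError("n_sim must be >= 100")
    ids, bx, sx, by, sy = hset.arrays()
    k = len(ids)
    if k < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO not applicable with {k} < 4 SNPs")
    theta = by / bx
    w = (bx / sy) ** 2

    pred = _loo_ivw_predictions(bx, theta, w)
    resid_obs = (by - pred) ** 2 / sy**2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(pred, sy, size=(n_sim, k))
    theta_sim = by_sim / bx
    sw = np.sum(w)
    swt = theta_sim @ w
    b_loo = (swt[:, None] - w * theta_sim) / (sw - w)
    pred_sim = b_loo * bx
    resid_sim = (by_sim - pred_sim) ** 2 / sy**2
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + np.sum(resid_sim >= resid_obs, axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * k)
    outlier_pvalues = {i: float(p) for i, p in zip(ids, p_adj)}
    outliers = [i for i, p in outlier_pvalues.items() if p < outlier_significance]

    est_before = ivw(hset, model="auto")
    distortion_p: float | None = None
    if outliers and k - len(outliers) >= 2:
        est_after = ivw(hset.drop(outliers), model="auto")
        distortion_p = _distortion_pvalue(
            bx, by, sy, np.array([i in outliers for i in ids]), est_before.beta, est_after.beta, rng
        )
    else:
        est_after = est_before
    return PressoResult(
        global_rss=rss_obs,
        global_pvalue=global_p,
        outlier_pvalues=outlier_pvalues,
        outliers=outliers,
        estimate_before=est_before,
        estimate_after=est_after,
        distortion_pvalue=distortion_p,
    )


def _distortion_pvalue(
    bx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    is_outlier: np.ndarray,
    beta_before: float,
    beta_after: float,
    rng: np.random.Generator,
    n_draw: int = 1000,
) -> float:
    """Compare the outlier-removal distortion to random removals of equal size."""
    if beta_after == 0:
        return 1.0
    k = len(bx)
    n_out = int(is_outlier.sum())
    theta = by / bx
    w = (bx / sy) ** 2
    d_obs = abs(beta_before - beta_after) / abs(beta_after)
    exceed = 0
    for _ in range(n_draw):
        drop = rng.choice(k, size=n_out, replace=False)
        keep = np.ones(k, dtype=bool)
        keep[drop] = False
        b = float(np.sum(w[keep] * theta[keep]) / np.sum(w[keep]))
        if beta_after != 0 and abs(beta_before - b) / abs(beta_after) >= d_obs:
            exceed += 1
    return float((1 + exceed) / (n_draw + 1))


def sensitivity_report(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_significance: float = 0.05,
) -> SensitivityReport:
    """Assemble every diagnostic the instrument count allows for one pair."""
    k = hset.n_kept
    q, df, q_p = cochran_q(hset)
    report = SensitivityReport(q_stat=q, q_df=df, q_pvalue=q_p, funnel=funnel_data(hset))
    if k >= 3:
        egger = mr_egger(hset)
        report.egger_intercept = egger.intercept
        report.egger_intercept_se = egger.intercept_se
        report.egger_intercept_pvalue = egger.intercept_pvalue
        report.loo = leave_one_out(hset)
    if k >= 4:
        report.presso = mr_presso(hset, n_sim=n_sim, seed=seed, outlier_significance=outlier_significance)
    else:
        logger.info("MR-PRESSO not applicable (fewer than 4 instruments)")
    return report
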