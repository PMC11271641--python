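"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of a psychiatric-exposure /
cancer-outcome study: per-SNP exposure effects whose standard errors scale
with sample size and allele frequency (the continuous-trait approximation
se = 1/sqrt(2*EAF*(1-EAF)*n)), and outcome effects equal to the causal
effect times the SNP-exposure effect plus an optional pleiotropic term plus
sampling noise.  Case/control imbalance enters through the effective sample
size n_eff = 4/(1/n_cases + 1/n_controls), so cohorts like the panic-disorder
(2,248 cases / 7,992 controls) and colorectal-cancer (636 cases / 455,640
controls) GWAS can be emulated directly.

Pleiotropy scope: with a pleiotropy mode set and ``prop_invalid = 0`` every
instrument receives a pleiotropic effect (the pervasive-pleiotropy scenario
MR-Egger targets, with InSIDE holding by construction); ``prop_invalid > 0``
restricts pleiotropy to that fraction of instruments (the invalid-subset
scenario the weighted median is robust to).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, InputError
from .summary_io import HarmonizedSet, SummaryStatRecord, harmonize

PLEIOTROPY_MODES = ("none", "balanced", "directional")

# non-palindromic allele pairs cycled across SNPs
_ALLELE_PAIRS = [("A", "G"), ("T", "C"), ("A", "C"), ("T", "G")]

_MIN_P = 1e-300  # keep p-values inside (0, 1]


def effective_sample_size(n_cases: int, n_controls: int) -> float:
    """Effective n of a case/control GWAS: 4/(1/n_cases + 1/n_controls)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ConfigurationError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


# Table-style defaults: panic-disorder-like exposure (2,248/7,992) and
# colorectal-cancer-like outcome (636/455,640), as effective sample sizes.
_DEFAULT_N_EXPOSURE = int(round(effective_sample_size(2248, 7992)))  # 7018
_DEFAULT_N_OUTCOME = int(round(effective_sample_size(636, 455_640)))  # 2541


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic exposure-outcome pair.

    Defaults mirror a panic-disorder-to-colorectal-cancer-sized study:
    13 instruments, instrument effects ~ N(0.15, 0.03) on the log-odds scale
    (per-SNP F roughly 25-80 at these sample sizes), EAF ~ U(0.05, 0.95).
    """

    n_snps: int = 13
    causal_beta: float = 0.0
    instrument_beta_dist: tuple[float, float] = (0.15, 0.03)
    eaf_range: tuple[float, float] = (0.05, 0.95)
    n_exposure: int = _DEFAULT_N_EXPOSURE
    n_outcome: int = _DEFAULT_N_OUTCOME
    pleiotropy: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    prop_invalid: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if self.instrument_beta_dist[1] < 0 or self.pleiotropy_sd < 0:
            raise ConfigurationError("sd parameters must be >= 0")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError("eaf_range must satisfy 0 < low < high < 1")
        if not (0.0 <= self.prop_invalid < 1.0):
            raise ConfigurationError("prop_invalid must lie in [0, 1)")
        if self.pleiotropy not in PLEIOTROPY_MODES:
            raise ConfigurationError(f"pleiotropy must be one of {PLEIOTROPY_MODES}")
        if self.n_exposure < 3 or self.n_outcome < 3:
            raise ConfigurationError("sample sizes must be >= 3")


@dataclass
class SimulationTruth:
    """Generative values behind one simulated pair."""

    causal_beta: float
    gamma: np.ndarray  # true SNP-exposure effects
    alpha: np.ndarray  # pleiotropic effects on the outcome
    eaf: np.ndarray
    invalid_ids: list[str] = field(default_factory=list)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(beta) / se), _MIN_P)


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], SimulationTruth]:
    """Draw one synthetic exposure table, outcome table and their ground truth.

    SNPs get non-palindromic alleles and widely spaced positions (one SNP per
    50 Mb slot across 22 chromosomes) so the tables pass cleanly through
    harmonization and distance-based clumping.  Reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_snps
    eaf = rng.uniform(*config.eaf_range, size=k)
    gamma = rng.normal(*config.instrument_beta_dist, size=k)

    se_exp = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_exposure)
    se_out = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_outcome)
    beta_exp = rng.normal(gamma, se_exp)

    alpha = np.zeros(k)
    invalid_idx: np.ndarray = np.array([], dtype=int)
    if config.pleiotropy != "none":
        mean = 0.0 if config.pleiotropy == "balanced" else config.pleiotropy_mean
        if config.prop_invalid > 0:
            m = int(round(config.prop_invalid * k))
            invalid_idx = rng.choice(k, size=m, replace=False)
        else:
            invalid_idx = np.arange(k)
        alpha[invalid_idx] = rng.normal(mean, config.pleiotropy_sd, size=len(invalid_idx))
    beta_out = rng.normal(config.causal_beta * gamma + alpha, se_out)

    p_exp = _two_sided_p(beta_exp, se_exp)
    p_out = _two_sided_p(beta_out, se_out)

    exposure: list[SummaryStatRecord] = []
    outcome: list[SummaryStatRecord] = []
    for j in range(k):
        ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        chrom = str(j % 22 + 1)
        pos = 50_000_000 * (j // 22 + 1)
        common = dict(
            snp_id=f"rs{j + 1}",
            effect_allele=ea,
            other_allele=oa,
            chrom=chrom,
            pos=pos,
            eaf=float(eaf[j]),
        )
        exposure.append(
            SummaryStatRecord(
                beta=float(beta_exp[j]), se=float(se_exp[j]), pvalue=float(p_exp[j]),
                n=config.n_exposure, **common,
            )
        )
        outcome.append(
            SummaryStatRecord(
                beta=float(beta_out[j]), se=float(se_out[j]), pvalue=float(p_out[j]),
                n=config.n_outcome, **common,
            )
        )
    truth = SimulationTruth(
        causal_beta=config.causal_beta,
        gamma=gamma,
        alpha=alpha,
        eaf=eaf,
        invalid_ids=[f"rs{j + 1}" for j in sorted(invalid_idx.tolist())],
    )
    return exposure, outcome, truth


def simulate_harmonized(config: SimulationConfig, exposure_name: str = "exposure",
                        outcome_name: str = "outcome") -> tuple[HarmonizedSet, SimulationTruth]:
    """Simulate a pair and pass it through the real harmonization path."""
    exposure, outcome, truth = simulate_two_sample(config)
    hset = harmonize(exposure, outcome, exposure_name=exposure_name, outcome_name=outcome_name)
    return hset, truth


def inject_outliers(hset: HarmonizedSet, snp_ids: Sequence[str], shift: float) -> HarmonizedSet:
    """Shift beta_out of the named kept SNPs by ``shift``; everything else unchanged."""
    kept_ids = {r.snp_id for r in hset.kept_records}
    unknown = set(snp_ids) - kept_ids
    if unknown:
        raise InputError(f"unknown snp_ids for outlier injection: {sorted(unknown)}")
    targets = set(snp_ids)
    records = [
        replace(r, beta_out=r.beta_out + shift) if r.snp_id in targets and r.kept else replace(r)
        for r in hset.records
    ]
    return HarmonizedSet(hset.exposure_name, hset.outcome_name, records)
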