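"""Multiple-testing correction across exposure-outcome hypothesis families.

The study tests six exposures against each of three outcomes; adjusted
p-values are computed per family with both Benjamini-Hochberg FDR and
Bonferroni.  The default family groups the exposures within each outcome
(m = 6), the grouping that reproduces the published adjusted tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError

FAMILY_CHOICES = ("per_outcome", "per_exposure", "global")


def _check(pvalues: Sequence[float]) -> None:
    for p in pvalues:
        if not (0.0 < p <= 1.0):
            raise ConfigurationError(f"p-values must lie in (0, 1], got {p}")


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    if len(pvalues) == 0:
        return []
    _check(pvalues)
    return list(multipletests(list(pvalues), method="fdr_bh")[1])


def bonferroni(pvalues: Sequence[float]) -> list[float]:
    """min(1, m*p) for each of the m p-values."""
    if len(pvalues) == 0:
        return []
    _check(pvalues)
    return list(multipletests(list(pvalues), method="bonferroni")[1])


@dataclass
class CorrectionTable:
    """Raw and adjusted p-values for every exposure-outcome hypothesis."""

    family: str
    entries: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: exposure, outcome, raw_pvalue, fdr, bonferroni

    def adjusted(self, exposure: str, outcome: str) -> tuple[float, float]:
        row = self.entries[(self.entries.exposure == exposure) & (self.entries.outcome == outcome)]
        if row.empty:
            raise KeyError((exposure, outcome))
        return float(row.fdr.iloc[0]), float(row.bonferroni.iloc[0])

    def wide(self) -> pd.DataFrame:
        """Rows = exposures, (FDR, Bonferroni) column pair per outcome."""
        fdr = self.entries.pivot(index="exposure", columns="outcome", values="fdr")
        bon = self.entries.pivot(index="exposure", columns="outcome", values="bonferroni")
        out = pd.concat({"fdr": fdr, "bonferroni": bon}, axis=1)
        return out.swaplevel(axis=1).sort_index(axis=1)


def correct_family(
    results: pd.DataFrame,
    family: str = "per_outcome",
) -> CorrectionTable:
    """Adjust raw p-values within the chosen hypothesis family.

    ``results`` needs columns exposure, outcome, raw_pvalue.  With
    ``per_outcome`` the m hypotheses in a family are the exposures tested
    against one outcome; ``per_exposure`` groups the outcomes per exposure;
    ``global`` adjusts everything together.
    """
    if family not in FAMILY_CHOICES:
        raise ConfigurationError(f"family must be one of {FAMILY_CHOICES}")
    for col in ("exposure", "outcome", "raw_pvalue"):
        if col not in results.columns:
            raise ConfigurationError(f"results missing column {col!r}")
    df = results[["exposure", "outcome", "raw_pvalue"]].copy()
    group_key = {"per_outcome": "outcome", "per_exposure": "exposure", "global": None}[family]
    df["fdr"] = 0.0
    df["bonferroni"] = 0.0
    groups = [df.index] if group_key is None else [g.index for _, g in df.groupby(group_key, sort=False)]
    for idx in groups:
        raw = df.loc[idx, "raw_pvalue"].tolist()
        df.loc[idx, "fdr"] = bh_fdr(raw)
        df.loc[idx, "bonferroni"] = bonferroni(raw)
    return CorrectionTable(family=family, entries=df.reset_index(drop=True))
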