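"""Instrumental-variable selection and qualification.

A valid genetic instrument must (1) associate with the exposure at genome-wide
significance, (2) be independent of other instruments (LD clumping), and
(3) not act on the outcome through confounders (handled here by a
user-supplied exclusion list standing in for a PhenoScanner-style lookup).
Instrument strength is summarised by the F-statistic computed from the
variance explained, R^2 = 2*EAF*(1-EAF)*beta^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import AnalysisError, ConfigurationError, InputError
from .summary_io import SummaryStatRecord

logger = logging.getLogger(__name__)

#: per-SNP F below or at this value marks a weak instrument (strict >)
WEAK_F_THRESHOLD = 10.0


@dataclass
class InstrumentStrength:
    r2: float
    f: float
    weak: bool
    scorable: bool = True


@dataclass
class InstrumentSet:
    """The qualified instruments for one exposure trait."""

    trait_name: str
    records: list[SummaryStatRecord]
    p_threshold: float
    r2_threshold: float
    window_kb: float
    per_snp_f: dict[str, float] = field(default_factory=dict)
    per_snp_r2: dict[str, float] = field(default_factory=dict)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def min_f(self) -> float | None:
        return min(self.per_snp_f.values()) if self.per_snp_f else None


class LDTable:
    """Pairwise r-squared lookup loaded from a TSV (columns snp_a, snp_b, r2)."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise InputError(f"r2 for ({a}, {b}) must lie in [0, 1], got {r2}")
        self._r2[self._key(a, b)] = float(r2)

    def lookup(self, a: str, b: str) -> float | None:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b))

    @classmethod
    def read(cls, path: str | Path) -> "LDTable":
        df = pd.read_csv(path, sep="\t")
        for col in ("snp_a", "snp_b", "r2"):
            if col not in df.columns:
                raise ConfigurationError(f"LD table {path} missing column {col!r}")
        table = cls()
        for _, row in df.iterrows():
            table.add(str(row["snp_a"]), str(row["snp_b"]), float(row["r2"]))
        return table


def filter_significant(
    records: Sequence[SummaryStatRecord], p_threshold: float
) -> list[SummaryStatRecord]:
    """Keep records with p-value strictly below the threshold, order preserved."""
    if not (0.0 < p_threshold < 1.0):
        raise ConfigurationError("p_threshold must lie in (0, 1)")
    out = [r for r in records if r.pvalue < p_threshold]
    if not out:
        logger.warning("no records pass p < %g; pipeline may report 'no instruments'", p_threshold)
    return out


def ld_clump(
    records: Sequence[SummaryStatRecord],
    ld: LDTable | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
    strict: bool = True,
) -> list[SummaryStatRecord]:
    """Greedy p-value-ordered clumping to approximately independent index SNPs.

    The most significant remaining SNP becomes an index SNP; every other SNP on
    the same chromosome within ``window_kb`` whose r^2 with the index is at or
    above ``r2_threshold`` is removed.  Ties in p-value break by snp_id so the
    result does not depend on input order.  A pair inside the window but absent
    from the LD table raises by default; with ``strict=False`` its r^2 is
    assumed 0 (distance-only fallback) with a warning.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ConfigurationError("r2_threshold must lie in (0, 1]")
    if window_kb <= 0:
        raise ConfigurationError("window_kb must be positive")
    for r in records:
        if r.chrom is None or r.pos is None:
            raise InputError(f"ld_clump requires chrom and pos on every record ({r.snp_id})")

    remaining = sorted(records, key=lambda r: (r.pvalue, r.snp_id))
    kept: list[SummaryStatRecord] = []
    warned_missing = False
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for other in remaining:
            if other.chrom == index.chrom and abs(other.pos - index.pos) <= window_kb * 1000:
                r2 = ld.lookup(index.snp_id, other.snp_id) if ld is not None else None
                if r2 is None:
                    if strict:
                        raise AnalysisError(
                            f"LD r2 missing for in-window pair ({index.snp_id}, {other.snp_id})"
                        )
                    if not warned_missing:
                        logger.warning("missing LD pairs assumed r2 = 0 (strict=False)")
                        warned_missing = True
                    r2 = 0.0
                if r2 >= r2_threshold:
                    continue
            survivors.append(other)
        remaining = survivors
    return kept


def instrument_strength(
    record: SummaryStatRecord, n: int | None = None, k: int = 1
) -> InstrumentStrength:
    """Variance explained and F-statistic for one instrument.

    R^2 = 2*EAF*(1-EAF)*beta^2 and F = R^2*(n-k-1) / (k*(1-R^2)); instruments
    with F strictly above 10 are considered strong.  A record without EAF is
    not scorable (returned flagged, not raised).
    """
    n_eff = record.n if record.n is not None else n
    if record.eaf is None:
        logger.warning("%s: EAF missing, instrument strength not scorable", record.snp_id)
        return InstrumentStrength(r2=math.nan, f=math.nan, weak=False, scorable=False)
    if not (0.0 < record.eaf < 1.0):
        return InstrumentStrength(r2=math.nan, f=math.nan, weak=False, scorable=False)
    if n_eff is None:
        raise ConfigurationError(f"{record.snp_id}: sample size unavailable (record.n and n both unset)")
    if k < 1 or n_eff <= k + 1:
        raise ConfigurationError("need n > k + 1 and k >= 1 for the F-statistic")
    r2 = 2.0 * record.eaf * (1.0 - record.eaf) * record.beta**2
    f = r2 * (n_eff - k - 1) / (k * (1.0 - r2))
    return InstrumentStrength(r2=r2, f=f, weak=not (f > WEAK_F_THRESHOLD))


def joint_strength(records: Sequence[SummaryStatRecord], n: int | None = None) -> InstrumentStrength:
    """Joint F over the instrument set: R^2 summed, k = number of SNPs."""
    if not records:
        raise InputError("joint_strength needs at least one record")
    k = len(records)
    parts = [instrument_strength(r, n=n, k=1) for r in records]
    if not all(p.scorable for p in parts):
        return InstrumentStrength(r2=math.nan, f=math.nan, weak=False, scorable=False)
    r2 = sum(p.r2 for p in parts)
    n_eff = n if n is not None else min(r.n for r in records if r.n is not None)
    if r2 >= 1.0:
        raise AnalysisError("summed R^2 >= 1; joint F undefined")
    f = r2 * (n_eff - k - 1) / (k * (1.0 - r2))
    return InstrumentStrength(r2=r2, f=f, weak=not (f > WEAK_F_THRESHOLD))


def apply_exclusion_list(
    records: Sequence[SummaryStatRecord],
    exclusions: Mapping[str, str] | Iterable[tuple[str, str]] | None,
) -> list[SummaryStatRecord]:
    """Remove SNPs named in an exclusion list (snp_id -> reason), logging removals."""
    if not exclusions:
        return list(records)
    excl = dict(exclusions)
    present = {r.snp_id for r in records}
    for snp_id, reason in excl.items():
        if snp_id in present:
            logger.info("excluding %s: %s", snp_id, reason)
        else:
            logger.warning("exclusion id %s not among instruments; ignored", snp_id)
    return [r for r in records if r.snp_id not in excl]


def read_exclusion_list(path: str | Path) -> dict[str, str]:
    """Read a TSV with columns snp_id, reason into a mapping."""
    df = pd.read_csv(path, sep="\t")
    if "snp_id" not in df.columns:
        raise ConfigurationError(f"exclusion list {path} missing column 'snp_id'")
    reasons = df["reason"] if "reason" in df.columns else ["unspecified"] * len(df)
    return {str(s): str(r) for s, r in zip(df["snp_id"], reasons)}


def select_instruments(
    records: Sequence[SummaryStatRecord],
    trait_name: str,
    p_threshold: float = 5e-8,
    ld: LDTable | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
    strict_ld: bool = False,
    exclusions: Mapping[str, str] | None = None,
    n: int | None = None,
) -> InstrumentSet:
    """Full selection pass: significance filter, LD clumping, exclusions, strength."""
    sig = filter_significant(records, p_threshold)
    clumped = ld_clump(sig, ld=ld, r2_threshold=r2_threshold, window_kb=window_kb, strict=strict_ld) if sig else []
    final = apply_exclusion_list(clumped, exclusions)
    per_f: dict[str, float] = {}
    per_r2: dict[str, float] = {}
    for rec in final:
        s = instrument_strength(rec, n=n, k=1)
        if s.scorable:
            per_f[rec.snp_id] = s.f
            per_r2[rec.snp_id] = s.r2
    return InstrumentSet(
        trait_name=trait_name,
        records=final,
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
        window_kb=window_kb,
        per_snp_f=per_f,
        per_snp_r2=per_r2,
    )
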