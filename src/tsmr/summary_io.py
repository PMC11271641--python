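"""Reading, validation and allele harmonization of GWAS summary statistics.

A summary-statistics table has one row per SNP with the variant identifier,
the two alleles, the effect-allele frequency (EAF), the estimated per-allele
effect (log odds ratio for a case/control trait), its standard error, the
association p-value and the sample size.  Two-sample Mendelian randomization
combines one such table for the exposure with one for the outcome, so before
any estimation the two tables must be put on a common effect allele per SNP:
that is what :func:`harmonize` does.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import AnalysisError, ConfigurationError, InputError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical field name -> default column header in input tables
CANONICAL_COLUMNS: dict[str, str] = {
    "snp_id": "snp",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "p",
    "n": "n",
    "n_cases": "n_cases",
    "n_controls": "n_controls",
}

REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue")

# actions harmonize() can assign to an exposure SNP
ACTION_KEPT = "kept"
ACTION_SIGN_FLIPPED = "sign_flipped"
ACTION_DROPPED_PALINDROMIC = "dropped_palindromic"
ACTION_DROPPED_MISSING = "dropped_missing"
ACTION_DROPPED_INCOMPATIBLE = "dropped_incompatible"
KEPT_ACTIONS = (ACTION_KEPT, ACTION_SIGN_FLIPPED)
ALL_ACTIONS = KEPT_ACTIONS + (
    ACTION_DROPPED_PALINDROMIC,
    ACTION_DROPPED_MISSING,
    ACTION_DROPPED_INCOMPATIBLE,
)


@dataclass
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele change in the trait (log odds for binary
    traits), ``se`` its standard error, ``eaf`` the effect-allele frequency.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def problems(self) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        out: list[str] = []
        if self.effect_allele not in VALID_ALLELES:
            out.append(f"effect_allele {self.effect_allele!r} not one of A/C/G/T")
        if self.other_allele not in VALID_ALLELES:
            out.append(f"other_allele {self.other_allele!r} not one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            out.append("effect_allele equals other_allele")
        if not (isinstance(self.se, (int, float)) and math.isfinite(self.se) and self.se > 0):
            out.append(f"se must be finite and > 0, got {self.se!r}")
        if not (isinstance(self.beta, (int, float)) and math.isfinite(self.beta)):
            out.append(f"beta must be finite, got {self.beta!r}")
        if not (0.0 < self.pvalue <= 1.0):
            out.append(f"pvalue must lie in (0, 1], got {self.pvalue!r}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            out.append(f"eaf must lie in [0, 1], got {self.eaf!r}")
        return out

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizedRecord:
    """One SNP after exposure/outcome allele alignment.

    ``effect_allele``/``other_allele`` are the exposure's alleles, to which
    both ``beta_exp`` and ``beta_out`` refer after harmonization.  For dropped
    SNPs the outcome-side fields may be ``None``.
    """

    snp_id: str
    beta_exp: float
    se_exp: float
    eaf_exp: float | None
    beta_out: float | None
    se_out: float | None
    eaf_out: float | None
    palindromic: bool
    action: str
    effect_allele: str = ""
    other_allele: str = ""

    @property
    def kept(self) -> bool:
        return self.action in KEPT_ACTIONS


@dataclass
class HarmonizedSet:
    """Aligned per-SNP exposure/outcome effects for one exposure-outcome pair."""

    exposure_name: str
    outcome_name: str
    records: list[HarmonizedRecord] = field(default_factory=list)

    @property
    def kept_records(self) -> list[HarmonizedRecord]:
        return [r for r in self.records if r.kept]

    @property
    def n_kept(self) -> int:
        return len(self.kept_records)

    def action_counts(self) -> dict[str, int]:
        counts = {a: 0 for a in ALL_ACTIONS}
        for r in self.records:
            counts[r.action] += 1
        return counts

    def subset(self, snp_ids: Iterable[str]) -> "HarmonizedSet":
        """A new set restricted to the kept SNPs named in ``snp_ids``."""
        wanted = set(snp_ids)
        recs = [replace(r) for r in self.kept_records if r.snp_id in wanted]
        return HarmonizedSet(self.exposure_name, self.outcome_name, recs)

    def drop(self, snp_ids: Iterable[str]) -> "HarmonizedSet":
        """A new set with the named kept SNPs removed."""
        unwanted = set(snp_ids)
        recs = [replace(r) for r in self.kept_records if r.snp_id not in unwanted]
        return HarmonizedSet(self.exposure_name, self.outcome_name, recs)

    def arrays(self):
        """(snp_ids, beta_exp, se_exp, beta_out, se_out) over kept records as numpy arrays."""
        import numpy as np

        kept = self.kept_records
        return (
            [r.snp_id for r in kept],
            np.array([r.beta_exp for r in kept], dtype=float),
            np.array([r.se_exp for r in kept], dtype=float),
            np.array([r.beta_out for r in kept], dtype=float),
            np.array([r.se_out for r in kept], dtype=float),
        )

    @classmethod
    def from_arrays(
        cls,
        beta_exp: Sequence[float],
        se_exp: Sequence[float],
        beta_out: Sequence[float],
        se_out: Sequence[float],
        snp_ids: Sequence[str] | None = None,
        eaf: Sequence[float] | None = None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "HarmonizedSet":
        """Build an already-aligned set directly from effect arrays (mainly for tests)."""
        k = len(beta_exp)
        if not (len(se_exp) == len(beta_out) == len(se_out) == k):
            raise InputError("effect/SE arrays must share one length")
        ids = list(snp_ids) if snp_ids is not None else [f"rs{i + 1}" for i in range(k)]
        recs = [
            HarmonizedRecord(
                snp_id=ids[i],
                beta_exp=float(beta_exp[i]),
                se_exp=float(se_exp[i]),
                eaf_exp=float(eaf[i]) if eaf is not None else None,
                beta_out=float(beta_out[i]),
                se_out=float(se_out[i]),
                eaf_out=float(eaf[i]) if eaf is not None else None,
                palindromic=False,
                action=ACTION_KEPT,
                effect_allele="A",
                other_allele="G",
            )
            for i in range(k)
        ]
        return cls(exposure_name, outcome_name, recs)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "snp": r.snp_id,
                "ea": r.effect_allele,
                "oa": r.other_allele,
                "beta_exp": r.beta_exp,
                "se_exp": r.se_exp,
                "eaf_exp": r.eaf_exp,
                "beta_out": r.beta_out,
                "se_out": r.se_out,
                "eaf_out": r.eaf_out,
                "palindromic": r.palindromic,
                "action_taken": r.action,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _opt_int(value) -> int | None:
    v = _opt_float(value)
    return None if v is None else int(round(v))


def dedupe_records(records: Sequence[SummaryStatRecord]) -> list[SummaryStatRecord]:
    """Keep, for each snp_id, the row with the lowest p-value; log the rest."""
    best: dict[str, SummaryStatRecord] = {}
    order: list[str] = []
    n_dropped = 0
    for rec in records:
        prev = best.get(rec.snp_id)
        if prev is None:
            best[rec.snp_id] = rec
            order.append(rec.snp_id)
        else:
            n_dropped += 1
            if rec.pvalue < prev.pvalue:
                best[rec.snp_id] = rec
    if n_dropped:
        logger.warning("dropped %d duplicate snp_id rows (kept lowest p-value)", n_dropped)
    return [best[s] for s in order]


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
) -> list[SummaryStatRecord]:
    """Read a delimited GWAS summary table into validated records.

    The delimiter (tab or comma) is auto-detected from the header line.
    ``column_map`` maps canonical field names (keys of
    :data:`CANONICAL_COLUMNS`) to the file's column headers and is merged over
    the defaults.  Rows violating record invariants are counted and logged,
    never silently dropped.  Duplicate snp_ids keep the lowest-p row.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary statistics file not found: {path}")
    colmap = dict(CANONICAL_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(CANONICAL_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown canonical fields in column_map: {sorted(unknown)}")
        colmap.update(column_map)

    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    for fld in REQUIRED_FIELDS:
        if colmap[fld] not in df.columns:
            raise ConfigurationError(
                f"required column {colmap[fld]!r} (field {fld!r}) missing from {path.name}"
            )
    present = {fld: col for fld, col in colmap.items() if col in df.columns}

    records: list[SummaryStatRecord] = []
    n_rejected = 0
    label = trait_name or path.name
    for idx, row in df.iterrows():
        try:
            rec = SummaryStatRecord(
                snp_id=str(row[present["snp_id"]]),
                effect_allele=str(row[present["effect_allele"]]).upper(),
                other_allele=str(row[present["other_allele"]]).upper(),
                beta=float(row[present["beta"]]),
                se=float(row[present["se"]]),
                pvalue=float(row[present["pvalue"]]),
                chrom=str(row[present["chrom"]]) if "chrom" in present and not pd.isna(row[present["chrom"]]) else None,
                pos=_opt_int(row[present["pos"]]) if "pos" in present else None,
                eaf=_opt_float(row[present["eaf"]]) if "eaf" in present else None,
                n=_opt_int(row[present["n"]]) if "n" in present else None,
                n_cases=_opt_int(row[present["n_cases"]]) if "n_cases" in present else None,
                n_controls=_opt_int(row[present["n_controls"]]) if "n_controls" in present else None,
            )
        except (TypeError, ValueError) as exc:
            n_rejected += 1
            logger.warning("%s row %d rejected: unparseable (%s)", label, idx, exc)
            continue
        probs = rec.problems()
        if probs:
            n_rejected += 1
            logger.warning("%s row %d (%s) rejected: %s", label, idx, rec.snp_id, "; ".join(probs))
            continue
        records.append(rec)
    if n_rejected:
        logger.warning("%s: rejected %d of %d rows", label, n_rejected, len(df))
    if not records:
        raise InputError(f"no parseable rows in {path}")
    return dedupe_records(records)


def write_summary_stats(records: Sequence[SummaryStatRecord], path: str | Path) -> None:
    """Write records as a TSV using the canonical column headers."""
    rows = []
    for r in records:
        rows.append(
            {
                "snp": r.snp_id,
                "chr": r.chrom,
                "pos": r.pos,
                "ea": r.effect_allele,
                "oa": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "p": r.pvalue,
                "n": r.n,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _complement_pair(ea: str, oa: str) -> tuple[str, str]:
    return _COMPLEMENT[ea], _COMPLEMENT[oa]


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    palindrome_eaf_window: float = 0.08,
    drop_palindromic_ambiguous: bool = True,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    Matching is by snp_id only.  Outcome alleles equal to the exposure's are
    kept as-is; swapped alleles flip the sign of ``beta_out`` and replace
    ``eaf_out`` by ``1 - eaf_out``; strand-complemented pairs are matched the
    same way after complementing.  Palindromic SNPs (A/T or C/G) cannot be
    resolved from alleles: when either EAF is missing, or the exposure EAF
    lies within ``palindrome_eaf_window`` of 0.5 and
    ``drop_palindromic_ambiguous`` is set, they are dropped; otherwise they
    are aligned by EAF concordance (same side of 0.5 keeps the sign).  Every
    exposure SNP appears exactly once in the result with an action tag.
    """
    if not exposure or not outcome:
        raise InputError("exposure and outcome record lists must both be non-empty")
    if not (0.0 <= palindrome_eaf_window < 0.5):
        raise ConfigurationError("palindrome_eaf_window must lie in [0, 0.5)")

    exposure = dedupe_records(exposure)
    outcome_by_id = {r.snp_id: r for r in dedupe_records(outcome)}

    if not any(r.snp_id in outcome_by_id for r in exposure):
        raise AnalysisError("no overlapping instruments between exposure and outcome")

    out_records: list[HarmonizedRecord] = []
    for ex in exposure:
        palindromic = ex.is_palindromic
        base = dict(
            snp_id=ex.snp_id,
            beta_exp=ex.beta,
            se_exp=ex.se,
            eaf_exp=ex.eaf,
            beta_out=None,
            se_out=None,
            eaf_out=None,
            palindromic=palindromic,
            effect_allele=ex.effect_allele,
            other_allele=ex.other_allele,
        )
        ou = outcome_by_id.get(ex.snp_id)
        if ou is None:
            out_records.append(HarmonizedRecord(action=ACTION_DROPPED_MISSING, **base))
            continue

        if palindromic:
            if {ou.effect_allele, ou.other_allele} != {ex.effect_allele, ex.other_allele}:
                out_records.append(HarmonizedRecord(action=ACTION_DROPPED_INCOMPATIBLE, **base))
                continue
            if ex.eaf is None or ou.eaf is None:
                out_records.append(HarmonizedRecord(action=ACTION_DROPPED_PALINDROMIC, **base))
                continue
            ambiguous = min(ex.eaf, 1.0 - ex.eaf) > 0.5 - palindrome_eaf_window
            if ambiguous and drop_palindromic_ambiguous:
                out_records.append(HarmonizedRecord(action=ACTION_DROPPED_PALINDROMIC, **base))
                continue
            # frequency alignment: concordant EAFs mean same effect allele
            concordant = (ex.eaf < 0.5) == (ou.eaf < 0.5)
            if concordant:
                base.update(beta_out=ou.beta, se_out=ou.se, eaf_out=ou.eaf)
                out_records.append(HarmonizedRecord(action=ACTION_KEPT, **base))
            else:
                base.update(beta_out=-ou.beta, se_out=ou.se, eaf_out=1.0 - ou.eaf)
                out_records.append(HarmonizedRecord(action=ACTION_SIGN_FLIPPED, **base))
            continue

        ex_pair = (ex.effect_allele, ex.other_allele)
        direct = (ou.effect_allele, ou.other_allele)
        swapped = (ou.other_allele, ou.effect_allele)
        comp_direct = _complement_pair(*direct)
        comp_swapped = _complement_pair(*swapped)
        if direct == ex_pair or comp_direct == ex_pair:
            base.update(beta_out=ou.beta, se_out=ou.se, eaf_out=ou.eaf)
            out_records.append(HarmonizedRecord(action=ACTION_KEPT, **base))
        elif swapped == ex_pair or comp_swapped == ex_pair:
            base.update(
                beta_out=-ou.beta,
                se_out=ou.se,
                eaf_out=None if ou.eaf is None else 1.0 - ou.eaf,
            )
            out_records.append(HarmonizedRecord(action=ACTION_SIGN_FLIPPED, **base))
        else:
            out_records.append(HarmonizedRecord(action=ACTION_DROPPED_INCOMPATIBLE, **base))

    hset = HarmonizedSet(exposure_name, outcome_name, out_records)
    counts = hset.action_counts()
    logger.info(
        "%s vs %s harmonized: %s",
        exposure_name,
        outcome_name,
        ", ".join(f"{a}={c}" for a, c in counts.items() if c),
    )
    return hset
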