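"""End-to-end orchestration of a multi-pair two-sample MR study.

For every exposure-outcome pair the pipeline runs: significance filtering,
LD clumping, exclusion-list filtering, instrument-strength scoring,
harmonization, the three causal estimators (IVW with the Q-driven
fixed/random switch, MR-Egger, weighted median), the sensitivity battery,
and finally multiplicity correction across the configured family.  Outputs
are TSV tables (full-precision machine tables plus 2-decimal rendered
tables), per-pair sensitivity files and a JSON run manifest sufficient to
reproduce the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .estimators import METHOD_EGGER, METHOD_WEIGHTED_MEDIAN, MREstimate, ivw, mr_egger, weighted_median
from .exceptions import AnalysisError, ConfigurationError, TsmrError
from .instruments import LDTable, read_exclusion_list, select_instruments
from .multiplicity import FAMILY_CHOICES, correct_family
from .sensitivity import sensitivity_report
from .summary_io import harmonize, read_summary_stats

logger = logging.getLogger(__name__)


@dataclass
class ExposureSpec:
    name: str
    path: str
    p_threshold: float | None = None
    n: int | None = None


@dataclass
class OutcomeSpec:
    name: str
    path: str


@dataclass
class AnalysisConfig:
    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    output_dir: str = "mr_output"
    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0
    palindrome_eaf_window: float = 0.08
    ld_table: str | None = None
    exclusions: str | None = None
    strict_ld: bool = False
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    correction_family: str = "per_outcome"
    column_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ConfigurationError("need at least one exposure and one outcome")
        if not (0.0 < self.p_threshold < 1.0):
            raise ConfigurationError("p_threshold must lie in (0, 1)")
        if self.correction_family not in FAMILY_CHOICES:
            raise ConfigurationError(f"correction_family must be one of {FAMILY_CHOICES}")


def load_config(path: str | Path) -> AnalysisConfig:
    """Load a YAML analysis config (see the CLI help for the schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    try:
        exposures = [ExposureSpec(**e) for e in raw.pop("exposures", [])]
        outcomes = [OutcomeSpec(**o) for o in raw.pop("outcomes", [])]
        return AnalysisConfig(exposures=exposures, outcomes=outcomes, **raw)
    except TypeError as exc:
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc


@dataclass
class PairResult:
    exposure: str
    outcome: str
    status: str  # "ok" or a "not estimable: ..." explanation
    n_instruments: int
    estimates: list[MREstimate] = field(default_factory=list)
    report: object | None = None
    ivw_model: str | None = None


@dataclass
class PipelineResult:
    estimates: pd.DataFrame
    corrections: pd.DataFrame | None
    pairs: list[PairResult]
    output_dir: Path
    manifest: dict


def _estimate_rows(pair: PairResult) -> list[dict]:
    rows = []
    for est in pair.estimates:
        rows.append(
            {
                "exposure": pair.exposure,
                "outcome": pair.outcome,
                "method": est.method,
                "n_snps": est.n_snps,
                "beta": est.beta,
                "se": est.se,
                "or": est.or_,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
                "egger_intercept": est.intercept,
                "egger_intercept_pvalue": est.intercept_pvalue,
                "status": pair.status,
            }
        )
    if not pair.estimates:
        rows.append(
            {"exposure": pair.exposure, "outcome": pair.outcome, "method": None,
             "n_snps": pair.n_instruments, "beta": None, "se": None, "or": None,
             "ci_low": None, "ci_high": None, "pvalue": None,
             "egger_intercept": None, "egger_intercept_pvalue": None, "status": pair.status}
        )
    return rows


def _render(df: pd.DataFrame) -> pd.DataFrame:
    """Human table: OR and CI to 2 decimals, p to 2 decimals (report style)."""
    out = df[["exposure", "outcome", "method", "n_snps"]].copy()
    out["OR (95% CI)"] = [
        f"{o:.2f} ({lo:.2f}-{hi:.2f})" if pd.notna(o) else ""
        for o, lo, hi in zip(df["or"], df["ci_low"], df["ci_high"])
    ]
    out["P"] = [f"{p:.2f}" if pd.notna(p) else "" for p in df["pvalue"]]
    return out


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    """Run the full study described by ``config`` and write all artifacts."""
    outdir = Path(config.output_dir)
    (outdir / "sensitivity").mkdir(parents=True, exist_ok=True)

    ld = LDTable.read(config.ld_table) if config.ld_table else None
    exclusions = read_exclusion_list(config.exclusions) if config.exclusions else None

    outcome_records = {
        o.name: read_summary_stats(o.path, column_map=config.column_map or None, trait_name=o.name)
        for o in config.outcomes
    }

    pairs: list[PairResult] = []
    errors: list[dict] = []
    for ei, exp in enumerate(config.exposures):
        exp_records = read_summary_stats(exp.path, column_map=config.column_map or None, trait_name=exp.name)
        iset = select_instruments(
            exp_records,
            trait_name=exp.name,
            p_threshold=exp.p_threshold or config.p_threshold,
            ld=ld,
            r2_threshold=config.r2_threshold,
            window_kb=config.window_kb,
            strict_ld=config.strict_ld,
            exclusions=exclusions,
            n=exp.n,
        )
        for oi, out in enumerate(config.outcomes):
            pair_seed = config.seed + 1000 * ei + oi  # stable per-pair seed
            pair = PairResult(exposure=exp.name, outcome=out.name, status="ok",
                              n_instruments=len(iset.records))
            try:
                if not iset.records:
                    raise AnalysisError("no instruments passed selection")
                hset = harmonize(
                    iset.records,
                    outcome_records[out.name],
                    palindrome_eaf_window=config.palindrome_eaf_window,
                    exposure_name=exp.name,
                    outcome_name=out.name,
                )
                hset.write_tsv(outdir / "sensitivity" / f"{exp.name}__{out.name}_harmonized.tsv")
                k = hset.n_kept
                pair.n_instruments = k
                if k < 1:
                    raise AnalysisError("no instruments survived harmonization")
                est_ivw = ivw(hset, model="auto")
                pair.ivw_model = est_ivw.method
                pair.estimates.append(est_ivw)
                if k >= 3:
                    pair.estimates.append(mr_egger(hset))
                    pair.estimates.append(weighted_median(hset, n_boot=config.n_boot, seed=pair_seed))
                if k >= 2:
                    pair.report = sensitivity_report(hset, n_sim=config.n_sim, seed=pair_seed)
                    _write_sensitivity(pair, outdir / "sensitivity")
            except TsmrError as exc:
                pair.status = f"not estimable: {exc}"
                errors.append({"exposure": exp.name, "outcome": out.name, "error": str(exc)})
                logger.warning("%s vs %s: %s", exp.name, out.name, exc)
            pairs.append(pair)

    est_df = pd.DataFrame([row for p in pairs for row in _estimate_rows(p)])
    est_df.to_csv(outdir / "estimates.tsv", sep="\t", index=False)
    _render(est_df).to_csv(outdir / "estimates_rendered.tsv", sep="\t", index=False)

    corrections = None
    ivw_rows = est_df[est_df.method.isin(["ivw_fixed", "ivw_random", "wald"])]
    if not ivw_rows.empty:
        fam = ivw_rows.rename(columns={"pvalue": "raw_pvalue"})[["exposure", "outcome", "raw_pvalue"]]
        fam = fam.dropna(subset=["raw_pvalue"])
        if not fam.empty:
            table = correct_family(fam, family=config.correction_family)
            corrections = table.wide()
            corrections.to_csv(outdir / "corrections.tsv", sep="\t")
            table.entries.to_csv(outdir / "corrections_long.tsv", sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "config": {
            **{k: v for k, v in asdict(config).items() if k not in ("exposures", "outcomes")},
            "exposures": [asdict(e) for e in config.exposures],
            "outcomes": [asdict(o) for o in config.outcomes],
        },
        "pairs": [
            {"exposure": p.exposure, "outcome": p.outcome, "status": p.status,
             "n_instruments": p.n_instruments, "ivw_model": p.ivw_model}
            for p in pairs
        ],
        "errors": errors,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(estimates=est_df, corrections=corrections, pairs=pairs,
                          output_dir=outdir, manifest=manifest)


def _write_sensitivity(pair: PairResult, outdir: Path) -> None:
    rep = pair.report
    stem = f"{pair.exposure}__{pair.outcome}"
    rows = [
        ("cochran_q", rep.q_stat),
        ("cochran_q_df", rep.q_df),
        ("cochran_q_pvalue", rep.q_pvalue),
        ("egger_intercept", rep.egger_intercept),
        ("egger_intercept_se", rep.egger_intercept_se),
        ("egger_intercept_pvalue", rep.egger_intercept_pvalue),
        ("funnel_asymmetry", rep.funnel.asymmetry if rep.funnel else None),
    ]
    if rep.presso is not None:
        rows += [
            ("presso_global_rss", rep.presso.global_rss),
            ("presso_global_pvalue", rep.presso.global_pvalue),
            ("presso_n_outliers", len(rep.presso.outliers)),
            ("presso_outliers", ";".join(rep.presso.outliers)),
            ("presso_distortion_pvalue", rep.presso.distortion_pvalue),
        ]
    pd.DataFrame(rows, columns=["statistic", "value"]).to_csv(
        outdir / f"{stem}_summary.tsv", sep="\t", index=False
    )
    if rep.loo:
        pd.DataFrame(
            [
                {"excluded_snp": e.snp_id, "beta": e.estimate.beta, "se": e.estimate.se,
                 "or": e.estimate.or_, "ci_low": e.estimate.ci_low, "ci_high": e.estimate.ci_high,
                 "pvalue": e.estimate.pvalue, "flagged": e.flagged}
                for e in rep.loo
            ]
        ).to_csv(outdir / f"{stem}_loo.tsv", sep="\t", index=False)
    if rep.funnel is not None:
        pd.DataFrame(
            [{"snp": p.snp_id, "ratio": p.ratio, "precision": p.precision} for p in rep.funnel.points]
        ).to_csv(outdir / f"{stem}_funnel.tsv", sep="\t", index=False)
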