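"""Orchestration of a full one-direction MR analysis and report writing.

``run_analysis`` wires the stages together: read summary statistics ->
select instruments -> substitute proxies -> harmonize -> run every requested
estimator -> diagnostics -> power.  A method that cannot run (too few
instruments) is reported as not-run and the analysis continues.  Given the
same configuration and seeds the JSON report is byte-identical across runs;
timestamps only ever appear in the log stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from . import diagnostics as diag
from . import estimators as est
from .exceptions import ConfigError, InsufficientInstrumentsError
from .io import read_proxy_table, read_summary_stats_counted
from .power import PowerConfig, detectable_or, mr_power_binary
from .summary_data import (
    GENOME_WIDE_P,
    HarmonizedInstrument,
    InstrumentSet,
    VariantAssociation,
    harmonize,
    load_fixture,
    select_instruments,
    substitute_proxies,
)

log = logging.getLogger(__name__)

DEFAULT_ESTIMATORS = ("ivw", "egger", "weighted_median", "simple_mode",
                      "weighted_mode", "mr_presso")


@dataclass
class StudyConfig:
    """One GWAS: file location, column mapping, and study-level numbers."""

    path: str
    columns: dict[str, str]
    name: str = ""
    trait_type: str = "continuous"
    sample_size: Optional[int] = None
    cases: Optional[int] = None
    variance_explained: Optional[float] = None


@dataclass
class AnalysisConfig:
    exposure: StudyConfig
    outcome: StudyConfig
    proxy_table: Optional[str] = None
    policy: str = "drop_all_palindromic"
    p_threshold: float = GENOME_WIDE_P
    estimators: Sequence[str] = DEFAULT_ESTIMATORS
    seed: int = 1
    n_boot: int = 1000
    n_presso_sim: int = 1000
    alpha: float = 0.05
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        ve = self.exposure.variance_explained
        if ve is not None and not (0 < ve < 1):
            raise ConfigError(f"variance_explained must be in (0, 1), got {ve}")
        unknown = [e for e in self.estimators if e not in DEFAULT_ESTIMATORS]
        if unknown:
            raise ConfigError(f"unknown estimators: {unknown}")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        try:
            d["exposure"] = StudyConfig(**d["exposure"])
            d["outcome"] = StudyConfig(**d["outcome"])
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid study configuration: {exc}") from exc
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class AnalysisReport:
    """Everything one direction of the analysis produced."""

    exposure_name: str
    outcome_name: str
    harmonization: list[HarmonizedInstrument]
    estimates: list[est.MREstimate]
    not_run: dict[str, str]
    pleiotropy: Optional[est.PleiotropyResult]
    heterogeneity: dict[str, diag.HeterogeneityResult]
    presso: Optional[est.PressoResult]
    leave_one_out: list[diag.LeaveOneOutRow]
    f_statistic: Optional[float]
    power: Optional[dict]
    read_log: dict[str, int]
    provenance: dict

    @property
    def included(self) -> list[HarmonizedInstrument]:
        return [h for h in self.harmonization if h.included]

    def to_dict(self) -> dict:
        def clean(x):
            if hasattr(x, "__dataclass_fields__"):
                return {k: clean(v) for k, v in asdict(x).items()}
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            return x

        return {
            "exposure": self.exposure_name,
            "outcome": self.outcome_name,
            "harmonization": [clean(h) for h in self.harmonization],
            "estimates": [e.to_dict() for e in self.estimates],
            "not_run": dict(self.not_run),
            "pleiotropy": clean(self.pleiotropy),
            "heterogeneity": {k: clean(v) for k, v in self.heterogeneity.items()},
            "presso": clean(self.presso),
            "leave_one_out": [
                {"dropped_rsid": r.dropped_rsid, **r.estimate.to_dict()}
                for r in self.leave_one_out
            ],
            "f_statistic": self.f_statistic,
            "power": self.power,
            "read_log": self.read_log,
            "provenance": self.provenance,
        }


def analyze_instruments(
    instruments: InstrumentSet,
    outcome_assocs: Sequence[VariantAssociation],
    *,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    policy: str = "drop_all_palindromic",
    estimators: Sequence[str] = DEFAULT_ESTIMATORS,
    seed: int = 1,
    n_boot: int = 1000,
    n_presso_sim: int = 1000,
    alpha: float = 0.05,
    outcome_sample_size: Optional[int] = None,
    outcome_cases: Optional[int] = None,
    provenance: Optional[dict] = None,
) -> AnalysisReport:
    """Run harmonization, estimation, diagnostics, and power on an
    already-selected instrument set."""
    harmonized = harmonize(instruments, outcome_assocs, policy=policy)
    included = [h for h in harmonized if h.included]
    log.info("%s -> %s: %d instruments, %d included after harmonization",
             exposure_name, outcome_name, len(instruments), len(included))

    estimates: list[est.MREstimate] = []
    not_run: dict[str, str] = {}
    pleiotropy = None
    presso = None
    for name in estimators:
        try:
            if name == "ivw":
                estimates.append(est.ivw(included))
            elif name == "egger":
                slope, pleiotropy = est.egger(included)
                estimates.append(slope)
            elif name == "weighted_median":
                estimates.append(est.weighted_median(included, n_boot=n_boot,
                                                     seed=seed))
            elif name == "simple_mode":
                estimates.append(est.mode_based(included, weighted=False,
                                                n_boot=n_boot, seed=seed))
            elif name == "weighted_mode":
                estimates.append(est.mode_based(included, weighted=True,
                                                n_boot=n_boot, seed=seed))
            elif name == "mr_presso":
                presso = est.mr_presso(included, n_sim=n_presso_sim, seed=seed)
            else:
                not_run[name] = "unknown estimator"
        except InsufficientInstrumentsError as exc:
            not_run[name] = f"not run: {exc}"
            log.warning("%s %s", name, not_run[name])

    heterogeneity: dict[str, diag.HeterogeneityResult] = {}
    for model in ("ivw", "egger"):
        try:
            heterogeneity[model] = diag.cochran_q(included, model)
        except InsufficientInstrumentsError:
            pass
    try:
        loo = diag.leave_one_out(included)
    except InsufficientInstrumentsError:
        loo = []

    f_stat = None
    if instruments.variance_explained and instruments.sample_size and len(instruments):
        f_stat = diag.f_statistic(instruments.variance_explained,
                                  instruments.sample_size, len(instruments))

    power = None
    if outcome_cases and outcome_sample_size and instruments.variance_explained:
        cfg = PowerConfig(n_outcome=outcome_sample_size,
                          case_fraction=outcome_cases / outcome_sample_size,
                          r2=instruments.variance_explained, alpha=alpha)
        or80 = detectable_or(cfg, 0.80)
        power = {
            "n_outcome": outcome_sample_size,
            "case_fraction": cfg.case_fraction,
            "r2": cfg.r2,
            "alpha": alpha,
            "detectable_or_at_80pct": or80,
            "power_at_detectable_or": mr_power_binary(cfg, or80),
        }

    return AnalysisReport(
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        harmonization=harmonized,
        estimates=estimates,
        not_run=not_run,
        pleiotropy=pleiotropy,
        heterogeneity=heterogeneity,
        presso=presso,
        leave_one_out=loo,
        f_statistic=f_stat,
        power=power,
        read_log={},
        provenance=provenance or {},
    )


def _config_hash(cfg: AnalysisConfig) -> str:
    d = asdict(cfg)
    d.pop("output_dir", None)  # where the report lands is not analytic input
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_analysis(cfg: AnalysisConfig) -> AnalysisReport:
    """Execute a configured one-direction analysis; write artifacts if asked."""
    exp_records, exp_skipped = read_summary_stats_counted(
        cfg.exposure.path, cfg.exposure.columns, cfg.exposure.trait_type)
    out_records, out_skipped = read_summary_stats_counted(
        cfg.outcome.path, cfg.outcome.columns, cfg.outcome.trait_type)

    instruments = select_instruments(
        exp_records, cfg.p_threshold,
        exposure_name=cfg.exposure.name or "exposure",
        variance_explained=cfg.exposure.variance_explained,
        sample_size=cfg.exposure.sample_size,
    )
    if cfg.proxy_table:
        candidates = read_proxy_table(cfg.proxy_table)
        instruments = substitute_proxies(
            instruments,
            outcome_rsids={v.rsid for v in out_records},
            candidates=candidates,
            exposure_lookup={v.rsid: v for v in exp_records},
        )

    report = analyze_instruments(
        instruments, out_records,
        exposure_name=cfg.exposure.name or "exposure",
        outcome_name=cfg.outcome.name or "outcome",
        policy=cfg.policy,
        estimators=cfg.estimators,
        seed=cfg.seed,
        n_boot=cfg.n_boot,
        n_presso_sim=cfg.n_presso_sim,
        alpha=cfg.alpha,
        outcome_sample_size=cfg.outcome.sample_size,
        outcome_cases=cfg.outcome.cases,
        provenance={"config_hash": _config_hash(cfg), "seed": cfg.seed,
                    "version": __version__},
    )
    report.read_log = {"exposure_rows_skipped": exp_skipped,
                       "outcome_rows_skipped": out_skipped}
    if cfg.output_dir:
        write_report(report, cfg.output_dir)
    return report


def run_fixture_analysis(name: str, seed: int = 1, n_boot: int = 1000,
                         n_presso_sim: int = 1000,
                         estimators: Sequence[str] = DEFAULT_ESTIMATORS,
                         ) -> AnalysisReport:
    """Full analysis of a bundled instrument table (proxies pre-substituted)."""
    instruments, outcome_assocs, meta = load_fixture(name)
    return analyze_instruments(
        instruments, outcome_assocs,
        exposure_name=meta["exposure_name"],
        outcome_name=meta["outcome_name"],
        estimators=estimators,
        seed=seed, n_boot=n_boot, n_presso_sim=n_presso_sim,
        outcome_sample_size=meta["n_outcome"],
        outcome_cases=meta.get("outcome_cases"),
        provenance={"fixture": name, "seed": seed, "version": __version__},
    )


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

_TSV_FLOAT = "%.3f"


def write_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Write estimates.tsv, harmonization.tsv, diagnostics TSVs and report.json.

    TSV floats are printed at three decimals; report.json keeps full
    precision and is byte-stable for a fixed configuration and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    single = diag.single_snp_table(report.included)
    rows = [{"label": e.extras["rsid"], "beta": e.theta, "se": e.se,
             "pvalue": e.pvalue} for e in single]
    rows += [{"label": e.method, "beta": e.theta, "se": e.se, "pvalue": e.pvalue}
             for e in report.estimates]
    p = out / "estimates.tsv"
    pd.DataFrame(rows, columns=["label", "beta", "se", "pvalue"]).to_csv(
        p, sep="\t", index=False, float_format=_TSV_FLOAT)
    written.append(p)

    p = out / "harmonization.tsv"
    pd.DataFrame([{
        "rsid": h.rsid, "status": h.status, "proxy_of": h.proxy_of,
        "effect_allele": h.effect_allele,
        "beta_exposure": h.beta_exposure, "se_exposure": h.se_exposure,
        "beta_outcome": h.beta_outcome, "se_outcome": h.se_outcome,
        "reason": h.reason,
    } for h in report.harmonization]).to_csv(p, sep="\t", index=False)
    written.append(p)

    p = out / "heterogeneity.tsv"
    pd.DataFrame([{"model": h.model, "Q": h.Q, "df": h.df, "pvalue": h.pvalue}
                  for h in report.heterogeneity.values()]).to_csv(
        p, sep="\t", index=False)
    written.append(p)

    if report.leave_one_out:
        p = out / "loo.tsv"
        # se is the floored multiplicative-random-effects SE; se_unfloored
        # drops the max(1, .) floor so both interval conventions are visible
        pd.DataFrame([{
            "dropped_rsid": r.dropped_rsid, "beta": r.estimate.theta,
            "se": r.estimate.se,
            "se_unfloored": r.estimate.extras["se_fixed"]
            * (r.estimate.extras["Q"] / max(r.estimate.n_snps - 1, 1)) ** 0.5,
            "pvalue": r.estimate.pvalue,
        } for r in report.leave_one_out]).to_csv(p, sep="\t", index=False)
        written.append(p)

    p = out / "forest.tsv"
    diag.forest_table(report.included, report.estimates).to_csv(
        p, sep="\t", index=False)
    written.append(p)

    p = out / "funnel.tsv"
    pd.DataFrame([{"rsid": f.rsid, "ratio_estimate": f.ratio_estimate,
                   "precision": f.precision}
                  for f in diag.funnel_data(report.included)]).to_csv(
        p, sep="\t", index=False)
    written.append(p)

    p = out / "scatter.tsv"
    fits = {e.method: (0.0, e.theta) for e in report.estimates}
    if report.pleiotropy is not None:
        for e in report.estimates:
            if e.method == "egger":
                fits["egger"] = (report.pleiotropy.intercept, e.theta)
    diag.scatter_data(report.included, fits).to_csv(p, sep="\t", index=False)
    written.append(p)

    p = out / "report.json"
    with open(p, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)
    return written
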