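"""Study orchestration: per-database MR, method selection, pooling, reporting.

For each (exposure, outcome, database) triple the analysis follows a fixed
decision tree:

* one instrument — Wald ratio;
* two instruments — IVW (fixed vs random chosen by the Q test);
* three or more — the Egger intercept test runs first; if it flags
  directional pleiotropy the primary estimate is MR-Egger with bootstrap
  SEs, otherwise IVW with the Q-test-driven fixed/random choice.

Sensitivity analyses are gated by instrument count: likelihood-based MR
needs more than 1 SNP, the weighted median more than 2, MR-PRESSO more than
3; leave-one-out runs whenever there are at least 2.  Gated-out analyses are
reported as explicitly "not evaluable".

Per-database primary estimates are pooled across databases by fixed-effect
meta-analysis, switching to DerSimonian–Laird random effects when the
between-database Q test is significant.  Pooled p-values are classified as
significant (below the Bonferroni threshold alpha/m), suggestive (between
that threshold and 0.05), or null.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, MRPipeError, ValidationError
from .diagnostics import (
    InterceptTest,
    LeaveOneOutTable,
    PressoResult,
    egger_intercept_test,
    leave_one_out,
    presso,
)
from .estimators import MREstimate, egger, ivw, likelihood_mr, wald_ratio, weighted_median
from .instruments import MRDataset, harmonize_dataset
from .meta_power import MetaEstimate, bonferroni_threshold, meta_auto
from .sumstats_io import read_confounder_table, read_proxy_table, read_sumstats

__all__ = [
    "AnalysisConfig",
    "EvidenceCall",
    "TripleResult",
    "analyze_triple",
    "rerun_without_outliers",
    "pool_and_classify",
    "run_study",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds, stochastic settings and input locations for a study run."""

    seed: int = 0
    p_instrument: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    f_min: float = 10.0
    p_conf: float = 5e-8
    proxy_r2_min: float = 0.8
    q_alpha: float = 0.05
    intercept_alpha: float = 0.05
    outlier_alpha: float = 0.05
    alpha_family: float = 0.05
    m_tests: int | None = None  # default: n_exposures * n_outcomes
    n_boot: int = 1000
    presso_n_sim: int = 1000
    palindrome_policy: str = "infer"
    # exposure trait -> sumstats path
    exposures: Mapping[str, str] = field(default_factory=dict)
    # outcome trait -> {database -> sumstats path}
    outcomes: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    proxy_table: str | None = None
    confounder_table: str | None = None
    ld_table: str | None = None

    def __post_init__(self):
        for name, val in (
            ("p_instrument", self.p_instrument),
            ("q_alpha", self.q_alpha),
            ("intercept_alpha", self.intercept_alpha),
            ("outlier_alpha", self.outlier_alpha),
            ("alpha_family", self.alpha_family),
            ("p_conf", self.p_conf),
        ):
            if not (0 < val < 1):
                raise ConfigError(f"{name} must lie in (0, 1), got {val}")
        if not (0 <= self.clump_r2 <= 1):
            raise ConfigError(f"clump_r2 must lie in [0, 1], got {self.clump_r2}")
        if self.m_tests is not None and self.m_tests < 1:
            raise ConfigError(f"m_tests must be >= 1, got {self.m_tests}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def resolve_m_tests(self) -> int:
        if self.m_tests is not None:
            return self.m_tests
        m = len(self.exposures) * len(self.outcomes)
        return max(m, 1)

    def triple_seed(self, *labels: str) -> int:
        """Deterministic per-triple seed derived from the master seed."""
        tag = zlib.crc32("|".join(labels).encode())
        ss = np.random.SeedSequence([self.seed, tag])
        return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class EvidenceCall:
    """Classification of a pooled p-value against the multiplicity scheme."""

    label: str  # significant | suggestive | null
    pval: float
    bonferroni: float
    suggestive_cutoff: float = 0.05


@dataclass
class TripleResult:
    """Everything computed for one (exposure, outcome, database) triple."""

    dataset: MRDataset
    primary: MREstimate
    sensitivity: dict[str, MREstimate | str]
    intercept_test: InterceptTest
    presso_result: PressoResult | None
    loo: LeaveOneOutTable | None
    rerun: "TripleResult | None" = None


def analyze_triple(dataset: MRDataset, cfg: AnalysisConfig, run_presso: bool = True) -> TripleResult:
    """Apply the method-selection decision tree and sensitivity suite."""
    j = dataset.n_snp
    if j == 0:
        reasons = "; ".join(f"{a.snp_id}: {a.reason}" for a in dataset.audit if a.action == "dropped")
        raise MRPipeError(f"no instruments survived selection ({reasons or 'no audit entries'})")

    seed = cfg.triple_seed(dataset.exposure_id, dataset.outcome_id, dataset.database_id)

    if j >= 3:
        itest = egger_intercept_test(dataset, alpha=cfg.intercept_alpha)
    else:
        itest = InterceptTest(evaluable=False, reason=f"needs >= 3 instruments, got {j}")

    if j == 1:
        primary = wald_ratio(dataset.instruments[0])
    elif itest.evaluable and itest.pleiotropy_flag:
        primary = egger(dataset, se_method="bootstrap", n_boot=cfg.n_boot, seed=seed)
    else:
        primary = ivw(dataset, effect_model="auto", q_alpha=cfg.q_alpha)

    sensitivity: dict[str, MREstimate | str] = {}
    sensitivity["max_likelihood"] = (
        likelihood_mr(dataset) if j > 1 else "not evaluable: needs > 1 SNP"
    )
    sensitivity["weighted_median"] = (
        weighted_median(dataset, n_boot=cfg.n_boot, seed=seed)
        if j > 2
        else "not evaluable: needs > 2 SNPs"
    )

    presso_result: PressoResult | None = None
    if run_presso:
        presso_result = presso(
            dataset, n_sim=cfg.presso_n_sim, outlier_alpha=cfg.outlier_alpha, seed=seed
        )

    loo = leave_one_out(dataset, q_alpha=cfg.q_alpha) if j >= 2 else None

    return TripleResult(
        dataset=dataset,
        primary=primary,
        sensitivity=sensitivity,
        intercept_test=itest,
        presso_result=presso_result,
        loo=loo,
    )


def rerun_without_outliers(
    dataset: MRDataset, presso_result: PressoResult, cfg: AnalysisConfig
) -> TripleResult:
    """Repeat the analysis with MR-PRESSO-flagged outliers removed."""
    if not presso_result.evaluable or not presso_result.outliers:
        raise ValidationError("rerun_without_outliers requires a PRESSO result with outliers")
    reduced = dataset.drop(presso_result.outliers)
    if reduced.n_snp == 0:
        raise MRPipeError("removing all flagged outliers would leave no instruments")
    return analyze_triple(reduced, cfg, run_presso=False)


def pool_and_classify(
    per_database: Sequence[MREstimate], cfg: AnalysisConfig
) -> tuple[MetaEstimate, EvidenceCall]:
    """Pool primary estimates across databases and classify the evidence."""
    meta = meta_auto(per_database, q_alpha=cfg.q_alpha)
    threshold, _ = bonferroni_threshold(cfg.alpha_family, cfg.resolve_m_tests())
    if meta.pval < threshold:
        label = "significant"
    elif meta.pval < 0.05:
        label = "suggestive"
    else:
        label = "null"
    return meta, EvidenceCall(label=label, pval=meta.pval, bonferroni=threshold)


# ---------------------------------------------------------------------------
# whole-study driver


def _estimate_row(exp: str, out: str, db: str, est: MREstimate) -> dict:
    lo, hi = est.or_ci
    return {
        "exposure": exp,
        "outcome": out,
        "database": db,
        "method": est.method,
        "nsnp": est.n_snp,
        "beta": est.beta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pval": est.pval,
        "or": est.or_scale,
        "or_ci_low": lo,
        "or_ci_high": hi,
        "q": est.q,
        "q_pval": est.q_pval,
        "egger_intercept": est.egger_intercept,
        "egger_intercept_p": est.egger_intercept_p,
    }


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def run_study(cfg: AnalysisConfig, outdir: str | Path) -> dict:
    """Run the full study over every (exposure, outcome) pair in the config.

    For each pair, per-database instrument building, the decision-tree
    analysis, MR-PRESSO-driven re-analysis, and cross-database pooling with
    evidence classification.  Writes tidy TSVs plus a machine-readable
    manifest; identical config and seed yield byte-identical outputs.
    A database whose analysis fails (for instance, no surviving instruments)
    is reported as a warning and the meta-analysis proceeds over the rest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    proxies = read_proxy_table(cfg.proxy_table) if cfg.proxy_table else ()
    confounders = read_confounder_table(cfg.confounder_table) if cfg.confounder_table else ()
    ld: dict[tuple[str, str], float] = {}
    if cfg.ld_table:
        ld_df = pd.read_csv(cfg.ld_table, sep=None, engine="python")
        for _, row in ld_df.iterrows():
            ld[(str(row["snp_a"]), str(row["snp_b"]))] = float(row["r2"])

    exposure_stats = {
        name: read_sumstats(path, trait_id=name) for name, path in cfg.exposures.items()
    }

    primary_rows, sens_rows, meta_rows, audit_rows, presso_rows = [], [], [], [], []
    warnings: list[str] = []

    for exp_name, exp_stats in exposure_stats.items():
        for out_name, databases in cfg.outcomes.items():
            per_db: list[MREstimate] = []
            per_db_labels: list[str] = []
            for db_name, out_path in databases.items():
                try:
                    out_stats = read_sumstats(out_path, trait_id=out_name)
                    dataset = harmonize_dataset(
                        exp_stats,
                        out_stats,
                        exposure_id=exp_name,
                        outcome_id=out_name,
                        database_id=db_name,
                        p_threshold=cfg.p_instrument,
                        ld=ld or None,
                        clump_r2=cfg.clump_r2,
                        clump_kb=cfg.clump_kb,
                        confounder_hits=confounders,
                        p_conf=cfg.p_conf,
                        f_min=cfg.f_min,
                        proxies=proxies,
                        proxy_r2_min=cfg.proxy_r2_min,
                        palindrome_policy=cfg.palindrome_policy,
                    )
                    result = analyze_triple(dataset, cfg)
                except MRPipeError as exc:
                    warnings.append(f"{exp_name}/{out_name}/{db_name}: {exc}")
                    continue

                for a in dataset.audit:
                    audit_rows.append(
                        {
                            "exposure": exp_name,
                            "outcome": out_name,
                            "database": db_name,
                            "snp": a.snp_id,
                            "stage": a.stage,
                            "action": a.action,
                            "reason": a.reason,
                        }
                    )
                primary_rows.append(_estimate_row(exp_name, out_name, db_name, result.primary))
                for method, est in result.sensitivity.items():
                    if isinstance(est, MREstimate):
                        sens_rows.append(_estimate_row(exp_name, out_name, db_name, est))
                    else:
                        sens_rows.append(
                            {
                                "exposure": exp_name,
                                "outcome": out_name,
                                "database": db_name,
                                "method": method,
                                "nsnp": dataset.n_snp,
                                "pval": None,
                                "beta": None,
                                "se": None,
                                "q": None,
                                "q_pval": None,
                                "ci_low": None,
                                "ci_high": None,
                                "or": None,
                                "or_ci_low": None,
                                "or_ci_high": None,
                                "egger_intercept": None,
                                "egger_intercept_p": None,
                                "status": est,
                            }
                        )

                pr = result.presso_result
                presso_row = {
                    "exposure": exp_name,
                    "outcome": out_name,
                    "database": db_name,
                    "evaluable": pr.evaluable if pr else False,
                    "global_p": pr.global_p if pr else None,
                    "outliers": ",".join(pr.outliers) if pr and pr.outliers else "",
                    "distortion_pct": pr.distortion_pct if pr else None,
                    "distortion_p": pr.distortion_p if pr else None,
                    "status": "" if (pr and pr.evaluable) else (pr.reason if pr else "not run"),
                }
                presso_rows.append(presso_row)

                if pr and pr.evaluable and pr.outliers and pr.estimate_no_outliers is not None:
                    rerun = rerun_without_outliers(dataset, pr, cfg)
                    row = _estimate_row(exp_name, out_name, f"{db_name}:no_outliers", rerun.primary)
                    primary_rows.append(row)
                    per_db.append(result.primary)  # pre-removal estimate enters the meta
                else:
                    per_db.append(result.primary)
                per_db_labels.append(db_name)

            if not per_db:
                warnings.append(f"{exp_name}/{out_name}: no database produced an estimate")
                continue
            meta, call = pool_and_classify(per_db, cfg)
            or_lo, or_hi = meta.or_ci
            meta_rows.append(
                {
                    "exposure": exp_name,
                    "outcome": out_name,
                    "model": meta.model,
                    "k": meta.k,
                    "databases": ",".join(per_db_labels),
                    "beta": meta.beta_pooled,
                    "se": meta.se_pooled,
                    "or": meta.or_scale,
                    "or_ci_low": or_lo,
                    "or_ci_high": or_hi,
                    "pval": meta.pval,
                    "q": meta.q,
                    "q_pval": meta.q_pval,
                    "i2": meta.i2,
                    "tau2": meta.tau2,
                    "evidence": call.label,
                }
            )

    _write_tsv(pd.DataFrame(primary_rows), outdir / "primary_estimates.tsv")
    _write_tsv(pd.DataFrame(sens_rows), outdir / "sensitivity_estimates.tsv")
    _write_tsv(pd.DataFrame(meta_rows), outdir / "meta_estimates.tsv")
    _write_tsv(pd.DataFrame(audit_rows), outdir / "instrument_audit.tsv")
    _write_tsv(pd.DataFrame(presso_rows), outdir / "presso_summary.tsv")

    threshold, display = bonferroni_threshold(cfg.alpha_family, cfg.resolve_m_tests())
    manifest = {
        "package": "mrpipe",
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items()},
        "m_tests": cfg.resolve_m_tests(),
        "bonferroni_threshold": threshold,
        "bonferroni_display": display,
        "warnings": warnings,
        "outputs": [
            "primary_estimates.tsv",
            "sensitivity_estimates.tsv",
            "meta_estimates.tsv",
            "instrument_audit.tsv",
            "presso_summary.tsv",
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
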