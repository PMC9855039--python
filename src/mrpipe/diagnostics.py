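"""Pleiotropy and influence diagnostics.

Covers the sensitivity toolkit around the point estimators: the MR-Egger
intercept test for directional pleiotropy, MR-PRESSO (global residual test,
per-SNP outlier test, distortion test), leave-one-out influence analysis,
and the data tables behind scatter, forest and funnel displays.

Diagnostics that cannot run for a dataset (too few instruments) return an
explicit "not evaluable" status rather than being silently absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientInstrumentsError, ValidationError
from .estimators import (
    MREstimate,
    egger,
    ivw,
    ratio_estimates,
    wald_ratio,
)
from .instruments import MRDataset

__all__ = [
    "InterceptTest",
    "PressoResult",
    "LeaveOneOutTable",
    "egger_intercept_test",
    "presso",
    "leave_one_out",
    "plot_tables",
]


@dataclass(frozen=True)
class InterceptTest:
    """MR-Egger intercept test for average directional pleiotropy."""

    evaluable: bool
    intercept: float | None = None
    se: float | None = None
    pval: float | None = None
    pleiotropy_flag: bool = False
    reason: str = ""


def egger_intercept_test(data: MRDataset, alpha: float = 0.05) -> InterceptTest:
    """Test whether the Egger intercept differs from zero at level ``alpha``.

    A nonzero intercept indicates average directional pleiotropy, in which
    case the IVW estimate is biased and the Egger slope is preferred.
    Datasets with fewer than 3 instruments return ``evaluable=False``.
    """
    if data.n_snp < 3:
        return InterceptTest(evaluable=False, reason=f"needs >= 3 instruments, got {data.n_snp}")
    est = egger(data, se_method="analytic")
    return InterceptTest(
        evaluable=True,
        intercept=est.egger_intercept,
        se=est.egger_intercept_se,
        pval=est.egger_intercept_p,
        pleiotropy_flag=est.egger_intercept_p < alpha,
    )


# ---------------------------------------------------------------------------
# MR-PRESSO


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    evaluable: bool
    reason: str = ""
    rss_obs: float | None = None
    global_p: float | None = None
    n_sim: int = 0
    outlier_p: dict[str, float] = field(default_factory=dict)
    outliers: tuple[str, ...] = ()
    estimate_all: MREstimate | None = None
    estimate_no_outliers: MREstimate | None = None
    distortion_pct: float | None = None
    distortion_p: float | None = None
    seed: int | None = None


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out origin-constrained WLS slopes, via sum subtraction.

    Works on 1-D arrays or 2-D (n_sim, J) arrays; returns the same shape.
    """
    num = w * bx * by
    den = w * bx**2
    tot_num = num.sum(axis=-1, keepdims=True)
    tot_den = den.sum(axis=-1, keepdims=True)
    return (tot_num - num) / (tot_den - den)


def presso(
    data: MRDataset,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
    n_distortion: int = 1000,
) -> PressoResult:
    """MR-PRESSO: residual-sum-of-squares pleiotropy test with outlier removal.

    The observed statistic is RSS = sum_j w_j (by_j - theta_(-j)·bx_j)² with
    theta_(-j) the leave-one-out IVW estimate and w_j = se_out_j^-2.  Null
    replicates draw bx* ~ N(bx, se_exp) and by* ~ N(mean, se_out) and
    recompute the statistic the same way (leave-one-out slopes refit on the
    replicate).  The global test simulates under the single-slope null
    (mean = theta_full·bx, theta_full the full-sample IVW slope), which
    holds the test near its nominal size; the per-SNP outlier test simulates
    each term under its leave-one-out slope (mean = theta_(-j)·bx_j), so a
    gross outlier does not contaminate its own null.  Empirical p-values
    carry an add-one correction so they are never zero.

    Per-SNP outlier p-values compare each observed residual term with its
    simulated distribution, Bonferroni-adjusted across the J instruments.
    When outliers are flagged, the IVW estimate is recomputed without them
    and the distortion test compares the induced change in theta against
    random same-size subset removals.

    Requires more than 3 instruments; smaller datasets return an explicit
    not-evaluable result.
    """
    if seed is None:
        raise ValidationError("presso requires a seed")
    if data.n_snp <= 3:
        return PressoResult(
            evaluable=False, reason=f"needs > 3 instruments, got {data.n_snp}", seed=seed
        )

    bx = np.array([i.beta_exp for i in data.instruments])
    sx = np.array([i.se_exp for i in data.instruments])
    by = np.array([i.beta_out for i in data.instruments])
    sy = np.array([i.se_out for i in data.instruments])
    snp_ids = [i.snp_id for i in data.instruments]
    w = sy**-2.0
    J = len(bx)
    rng = np.random.default_rng(seed)

    theta_loo = _loo_slopes(bx, by, w)
    theta_full = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    terms_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(terms_obs.sum())

    # global test: replicates under the single-slope null
    bx_star = rng.normal(bx, sx, size=(n_sim, J))
    by_star = rng.normal(theta_full * bx, sy, size=(n_sim, J))
    theta_loo_star = _loo_slopes(bx_star, by_star, w)
    rss_star = (w * (by_star - theta_loo_star * bx_star) ** 2).sum(axis=1)

    # outlier test: each term's replicates under its leave-one-out slope
    bx_star_o = rng.normal(bx, sx, size=(n_sim, J))
    by_star_o = rng.normal(theta_loo * bx, sy, size=(n_sim, J))
    theta_loo_star_o = _loo_slopes(bx_star_o, by_star_o, w)
    terms_star = w * (by_star_o - theta_loo_star_o * bx_star_o) ** 2

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + np.sum(terms_star >= terms_obs, axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * J)
    outlier_p = dict(zip(snp_ids, p_adj.tolist()))
    outliers = tuple(s for s, p in outlier_p.items() if p < outlier_alpha)

    estimate_all = ivw(data)
    estimate_no, distortion_pct, distortion_p = None, None, None
    if outliers and len(outliers) < J:
        reduced = data.drop(outliers)
        estimate_no = ivw(reduced)
        if estimate_no.beta != 0:
            distortion_pct = float(
                100 * (estimate_all.beta - estimate_no.beta) / abs(estimate_no.beta)
            )
            # null distribution: distortion induced by removing random subsets
            # of the same size
            k_keep = J - len(outliers)
            d_null = np.empty(n_distortion)
            for b in range(n_distortion):
                keep = rng.choice(J, size=k_keep, replace=False)
                num = np.sum(w[keep] * bx[keep] * by[keep])
                den = np.sum(w[keep] * bx[keep] ** 2)
                theta_b = num / den
                d_null[b] = 100 * (estimate_all.beta - theta_b) / abs(theta_b)
            distortion_p = float(
                (1 + np.sum(np.abs(d_null) >= abs(distortion_pct))) / (n_distortion + 1)
            )

    return PressoResult(
        evaluable=True,
        rss_obs=rss_obs,
        global_p=global_p,
        n_sim=n_sim,
        outlier_p=outlier_p,
        outliers=outliers,
        estimate_all=estimate_all,
        estimate_no_outliers=estimate_no,
        distortion_pct=distortion_pct,
        distortion_p=distortion_p,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# leave-one-out


@dataclass(frozen=True)
class LeaveOneOutTable:
    """Re-estimates of the causal effect with each instrument omitted in turn."""

    rows: tuple[tuple[str, MREstimate], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "excluded_snp": [s for s, _ in self.rows],
                "method": [e.method for _, e in self.rows],
                "n_snp": [e.n_snp for _, e in self.rows],
                "beta": [e.beta for _, e in self.rows],
                "se": [e.se for _, e in self.rows],
                "pval": [e.pval for _, e in self.rows],
            }
        )


def leave_one_out(data: MRDataset, effect_model: str = "auto", q_alpha: float = 0.05) -> LeaveOneOutTable:
    """IVW re-estimates omitting one instrument at a time (Wald when J-1 = 1)."""
    if data.n_snp < 2:
        raise InsufficientInstrumentsError("leave-one-out needs >= 2 instruments")
    rows = []
    for inst in data.instruments:
        reduced = data.drop([inst.snp_id])
        if reduced.n_snp == 1:
            est = wald_ratio(reduced.instruments[0])
        else:
            est = ivw(reduced, effect_model=effect_model, q_alpha=q_alpha)
        rows.append((inst.snp_id, est))
    return LeaveOneOutTable(rows=tuple(rows))


# ---------------------------------------------------------------------------
# plot data tables


def plot_tables(data: MRDataset, estimates: Sequence[MREstimate]) -> dict[str, pd.DataFrame]:
    """Data tables behind the standard MR displays.

    Returns ``scatter`` (per-SNP effect pairs with error bars, plus one
    fitted line per estimate: slope and intercept), ``forest`` (per-SNP Wald
    ratios with pooled rows appended), and ``funnel`` (ratio vs precision).
    """
    if not estimates:
        raise ValidationError("plot_tables needs at least one estimate")
    ratios = ratio_estimates(data)

    scatter_points = data.to_frame()[["snp", "beta_exp", "se_exp", "beta_out", "se_out"]]
    lines = pd.DataFrame(
        {
            "method": [e.method for e in estimates],
            "slope": [e.beta for e in estimates],
            "intercept": [e.egger_intercept if e.egger_intercept is not None else 0.0 for e in estimates],
        }
    )

    forest = pd.DataFrame(
        {
            "label": [r.snp_id for r in ratios] + [e.method for e in estimates],
            "kind": ["snp"] * len(ratios) + ["pooled"] * len(estimates),
            "beta": [r.beta_ratio for r in ratios] + [e.beta for e in estimates],
            "se": [r.se_ratio for r in ratios] + [e.se for e in estimates],
        }
    )
    forest["ci_low"] = forest["beta"] - 1.959963984540054 * forest["se"]
    forest["ci_high"] = forest["beta"] + 1.959963984540054 * forest["se"]

    funnel = pd.DataFrame(
        {
            "snp": [r.snp_id for r in ratios],
            "beta_ratio": [r.beta_ratio for r in ratios],
            "precision": [1 / r.se_ratio for r in ratios],
        }
    )
    return {"scatter": scatter_points, "scatter_lines": lines, "forest": forest, "funnel": funnel}
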