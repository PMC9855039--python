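"""Summary-data causal estimators for two-sample Mendelian randomization.

Each instrument j contributes a Wald ratio beta_out_j / beta_exp_j with
first-order standard error se_out_j / |beta_exp_j|.  The estimators pool
these ratios under different identifying assumptions:

* **IVW** — inverse-variance-weighted mean of the ratios, algebraically the
  weighted least-squares slope through the origin of beta_out on beta_exp
  with weights se_out^-2.  Valid when every instrument is valid or any
  horizontal pleiotropy is balanced.  The fixed-effect SE is (sum w)^-1/2;
  the random-effects (multiplicative) SE inflates it by max(1, sqrt(Q/(J-1))).
* **MR-Egger** — the same regression with an unconstrained intercept; the
  slope is consistent under InSIDE even with directional pleiotropy, and the
  intercept estimates the average pleiotropic effect.
* **Weighted median** — the weighted median of the ratios; consistent when
  at least half the weight comes from valid instruments.
* **Likelihood-based MR** — joint normal likelihood for the exposure and
  outcome effects with a common proportionality parameter theta, maximized
  by profiling out the per-SNP true exposure effects.

Heterogeneity among ratios is quantified by Cochran's Q and I².
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import EstimationError, InsufficientInstrumentsError, UndefinedRatioError, ValidationError
from .instruments import HarmonizedInstrument, MRDataset

__all__ = [
    "RatioEstimate",
    "MREstimate",
    "HeterogeneityStats",
    "wald_ratio",
    "ratio_estimates",
    "ivw",
    "cochran_q",
    "egger",
    "weighted_median",
    "likelihood_mr",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with first-order SE and inverse-variance weight."""

    snp_id: str
    beta_ratio: float
    se_ratio: float

    @property
    def weight(self) -> float:
        return self.se_ratio**-2


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q with its chi-square p-value and the I² percentage."""

    q: float
    df: int
    pval: float
    i2: float


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-OR scale with derived OR views."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    q: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None

    def __post_init__(self):
        if not self.se > 0:
            raise ValidationError(f"{self.method}: se must be positive, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.method}: pval must lie in (0, 1], got {self.pval}")

    @property
    def ci_low(self) -> float:
        return self.beta - _Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + _Z95 * self.se

    @property
    def or_scale(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def _normal_p(beta: float, se: float) -> float:
    p = 2 * stats.norm.sf(abs(beta) / se)
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def _t_p(beta: float, se: float, df: int) -> float:
    p = 2 * stats.t.sf(abs(beta) / se, df)
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def _arrays(data: MRDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = np.array([i.beta_exp for i in data.instruments])
    sx = np.array([i.se_exp for i in data.instruments])
    by = np.array([i.beta_out for i in data.instruments])
    sy = np.array([i.se_out for i in data.instruments])
    return bx, sx, by, sy


# ---------------------------------------------------------------------------
# per-SNP ratios and heterogeneity


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-instrument causal estimate: beta_out/beta_exp, SE se_out/|beta_exp|."""
    if inst.beta_exp == 0:
        raise UndefinedRatioError(f"{inst.snp_id}: beta_exp is zero, Wald ratio undefined")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    return MREstimate(method="wald", beta=beta, se=se, pval=_normal_p(beta, se), n_snp=1)


def ratio_estimates(data: MRDataset) -> list[RatioEstimate]:
    out = []
    for inst in data.instruments:
        if inst.beta_exp == 0:
            raise UndefinedRatioError(f"{inst.snp_id}: beta_exp is zero, Wald ratio undefined")
        out.append(
            RatioEstimate(inst.snp_id, inst.beta_out / inst.beta_exp, inst.se_out / abs(inst.beta_exp))
        )
    return out


def cochran_q(ratios: Sequence[RatioEstimate], theta: float) -> HeterogeneityStats:
    """Cochran's Q = sum w_j (ratio_j - theta)² with df = J - 1, plus I²."""
    if len(ratios) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 instruments")
    w = np.array([r.weight for r in ratios])
    b = np.array([r.beta_ratio for r in ratios])
    q = float(np.sum(w * (b - theta) ** 2))
    df = len(ratios) - 1
    pval = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100
    return HeterogeneityStats(q=q, df=df, pval=pval, i2=i2)


# ---------------------------------------------------------------------------
# IVW


def ivw(data: MRDataset, effect_model: str = "auto", q_alpha: float = 0.05) -> MREstimate:
    """Inverse-variance-weighted estimate across the dataset's instruments.

    ``effect_model`` is ``"fixed"``, ``"random"`` (multiplicative SE
    inflation by max(1, sqrt(Q/(J-1)))), or ``"auto"``, which uses the
    random-effects SE exactly when the Q test is significant at ``q_alpha``.
    A single-instrument dataset delegates to the Wald ratio.
    """
    if data.n_snp == 0:
        raise InsufficientInstrumentsError("IVW on an empty dataset")
    if data.n_snp == 1:
        return wald_ratio(data.instruments[0])
    return ivw_from_ratios(ratio_estimates(data), effect_model, q_alpha)


def ivw_from_ratios(
    ratios: Sequence[RatioEstimate], effect_model: str = "auto", q_alpha: float = 0.05
) -> MREstimate:
    if effect_model not in ("fixed", "random", "auto"):
        raise ValidationError(f"unknown effect_model {effect_model!r}")
    if len(ratios) == 1:
        r = ratios[0]
        return MREstimate(
            method="wald", beta=r.beta_ratio, se=r.se_ratio,
            pval=_normal_p(r.beta_ratio, r.se_ratio), n_snp=1,
        )
    w = np.array([r.weight for r in ratios])
    b = np.array([r.beta_ratio for r in ratios])
    theta = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    het = cochran_q(ratios, theta)
    inflation = max(1.0, np.sqrt(het.q / het.df))
    if effect_model == "auto":
        effect_model = "random" if het.pval < q_alpha else "fixed"
    se = se_fixed * inflation if effect_model == "random" else se_fixed
    return MREstimate(
        method=f"ivw_{'re' if effect_model == 'random' else 'fe'}",
        beta=theta,
        se=se,
        pval=_normal_p(theta, se),
        n_snp=len(ratios),
        q=het.q,
        q_pval=het.pval,
    )


# ---------------------------------------------------------------------------
# MR-Egger


def _wls_line(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of by on bx with intercept; returns (slope, intercept)."""
    sw = w.sum()
    mx = np.sum(w * bx) / sw
    my = np.sum(w * by) / sw
    sxx = np.sum(w * (bx - mx) ** 2)
    if sxx <= 0:
        raise EstimationError("singular design: all exposure effects identical")
    slope = float(np.sum(w * (bx - mx) * (by - my)) / sxx)
    intercept = float(my - slope * mx)
    return slope, intercept


def egger(
    data: MRDataset,
    se_method: str = "analytic",
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """MR-Egger regression: weighted regression of beta_out on beta_exp with intercept.

    Instruments are first oriented so every exposure effect is positive
    (simultaneous sign flips leave the causal estimand unchanged but fix the
    intercept's meaning).  Weights are se_out^-2; analytic SEs use the
    weighted-least-squares residual dispersion with t(J-2) reference
    distributions, so the intercept test holds its nominal size when the
    ratio variances are proportional to the weights.
    ``se_method="bootstrap"`` replaces the slope SE by the standard
    deviation of slopes refit on parametric resamples of the summary
    statistics.
    """
    if data.n_snp < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {data.n_snp}")
    bx, sx, by, sy = _arrays(data)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = sy**-2.0
    J = len(bx)

    slope, intercept = _wls_line(bx, by, w)
    resid = by - intercept - slope * bx
    rss = float(np.sum(w * resid**2))
    dispersion = max(rss / (J - 2), np.finfo(float).tiny)  # exact fits keep se > 0
    sw = w.sum()
    mx = np.sum(w * bx) / sw
    sxx = float(np.sum(w * (bx - mx) ** 2))
    se_slope = float(np.sqrt(dispersion / sxx))
    se_intercept = float(np.sqrt(dispersion * (1 / sw + mx**2 / sxx)))

    if se_method == "bootstrap":
        if seed is None:
            raise ValidationError("bootstrap SEs require a seed")
        rng = np.random.default_rng(seed)
        bx_star = rng.normal(bx, sx, size=(n_boot, J))
        by_star = rng.normal(by, sy, size=(n_boot, J))
        # vectorized closed-form WLS per resample (weights fixed at se_out^-2)
        mxs = (w * bx_star).sum(axis=1) / sw
        mys = (w * by_star).sum(axis=1) / sw
        dx = bx_star - mxs[:, None]
        sxx_star = (w * dx**2).sum(axis=1)
        slopes = (w * dx * (by_star - mys[:, None])).sum(axis=1) / sxx_star
        se_slope = float(np.std(slopes, ddof=1))
    elif se_method != "analytic":
        raise ValidationError(f"unknown se_method {se_method!r}")

    return MREstimate(
        method="egger",
        beta=slope,
        se=se_slope,
        pval=_t_p(slope, se_slope, J - 2),
        n_snp=J,
        q=rss,
        q_pval=float(stats.chi2.sf(rss, J - 2)),
        egger_intercept=intercept,
        egger_intercept_se=se_intercept,
        egger_intercept_p=_t_p(intercept, se_intercept, J - 2),
    )


# ---------------------------------------------------------------------------
# weighted median


def _weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    """Weighted median by linear interpolation at cumulative midpoint 0.5.

    Sort the ratios ascending; place each at the midpoint of its cumulative
    standardized weight; interpolate at one half.  Outside [p_1, p_J] the
    extreme ratio is returned.
    """
    order = np.argsort(b)
    b, w = b[order], w[order]
    wn = w / w.sum()
    p = np.cumsum(wn) - wn / 2
    return float(np.interp(0.5, p, b))


def weighted_median(
    data: MRDataset, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimator with a parametric-bootstrap SE.

    Consistent when instruments carrying at least half the total inverse-
    variance weight are valid.  The SE is the standard deviation of the
    estimator over ``n_boot`` parametric resamples of the per-SNP summary
    statistics.
    """
    if data.n_snp < 3:
        raise InsufficientInstrumentsError(
            f"weighted median needs >= 3 instruments, got {data.n_snp}"
        )
    if seed is None:
        raise ValidationError("weighted_median requires a seed for its bootstrap SE")
    bx, sx, by, sy = _arrays(data)
    ratios = by / bx
    w = (sy / np.abs(bx)) ** -2.0
    theta = _weighted_median(ratios, w)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, len(bx)))
    by_star = rng.normal(by, sy, size=(n_boot, len(bx)))
    draws = np.empty(n_boot)
    for i in range(n_boot):
        bxi = bx_star[i]
        bxi = np.where(bxi == 0, np.finfo(float).tiny, bxi)
        ri = by_star[i] / bxi
        wi = (sy / np.abs(bxi)) ** -2.0
        draws[i] = _weighted_median(ri, wi)
    se = float(np.std(draws, ddof=1))
    return MREstimate(
        method="weighted_median", beta=theta, se=se, pval=_normal_p(theta, se), n_snp=data.n_snp
    )


# ---------------------------------------------------------------------------
# likelihood-based MR


def _profile_loglik(theta: float, bx, sx, by, sy) -> float:
    """Log-likelihood profiled over the per-SNP true exposure effects.

    Given theta, the maximizing xi_j has the closed form
    (bx_j/sx_j² + theta·by_j/sy_j²) / (sx_j^-2 + theta²·sy_j^-2).
    """
    xi = (bx / sx**2 + theta * by / sy**2) / (sx**-2.0 + theta**2 / sy**2)
    return float(
        -0.5 * np.sum(((bx - xi) / sx) ** 2) - 0.5 * np.sum(((by - theta * xi) / sy) ** 2)
    )


def likelihood_mr(data: MRDataset) -> MREstimate:
    """Maximum-likelihood estimate of the proportionality parameter theta.

    The model is bx_j ~ N(xi_j, sx_j²), by_j ~ N(theta·xi_j, sy_j²) with
    independent errors.  The per-SNP nuisance effects xi_j are profiled out
    in closed form; theta is found by 1-D optimization and its SE from the
    numerical curvature of the profile log-likelihood at the maximum.
    """
    if data.n_snp < 2:
        raise InsufficientInstrumentsError(
            f"likelihood-based MR needs >= 2 instruments, got {data.n_snp}"
        )
    bx, sx, by, sy = _arrays(data)
    start = ivw(data, effect_model="fixed").beta
    span = 10 * abs(start) + 10
    res = optimize.minimize_scalar(
        lambda t: -_profile_loglik(t, bx, sx, by, sy),
        bounds=(start - span, start + span),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise EstimationError(f"likelihood-based MR failed to converge: {res.message}")
    theta = float(res.x)
    h = 1e-4 * (1 + abs(theta))
    curv = (
        _profile_loglik(theta + h, bx, sx, by, sy)
        - 2 * _profile_loglik(theta, bx, sx, by, sy)
        + _profile_loglik(theta - h, bx, sx, by, sy)
    ) / h**2
    if curv >= 0:
        raise EstimationError("profile log-likelihood is not locally concave at the optimum")
    se = float(np.sqrt(-1 / curv))
    return MREstimate(
        method="max_likelihood", beta=theta, se=se, pval=_normal_p(theta, se), n_snp=data.n_snp
    )
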