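"""Cross-database meta-analysis, MR power for binary outcomes, and multiplicity.

Per-database causal estimates (log-OR scale) are pooled by inverse-variance
fixed-effect or DerSimonian–Laird random-effects meta-analysis, with
Cochran's Q and I² quantifying between-database heterogeneity.  Power for a
binary outcome follows the standard non-centrality approximation used by MR
power calculators: with n outcome samples, case fraction K, instrument
r² on the exposure, and true odds ratio OR,

    lambda = |ln OR| * sqrt(n * r2 * K * (1 - K))
    power  = Phi(lambda - z_{1-alpha/2}) + Phi(-lambda - z_{1-alpha/2}).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, ValidationError
from .estimators import MREstimate, _normal_p

__all__ = [
    "MetaEstimate",
    "PowerResult",
    "meta_fixed",
    "meta_random",
    "meta_auto",
    "i_squared",
    "mr_power_binary",
    "bonferroni_threshold",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MetaEstimate:
    """Pooled estimate across databases with heterogeneity statistics."""

    beta_pooled: float
    se_pooled: float
    pval: float
    model: str  # fixed | random
    k: int
    q: float
    q_pval: float | None
    i2: float
    tau2: float = 0.0

    def __post_init__(self):
        if self.model == "fixed" and self.tau2 != 0.0:
            raise ValidationError("fixed-effect meta-analysis forces tau2 = 0")
        if not (0 <= self.i2 <= 100):
            raise ValidationError(f"i2 out of range: {self.i2}")

    @property
    def ci_low(self) -> float:
        return self.beta_pooled - _Z95 * self.se_pooled

    @property
    def ci_high(self) -> float:
        return self.beta_pooled + _Z95 * self.se_pooled

    @property
    def or_scale(self) -> float:
        return math.exp(self.beta_pooled)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


def i_squared(q: float, df: int) -> float:
    """I² heterogeneity percentage: max(0, (Q - df)/Q) * 100; 0 when Q = 0."""
    if df < 1:
        raise ValidationError(f"df must be >= 1, got {df}")
    if q <= 0:
        return 0.0
    return max(0.0, (q - df) / q) * 100


def _pool(betas: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    beta = float(np.sum(weights * betas) / np.sum(weights))
    se = float(np.sum(weights) ** -0.5)
    return beta, se


def _meta_q(betas: np.ndarray, w: np.ndarray) -> float:
    beta_f = np.sum(w * betas) / np.sum(w)
    return float(np.sum(w * (betas - beta_f) ** 2))


def meta_fixed(estimates: Sequence[MREstimate]) -> MetaEstimate:
    """Fixed-effect inverse-variance pooling of per-database estimates."""
    if len(estimates) < 1:
        raise InsufficientInstrumentsError("meta-analysis needs at least 1 estimate")
    betas = np.array([e.beta for e in estimates])
    w = np.array([e.se for e in estimates]) ** -2.0
    beta, se = _pool(betas, w)
    k = len(estimates)
    q = _meta_q(betas, w) if k > 1 else 0.0
    q_pval = float(stats.chi2.sf(q, k - 1)) if k > 1 else None
    return MetaEstimate(
        beta_pooled=beta,
        se_pooled=se,
        pval=_normal_p(beta, se),
        model="fixed",
        k=k,
        q=q,
        q_pval=q_pval,
        i2=i_squared(q, k - 1) if k > 1 else 0.0,
    )


def meta_random(estimates: Sequence[MREstimate]) -> MetaEstimate:
    """DerSimonian–Laird random-effects pooling.

    tau² = max(0, (Q - (k-1)) / (sum w - sum w²/sum w)) with fixed-effect
    weights w = se^-2; the pooled estimate re-weights by 1/(se² + tau²).
    """
    if len(estimates) < 2:
        raise InsufficientInstrumentsError("random-effects meta-analysis needs >= 2 estimates")
    betas = np.array([e.beta for e in estimates])
    se = np.array([e.se for e in estimates])
    w = se**-2.0
    k = len(estimates)
    q = _meta_q(betas, w)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    beta, se_pooled = _pool(betas, w_star)
    return MetaEstimate(
        beta_pooled=beta,
        se_pooled=se_pooled,
        pval=_normal_p(beta, se_pooled),
        model="random",
        k=k,
        q=q,
        q_pval=float(stats.chi2.sf(q, k - 1)),
        i2=i_squared(q, k - 1),
        tau2=float(tau2),
    )


def meta_auto(estimates: Sequence[MREstimate], q_alpha: float = 0.05) -> MetaEstimate:
    """Fixed-effect pooling unless the between-database Q test is significant."""
    fixed = meta_fixed(estimates)
    if fixed.k >= 2 and fixed.q_pval is not None and fixed.q_pval < q_alpha:
        return meta_random(estimates)
    return fixed


# ---------------------------------------------------------------------------
# power


@dataclass(frozen=True)
class PowerResult:
    """Power of a two-sample MR test on a binary outcome."""

    n: int
    k_case: float
    r2_xz: float
    or_true: float
    alpha: float
    power: float


def mr_power_binary(
    n: int, k_case: float, r2_xz: float, or_true: float, alpha: float = 0.05
) -> PowerResult:
    """Approximate power of the two-sided MR Wald test for a binary outcome.

    Uses the normal approximation with non-centrality
    |ln OR| * sqrt(n * r2_xz * K * (1 - K)).  Power is exactly ``alpha``
    at OR = 1 (both rejection tails counted) and is symmetric in
    OR <-> 1/OR.
    """
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    if not (0 < k_case < 1):
        raise ValidationError(f"k_case must lie in (0, 1), got {k_case}")
    if not (0 <= r2_xz <= 1):
        raise ValidationError(f"r2_xz must lie in [0, 1], got {r2_xz}")
    if or_true <= 0:
        raise ValidationError(f"or_true must be positive, got {or_true}")
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    b = math.log(or_true)
    lam = abs(b) * math.sqrt(n * r2_xz * k_case * (1 - k_case))
    z = stats.norm.ppf(1 - alpha / 2)
    power = float(stats.norm.cdf(lam - z) + stats.norm.cdf(-lam - z))
    return PowerResult(n=n, k_case=k_case, r2_xz=r2_xz, or_true=or_true, alpha=alpha, power=power)


def bonferroni_threshold(alpha_family: float, m: int) -> tuple[float, float]:
    """Per-test threshold alpha/m with a one-significant-figure display value."""
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    if not (0 < alpha_family < 1):
        raise ValidationError(f"alpha_family must lie in (0, 1), got {alpha_family}")
    threshold = alpha_family / m
    display = float(f"{threshold:.0e}")
    return threshold, display
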