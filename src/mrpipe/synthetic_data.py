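"""Synthetic two-sample GWAS summary statistics with known ground truth.

Generates the statistical structure the MR pipeline assumes: two
non-overlapping cohorts — an exposure cohort with a continuous trait and an
outcome cohort with a binary disorder — genotyped at J independent
Hardy–Weinberg SNPs.  The exposure is

    X = sum_j gamma_j G_j + eps,   eps ~ N(0, 1 - r2_xz),

with the per-SNP effects gamma_j scaled so the instruments jointly explain
``r2_xz`` of the exposure variance (mirroring the "explained variance"
reported for real instrument sets).  Disease liability is logistic:

    Y ~ Bernoulli(expit(a0 + theta * X + sum_j alpha_j G_j)),

where theta is the true causal log-OR per exposure unit, the alpha_j encode
the horizontal-pleiotropy architecture, and a0 is solved numerically so the
realized case fraction matches the target prevalence.

Each cohort is then summarized SNP-by-SNP exactly as a GWAS would: ordinary
least squares for the continuous exposure, maximum-likelihood logistic
regression for the binary outcome (so outcome effects are log-ORs).  The
generator is fully deterministic given (scenario, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import ValidationError
from .instruments import HarmonizedInstrument, MRDataset
from .sumstats_io import VariantAssociation, write_sumstats

__all__ = [
    "PleiotropyModel",
    "SimulationScenario",
    "SyntheticTruth",
    "simulate_cohorts",
    "summarize_gwas",
    "simulate_summary_stats",
    "make_two_sample_dataset",
    "dataset_from_sumstats",
    "scenario_preset",
    "PRESETS",
]

# non-palindromic allele pairs, cycled across SNPs so harmonization is lossless
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass(frozen=True)
class PleiotropyModel:
    """Horizontal-pleiotropy architecture for the outcome model.

    ``kind``:
      * ``none`` — all alpha_j = 0 (valid instruments).
      * ``balanced`` — alpha_j ~ N(0, sd²): zero-mean direct effects.
      * ``directional`` — alpha_j ~ N(mean, sd²): nonzero average effect.
      * ``single_outlier`` — one SNP (the first) receives a direct effect;
        ``effect`` sets it absolutely, or ``times_se`` expresses it as a
        multiple of that SNP's approximate outcome-GWAS standard error.
      * ``contaminated`` — a fraction ``frac`` of SNPs (the first ones)
        receive alpha_j = ``ratio_shift`` * gamma_j, shifting their Wald
        ratios by ``ratio_shift``.
    """

    kind: Literal["none", "balanced", "directional", "single_outlier", "contaminated"] = "none"
    mean: float = 0.0
    sd: float = 0.0
    effect: float | None = None
    times_se: float | None = None
    frac: float = 0.0
    ratio_shift: float = 0.0

    def realize(
        self,
        rng: np.random.Generator,
        gamma: np.ndarray,
        approx_se_out: np.ndarray,
    ) -> np.ndarray:
        j = len(gamma)
        if self.kind == "none":
            return np.zeros(j)
        if self.kind == "balanced":
            return rng.normal(0.0, self.sd, size=j)
        if self.kind == "directional":
            return rng.normal(self.mean, self.sd, size=j)
        if self.kind == "single_outlier":
            alpha = np.zeros(j)
            if self.effect is not None:
                alpha[0] = self.effect
            elif self.times_se is not None:
                alpha[0] = self.times_se * approx_se_out[0]
            else:
                raise ValidationError("single_outlier needs effect or times_se")
            return alpha
        if self.kind == "contaminated":
            alpha = np.zeros(j)
            k = int(round(self.frac * j))
            alpha[:k] = self.ratio_shift * gamma[:k]
            return alpha
        raise ValidationError(f"unknown pleiotropy kind {self.kind!r}")


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth generative parameters for one synthetic two-sample study."""

    n_exposure: int = 50_000
    n_outcome: int = 50_000
    j: int = 10
    theta: float = 0.2
    r2_xz: float = 0.02
    prevalence: float = 0.1
    maf: tuple[float, ...] | None = None  # drawn U(0.1, 0.5) when None
    gamma_spread: float = 0.5  # lognormal sd of per-SNP effect magnitudes
    # optional block LD: within consecutive blocks of ld_block_size SNPs,
    # each genotype copies its left neighbour with probability ld_rho
    # (adjacent correlation ~ ld_rho); exists to exercise clumping
    ld_block_size: int = 1
    ld_rho: float = 0.0
    pleiotropy: PleiotropyModel = field(default_factory=PleiotropyModel)
    inside_violation: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.r2_xz < 1):
            raise ValidationError(f"r2_xz must lie in (0, 1), got {self.r2_xz}")
        if not (0 < self.prevalence < 1):
            raise ValidationError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        if self.j < 1 or self.n_exposure < 10 or self.n_outcome < 10:
            raise ValidationError("j and cohort sizes must be sensible positive integers")
        if self.maf is not None:
            if len(self.maf) != self.j:
                raise ValidationError("maf must have length j")
            if not all(0.01 < f < 0.5 for f in self.maf):
                raise ValidationError("maf values must lie in (0.01, 0.5)")
        if not (0 <= self.ld_rho < 1) or self.ld_block_size < 1:
            raise ValidationError("ld_rho must lie in [0, 1) and ld_block_size be >= 1")


@dataclass(frozen=True)
class CohortSample:
    """Individual-level data for one cohort."""

    genotypes: np.ndarray  # (n, J) dosages in {0, 1, 2}
    trait: np.ndarray  # (n,) continuous or 0/1
    trait_type: Literal["continuous", "binary"]


@dataclass
class SyntheticTruth:
    """Everything needed to score the pipeline against the generative truth."""

    scenario: SimulationScenario
    maf: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    theta: float
    r2_xz_target: float
    alpha0: float
    exposure_path: str | None = None
    outcome_path: str | None = None

    def to_json(self) -> str:
        d = {
            "scenario": asdict(self.scenario),
            "maf": self.maf.tolist(),
            "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(),
            "theta": self.theta,
            "r2_xz_target": self.r2_xz_target,
            "alpha0": self.alpha0,
            "exposure_path": self.exposure_path,
            "outcome_path": self.outcome_path,
        }
        return json.dumps(d, indent=2)


def _draw_parameters(
    scenario: SimulationScenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (maf, gamma, alpha) for the scenario."""
    j = scenario.j
    maf = (
        np.asarray(scenario.maf, dtype=float)
        if scenario.maf is not None
        else rng.uniform(0.1, 0.5, size=j)
    )
    if scenario.ld_block_size > 1:
        # the copy mechanism needs a common marginal within each block
        for start in range(0, j, scenario.ld_block_size):
            maf[start:start + scenario.ld_block_size] = maf[start]
    # per-SNP effect magnitudes vary lognormally (GWAS hits span a wide
    # range of effect sizes), scaled jointly to the target r2
    raw = np.exp(scenario.gamma_spread * rng.normal(size=j))
    var_g = 2 * maf * (1 - maf)
    scale = np.sqrt(scenario.r2_xz / np.sum(raw**2 * var_g))
    gamma = raw * scale

    # approximate per-SNP outcome-GWAS SE for a logistic marginal fit
    n, k = scenario.n_outcome, scenario.prevalence
    approx_se_out = 1.0 / np.sqrt(n * k * (1 - k) * var_g)

    alpha = scenario.pleiotropy.realize(rng, gamma, approx_se_out)
    if scenario.inside_violation and scenario.pleiotropy.kind in ("balanced", "directional"):
        # correlate direct effects with instrument strength (InSIDE breach)
        alpha = alpha + 0.5 * np.std(alpha) * (gamma - gamma.mean()) / max(np.std(gamma), 1e-12)
    return maf, gamma, alpha


def _draw_genotypes(
    scenario: SimulationScenario, maf: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Hardy-Weinberg dosages, optionally correlated within LD blocks.

    With ``ld_rho > 0`` each SNP after a block head copies its left
    neighbour's genotype per individual with probability ``ld_rho``, giving
    adjacent genotype correlation ~ ld_rho (so r² ~ ld_rho²) decaying
    geometrically within the block.
    """
    g = rng.binomial(2, maf, size=(n, scenario.j)).astype(np.float64)
    if scenario.ld_rho > 0 and scenario.ld_block_size > 1:
        for k in range(1, scenario.j):
            if k % scenario.ld_block_size == 0:
                continue  # block head: independent
            copy = rng.uniform(size=n) < scenario.ld_rho
            g[copy, k] = g[copy, k - 1]
    return g


def empirical_r2(genotypes: np.ndarray, snp_ids: Sequence[str]) -> dict[tuple[str, str], float]:
    """Pairwise squared genotype correlation, as a clump-ready lookup table."""
    corr = np.corrcoef(genotypes, rowvar=False)
    out = {}
    for a in range(len(snp_ids)):
        for b in range(a + 1, len(snp_ids)):
            out[(snp_ids[a], snp_ids[b])] = float(corr[a, b] ** 2)
    return out


def simulate_cohorts(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> tuple[CohortSample, CohortSample, SyntheticTruth]:
    """Simulate the exposure and outcome cohorts for one scenario.

    The two cohorts are drawn independently (no shared individuals).  The
    liability intercept a0 is solved on the realized outcome-cohort linear
    predictor so the expected case fraction equals the target prevalence.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    maf, gamma, alpha = _draw_parameters(scenario, rng)
    j = scenario.j

    g_exp = _draw_genotypes(scenario, maf, scenario.n_exposure, rng)
    eps = rng.normal(0.0, np.sqrt(1 - scenario.r2_xz), size=scenario.n_exposure)
    x_exp = g_exp @ gamma + eps

    g_out = _draw_genotypes(scenario, maf, scenario.n_outcome, rng)
    eps_out = rng.normal(0.0, np.sqrt(1 - scenario.r2_xz), size=scenario.n_outcome)
    x_out = g_out @ gamma + eps_out  # latent exposure in the outcome cohort
    eta = scenario.theta * x_out + g_out @ alpha

    def mean_prev(a0: float) -> float:
        return float(np.mean(special.expit(a0 + eta))) - scenario.prevalence

    try:
        alpha0 = optimize.brentq(mean_prev, -30.0, 30.0, xtol=1e-10)
    except ValueError as exc:
        raise ValidationError(f"cannot reach target prevalence {scenario.prevalence}") from exc
    y = (rng.uniform(size=scenario.n_outcome) < special.expit(alpha0 + eta)).astype(np.float64)

    truth = SyntheticTruth(
        scenario=scenario,
        maf=maf,
        gamma=gamma,
        alpha=alpha,
        theta=scenario.theta,
        r2_xz_target=scenario.r2_xz,
        alpha0=float(alpha0),
    )
    exposure = CohortSample(g_exp, x_exp, "continuous")
    outcome = CohortSample(g_out, y, "binary")
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# per-SNP GWAS summaries


def _ols_per_snp(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simple-regression slope, SE and p per SNP, vectorized across columns."""
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(gc**2, axis=0)
    beta = gc.T @ yc / sxx
    rss = np.sum(yc**2) - beta**2 * sxx
    se = np.sqrt(rss / (n - 2) / sxx)
    pval = 2 * stats.t.sf(np.abs(beta / se), n - 2)
    return beta, se, pval


def _logistic_per_snp(
    g: np.ndarray, y: np.ndarray, max_iter: int = 25, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic fit (intercept + dosage) per SNP.

    Newton–Raphson run simultaneously across all SNPs; each SNP's model has
    two parameters so the per-iteration update is closed form.  Returns
    (beta, se, pval, converged).
    """
    n, j = g.shape
    b0 = np.full(j, special.logit(np.clip(y.mean(), 1e-12, 1 - 1e-12)))
    b1 = np.zeros(j)
    converged = np.zeros(j, dtype=bool)
    for _ in range(max_iter):
        eta = b0[None, :] + g * b1[None, :]
        p = special.expit(eta)
        w = p * (1 - p)
        r = y[:, None] - p
        u0 = r.sum(axis=0)
        u1 = (g * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * g).sum(axis=0)
        h11 = (w * g**2).sum(axis=0)
        det = h00 * h11 - h01**2
        det = np.where(det <= 0, np.nan, det)
        d0 = (h11 * u0 - h01 * u1) / det
        d1 = (h00 * u1 - h01 * u0) / det
        b0 += np.nan_to_num(d0)
        b1 += np.nan_to_num(d1)
        converged = np.maximum(np.abs(d0), np.abs(d1)) < tol
        if converged.all():
            break
    eta = b0[None, :] + g * b1[None, :]
    p = special.expit(eta)
    w = p * (1 - p)
    h00 = w.sum(axis=0)
    h01 = (w * g).sum(axis=0)
    h11 = (w * g**2).sum(axis=0)
    det = h00 * h11 - h01**2
    se = np.sqrt(h00 / det)
    pval = 2 * stats.norm.sf(np.abs(b1 / se))
    return b1, se, pval, converged


def summarize_gwas(
    sample: CohortSample,
    trait_id: str = "",
    snp_ids: Sequence[str] | None = None,
) -> list[VariantAssociation]:
    """Per-SNP marginal association scan, as a GWAS would release it.

    OLS for continuous traits, maximum-likelihood logistic regression for
    binary traits (betas are log-ORs).  Monomorphic or non-converged SNPs
    are excluded; their indices are reported via a warning on stderr.
    """
    import sys

    g, y = sample.genotypes, sample.trait
    n, j = g.shape
    if snp_ids is None:
        snp_ids = [f"rs{k + 1}" for k in range(j)]
    eaf = g.mean(axis=0) / 2
    poly = (eaf > 0) & (eaf < 1)

    if sample.trait_type == "continuous":
        beta = np.full(j, np.nan)
        se = np.full(j, np.nan)
        pval = np.full(j, np.nan)
        b, s, p = _ols_per_snp(g[:, poly], y)
        beta[poly], se[poly], pval[poly] = b, s, p
        ok = poly
    else:
        beta = np.full(j, np.nan)
        se = np.full(j, np.nan)
        pval = np.full(j, np.nan)
        b, s, p, conv = _logistic_per_snp(g[:, poly], y)
        beta[poly], se[poly], pval[poly] = b, s, p
        ok = poly.copy()
        ok[poly] &= conv & np.isfinite(s)

    records: list[VariantAssociation] = []
    for k in range(j):
        if not ok[k] or not np.isfinite(beta[k]) or not se[k] > 0:
            print(
                f"warning: SNP {snp_ids[k]} excluded from summary "
                f"({'monomorphic' if not poly[k] else 'fit did not converge'})",
                file=sys.stderr,
            )
            continue
        a1, a2 = _ALLELE_PAIRS[k % len(_ALLELE_PAIRS)]
        records.append(
            VariantAssociation(
                snp_id=snp_ids[k],
                effect_allele=a1,
                other_allele=a2,
                beta=float(beta[k]),
                se=float(se[k]),
                pval=float(min(max(pval[k], np.nextafter(0, 1)), 1.0)),
                eaf=float(eaf[k]),
                n=n,
                trait_id=trait_id,
            )
        )
    return records


def simulate_summary_stats(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> tuple[list[VariantAssociation], list[VariantAssociation], SyntheticTruth]:
    """Simulate both cohorts and return their GWAS summary statistics."""
    exposure, outcome, truth = simulate_cohorts(scenario, rng)
    exp_stats = summarize_gwas(exposure, trait_id="exposure")
    out_stats = summarize_gwas(outcome, trait_id="outcome")
    return exp_stats, out_stats, truth


def make_two_sample_dataset(
    scenario: SimulationScenario, outdir: str | Path
) -> tuple[Path, Path, SyntheticTruth]:
    """End-to-end generation: simulate, summarize, and write the TSV pair.

    Outputs are byte-identical across runs with the same (scenario, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp_stats, out_stats, truth = simulate_summary_stats(scenario)
    exp_path = outdir / "exposure_sumstats.tsv"
    out_path = outdir / "outcome_sumstats.tsv"
    write_sumstats(exp_stats, exp_path)
    write_sumstats(out_stats, out_path)
    truth.exposure_path = str(exp_path)
    truth.outcome_path = str(out_path)
    (outdir / "truth.json").write_text(truth.to_json())
    return exp_path, out_path, truth


def dataset_from_sumstats(
    exp_stats: Sequence[VariantAssociation],
    out_stats: Sequence[VariantAssociation],
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    database_id: str = "sim",
) -> MRDataset:
    """Pair already-aligned exposure/outcome summaries into an MRDataset.

    A convenience for simulation studies where both tables come from the
    same generator and share allele orientation by construction; real data
    should go through :func:`mrpipe.instruments.harmonize_dataset`.
    """
    out_by_id = {a.snp_id: a for a in out_stats}
    instruments = [
        HarmonizedInstrument(
            snp_id=e.snp_id,
            beta_exp=e.beta,
            se_exp=e.se,
            beta_out=out_by_id[e.snp_id].beta,
            se_out=out_by_id[e.snp_id].se,
            eaf=e.eaf,
        )
        for e in exp_stats
        if e.snp_id in out_by_id
    ]
    return MRDataset(exposure_id, outcome_id, database_id, instruments)


# ---------------------------------------------------------------------------
# presets: the study conditions exercised by the test-bench


def _preset_map() -> dict[str, SimulationScenario]:
    base = SimulationScenario()
    return {
        # valid instruments, true effect 0.2
        "valid": base,
        # valid instruments, no causal effect
        "null": replace(base, theta=0.0),
        # zero-mean direct effects on all instruments
        "balanced": replace(
            base, pleiotropy=PleiotropyModel(kind="balanced", sd=0.01)
        ),
        # common directional pleiotropy on all instruments, InSIDE holds
        "directional": replace(
            base, pleiotropy=PleiotropyModel(kind="directional", mean=0.01, sd=0.005)
        ),
        # one instrument with a direct effect 10x its outcome-GWAS SE
        "outlier": replace(
            base, pleiotropy=PleiotropyModel(kind="single_outlier", times_se=10.0)
        ),
        # 40% of instruments invalid, ratio shift +0.5.  Instruments are
        # stronger (r2 = 0.10, within the range real micronutrient
        # instrument sets explain) and more homogeneous, so per-SNP ratios
        # resolve the two clusters and the invalid minority stays below
        # half the inverse-variance weight — the regime the weighted
        # median's validity condition describes
        "contaminated": replace(
            base,
            r2_xz=0.10,
            gamma_spread=0.2,
            pleiotropy=PleiotropyModel(kind="contaminated", frac=0.4, ratio_shift=0.5),
        ),
    }


PRESETS = tuple(_preset_map())


def scenario_preset(name: str, seed: int = 0, **overrides) -> SimulationScenario:
    """Named study conditions used throughout the test-bench.

    ``valid`` (theta = 0.2, J = 10, n = 50k/50k, r² = 0.02, prevalence 0.1),
    ``null`` (theta = 0), ``balanced``, ``directional``, ``outlier``, and
    ``contaminated`` — see :class:`PleiotropyModel` for the architectures.
    """
    presets = _preset_map()
    if name not in presets:
        raise ValidationError(f"unknown preset {name!r}; available: {', '.join(presets)}")
    return replace(presets[name], seed=seed, **overrides)
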