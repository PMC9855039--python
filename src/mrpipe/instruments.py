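"""Instrument selection and harmonization for one (exposure, outcome) pair.

The steps mirror standard two-sample MR practice: keep genome-wide-significant
exposure variants, reduce them to a near-independent set by greedy LD
clumping, drop variants associated with known confounders, drop weak
instruments by the F = beta²/se² rule, substitute high-LD proxies for
variants absent from the outcome GWAS, and orient the outcome effect to the
exposure's effect allele.

Every input variant ends up exactly once in the audit log — kept, proxied, or
dropped with a reason — so instrument attrition is fully traceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .sumstats_io import ConfounderHit, ProxyRecord, VariantAssociation

__all__ = [
    "HarmonizedInstrument",
    "MRDataset",
    "AuditEntry",
    "select_significant",
    "clump",
    "drop_ld_unresolved",
    "screen_confounders",
    "filter_weak",
    "substitute_proxies",
    "harmonize",
    "harmonize_dataset",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: eaf window inside which a palindromic SNP's strand cannot be inferred
AMBIGUOUS_EAF_WINDOW = (0.42, 0.58)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects for one SNP, on a common effect allele.

    ``f_stat`` is the instrument-strength statistic beta_exp²/se_exp².
    ``proxy_of`` records the original variant when a proxy was substituted;
    ``flipped`` records whether the outcome effect was sign-flipped during
    harmonization.
    """

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf: float | None = None
    proxy_of: str | None = None
    flipped: bool = False

    def __post_init__(self):
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValidationError(f"{self.snp_id}: standard errors must be positive")

    @property
    def f_stat(self) -> float:
        return self.beta_exp**2 / self.se_exp**2


@dataclass(frozen=True)
class AuditEntry:
    snp_id: str
    stage: str
    action: str  # kept | dropped | proxied
    reason: str = ""


@dataclass
class MRDataset:
    """Harmonized instrument set for one (exposure, outcome, database) triple."""

    exposure_id: str
    outcome_id: str
    database_id: str
    instruments: list[HarmonizedInstrument]
    audit: list[AuditEntry] = field(default_factory=list)

    def __post_init__(self):
        ids = [inst.snp_id for inst in self.instruments]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate snp_ids in MRDataset")

    @property
    def n_snp(self) -> int:
        return len(self.instruments)

    def subset(self, keep: Iterable[str]) -> "MRDataset":
        keep = set(keep)
        return MRDataset(
            self.exposure_id,
            self.outcome_id,
            self.database_id,
            [inst for inst in self.instruments if inst.snp_id in keep],
            list(self.audit),
        )

    def drop(self, remove: Iterable[str]) -> "MRDataset":
        remove = set(remove)
        return self.subset(inst.snp_id for inst in self.instruments if inst.snp_id not in remove)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": [i.snp_id for i in self.instruments],
                "beta_exp": [i.beta_exp for i in self.instruments],
                "se_exp": [i.se_exp for i in self.instruments],
                "beta_out": [i.beta_out for i in self.instruments],
                "se_out": [i.se_out for i in self.instruments],
                "eaf": [i.eaf for i in self.instruments],
                "f_stat": [i.f_stat for i in self.instruments],
                "proxy_of": [i.proxy_of for i in self.instruments],
                "flipped": [i.flipped for i in self.instruments],
            }
        )

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": [a.snp_id for a in self.audit],
                "stage": [a.stage for a in self.audit],
                "action": [a.action for a in self.audit],
                "reason": [a.reason for a in self.audit],
            }
        )


# ---------------------------------------------------------------------------
# selection steps


def select_significant(
    assocs: Sequence[VariantAssociation], p_threshold: float = 5e-8
) -> list[VariantAssociation]:
    """Keep variants with pval strictly below the significance threshold."""
    if not (0 < p_threshold < 1) and p_threshold != 1.0:
        raise ValidationError(f"p_threshold must lie in (0, 1], got {p_threshold}")
    return [a for a in assocs if a.pval < p_threshold]


LDLookup = Callable[[str, str], float] | Mapping[tuple[str, str], float]


def _ld_r2(ld: LDLookup | None, a: str, b: str) -> float:
    if ld is None:
        return 0.0
    if callable(ld):
        return ld(a, b)
    return ld.get((a, b), ld.get((b, a), 0.0))


def clump(
    assocs: Sequence[VariantAssociation],
    ld: LDLookup | None,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
    positions: Mapping[str, tuple[str, int]] | None = None,
) -> list[VariantAssociation]:
    """Greedy LD clumping: keep index variants, discard their LD partners.

    Repeatedly takes the remaining variant with the smallest p-value (ties
    broken by lexicographic snp_id) and discards every remaining variant with
    r² above ``r2_max`` with it.  When ``positions`` maps snp_id to
    (chromosome, basepair), the discard rule only applies within
    ``window_kb``; without positions the r² lookup is authoritative and the
    window is ignored.  Output is sorted by p-value ascending.
    """
    remaining = sorted(assocs, key=lambda a: (a.pval, a.snp_id))
    kept: list[VariantAssociation] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for other in remaining:
            in_window = True
            if positions is not None:
                ci, pi = positions[index.snp_id]
                co, po = positions[other.snp_id]
                in_window = ci == co and abs(pi - po) <= window_kb * 1000
            if in_window and _ld_r2(ld, index.snp_id, other.snp_id) > r2_max:
                continue
            survivors.append(other)
        remaining = survivors
    return kept


def drop_ld_unresolved(
    assocs: Sequence[VariantAssociation],
    ld_panel: set[str] | frozenset[str],
    audit: list[AuditEntry] | None = None,
) -> list[VariantAssociation]:
    """Drop variants absent from the LD reference panel (their LD is unknown)."""
    kept = []
    for a in assocs:
        if a.snp_id in ld_panel:
            kept.append(a)
        elif audit is not None:
            audit.append(AuditEntry(a.snp_id, "ld_panel", "dropped", "absent from LD reference panel"))
    return kept


def screen_confounders(
    assocs: Sequence[VariantAssociation],
    hits: Sequence[ConfounderHit],
    p_conf: float = 5e-8,
    audit: list[AuditEntry] | None = None,
) -> list[VariantAssociation]:
    """Drop variants significantly associated with a known confounder."""
    if not (0 < p_conf < 1):
        raise ValidationError(f"p_conf must lie in (0, 1), got {p_conf}")
    flagged: dict[str, str] = {}
    for hit in hits:
        if hit.pval < p_conf and hit.snp_id not in flagged:
            flagged[hit.snp_id] = hit.confounder_trait
    kept = []
    for a in assocs:
        if a.snp_id in flagged:
            if audit is not None:
                audit.append(
                    AuditEntry(
                        a.snp_id,
                        "confounder_screen",
                        "dropped",
                        f"associated with confounder {flagged[a.snp_id]!r} at p < {p_conf:g}",
                    )
                )
        else:
            kept.append(a)
    return kept


def filter_weak(
    instruments: Sequence[HarmonizedInstrument],
    f_min: float = 10.0,
    audit: list[AuditEntry] | None = None,
) -> list[HarmonizedInstrument]:
    """Keep instruments with F strictly above ``f_min`` (weak-instrument rule)."""
    if not f_min > 0:
        raise ValidationError(f"f_min must be positive, got {f_min}")
    kept = []
    for inst in instruments:
        if inst.f_stat > f_min:
            kept.append(inst)
        elif audit is not None:
            audit.append(
                AuditEntry(
                    inst.snp_id,
                    "weak_filter",
                    "dropped",
                    f"F = {inst.f_stat:.3g} <= {f_min:g}",
                )
            )
    return kept


def substitute_proxies(
    missing: Sequence[str],
    proxies: Sequence[ProxyRecord],
    outcome_snps: set[str] | frozenset[str],
    r2_min: float = 0.8,
    audit: list[AuditEntry] | None = None,
) -> dict[str, ProxyRecord]:
    """Map each missing SNP to its best available proxy, or drop it.

    For each missing SNP the highest-r² proxy with r² >= ``r2_min`` that is
    present in the outcome GWAS is chosen; ties at equal r² resolve to the
    lexicographically smallest proxy snp_id.  SNPs with no acceptable proxy
    are dropped (recorded in the audit); they do not appear in the result.
    """
    by_missing: dict[str, list[ProxyRecord]] = {}
    for p in proxies:
        by_missing.setdefault(p.missing_snp, []).append(p)
    chosen: dict[str, ProxyRecord] = {}
    for snp in missing:
        candidates = [
            p
            for p in by_missing.get(snp, [])
            if p.r2 >= r2_min and p.proxy_snp in outcome_snps
        ]
        if not candidates:
            if audit is not None:
                audit.append(
                    AuditEntry(snp, "proxy", "dropped", "missing from outcome GWAS, no proxy available")
                )
            continue
        best = min(candidates, key=lambda p: (-p.r2, p.proxy_snp))
        chosen[snp] = best
        if audit is not None:
            audit.append(
                AuditEntry(snp, "proxy", "proxied", f"substituted by {best.proxy_snp} (r2 = {best.r2:g})")
            )
    return chosen


# ---------------------------------------------------------------------------
# harmonization


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize(
    exp: VariantAssociation,
    out: VariantAssociation,
    palindrome_policy: str = "infer",
    ambiguity_window: tuple[float, float] = AMBIGUOUS_EAF_WINDOW,
    proxy_of: str | None = None,
) -> tuple[HarmonizedInstrument | None, str]:
    """Orient an outcome association onto the exposure's effect allele.

    Returns ``(instrument, "")`` on success or ``(None, reason)`` when the
    pair must be dropped.  Non-palindromic pairs are aligned directly, or
    after complementing the outcome alleles when the file used the opposite
    strand; if the outcome's alleles are swapped relative to the exposure,
    ``beta_out`` is negated and the outcome eaf complemented.

    Palindromic variants (A/T or C/G) cannot be strand-resolved from alleles
    alone.  Under ``palindrome_policy="infer"`` the orientation minimizing
    the allele-frequency distance between the two studies is used, unless
    either frequency falls in the ambiguous window (default [0.42, 0.58]) or
    is missing, in which case the variant is dropped.  Under ``"drop"`` all
    palindromic variants are dropped.
    """
    ea_x, oa_x = exp.alleles
    ea_y, oa_y = out.alleles
    beta_out, eaf_out = out.beta, out.eaf
    flipped = False

    if _is_palindromic(ea_x, oa_x):
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return None, "allele mismatch"
        if palindrome_policy == "drop":
            return None, "palindromic variant (policy: drop)"
        if palindrome_policy != "infer":
            raise ValidationError(f"unknown palindrome_policy {palindrome_policy!r}")
        if exp.eaf is None or out.eaf is None:
            return None, "palindromic variant with missing eaf"
        lo, hi = ambiguity_window
        if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
            return None, "palindromic variant with ambiguous allele frequency"
        # orientation by frequency distance: same allele should have similar
        # frequency in two same-ancestry studies
        if abs(exp.eaf - out.eaf) > abs(exp.eaf - (1 - out.eaf)):
            beta_out, eaf_out, flipped = -beta_out, 1 - eaf_out, True
    else:
        if {ea_y, oa_y} != {ea_x, oa_x}:
            comp = (_COMPLEMENT[ea_y], _COMPLEMENT[oa_y])
            if set(comp) == {ea_x, oa_x}:
                ea_y, oa_y = comp  # opposite-strand report; effects unchanged
            else:
                return None, "allele mismatch"
        if (ea_y, oa_y) == (oa_x, ea_x):
            beta_out, flipped = -beta_out, True
            if eaf_out is not None:
                eaf_out = 1 - eaf_out
        elif (ea_y, oa_y) != (ea_x, oa_x):
            return None, "allele mismatch"

    return (
        HarmonizedInstrument(
            snp_id=exp.snp_id,
            beta_exp=exp.beta,
            se_exp=exp.se,
            beta_out=beta_out,
            se_out=out.se,
            eaf=exp.eaf,
            proxy_of=proxy_of,
            flipped=flipped,
        ),
        "",
    )


def harmonize_dataset(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    database_id: str = "db",
    p_threshold: float = 5e-8,
    ld: LDLookup | None = None,
    clump_r2: float = 0.001,
    clump_kb: float = 10_000,
    positions: Mapping[str, tuple[str, int]] | None = None,
    ld_panel: set[str] | None = None,
    confounder_hits: Sequence[ConfounderHit] = (),
    p_conf: float = 5e-8,
    f_min: float = 10.0,
    proxies: Sequence[ProxyRecord] = (),
    proxy_r2_min: float = 0.8,
    palindrome_policy: str = "infer",
) -> MRDataset:
    """Run the full instrument-building pipeline for one triple.

    Order: significance filter -> LD-panel check -> clumping -> confounder
    screen -> proxy substitution for variants absent from the outcome ->
    harmonization -> weak-instrument filter.  The audit log accounts for
    every candidate variant exactly once.
    """
    audit: list[AuditEntry] = []

    sig = select_significant(exposure, p_threshold)
    sig_ids = {a.snp_id for a in sig}
    for a in exposure:
        if a.snp_id not in sig_ids:
            audit.append(
                AuditEntry(a.snp_id, "significance", "dropped", f"p = {a.pval:.3g} >= {p_threshold:g}")
            )

    if ld_panel is not None:
        sig = drop_ld_unresolved(sig, ld_panel, audit)

    clumped = clump(sig, ld, clump_r2, clump_kb, positions)
    clumped_ids = {a.snp_id for a in clumped}
    for a in sig:
        if a.snp_id not in clumped_ids:
            audit.append(
                AuditEntry(a.snp_id, "clump", "dropped", f"in LD (r2 > {clump_r2:g}) with a better variant")
            )

    screened = screen_confounders(clumped, confounder_hits, p_conf, audit)

    out_by_id = {a.snp_id: a for a in outcome}
    missing = [a.snp_id for a in screened if a.snp_id not in out_by_id]
    proxy_map = substitute_proxies(missing, proxies, set(out_by_id), proxy_r2_min, audit)

    instruments: list[HarmonizedInstrument] = []
    for a in screened:
        if a.snp_id in out_by_id:
            out_assoc = out_by_id[a.snp_id]
            exp_assoc, proxy_of = a, None
        elif a.snp_id in proxy_map:
            rec = proxy_map[a.snp_id]
            out_assoc = out_by_id[rec.proxy_snp]
            # re-express the exposure variant in the proxy's allele frame
            try:
                exp_assoc = replace(
                    a,
                    snp_id=rec.proxy_snp,
                    effect_allele=rec.allele_map[a.effect_allele],
                    other_allele=rec.allele_map[a.other_allele],
                )
            except KeyError:
                audit.append(AuditEntry(a.snp_id, "proxy", "dropped", "proxy allele map incomplete"))
                continue
            proxy_of = a.snp_id
        else:
            continue  # already audited by substitute_proxies
        inst, reason = harmonize(exp_assoc, out_assoc, palindrome_policy, proxy_of=proxy_of)
        if inst is None:
            audit.append(AuditEntry(a.snp_id, "harmonize", "dropped", reason))
            continue
        instruments.append(inst)

    strong = filter_weak(instruments, f_min, audit)
    for inst in strong:
        if inst.proxy_of is None:
            audit.append(AuditEntry(inst.snp_id, "final", "kept", ""))
        # proxied-and-kept variants keep their "proxied" disposition

    # one final disposition per input variant: the last entry wins
    proxy_to_original = {rec.proxy_snp: orig for orig, rec in proxy_map.items()}
    last: dict[str, AuditEntry] = {}
    for entry in audit:
        key = proxy_to_original.get(entry.snp_id, entry.snp_id)
        if entry.action == "dropped" or key not in last:
            last[key] = entry
        elif last[key].action != "dropped":
            last[key] = entry
    ordered = [last[a.snp_id] for a in exposure if a.snp_id in last]

    return MRDataset(exposure_id, outcome_id, database_id, strong, ordered)
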