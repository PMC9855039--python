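"""Read, validate and write GWAS summary-statistic tables.

The package consumes per-variant association tables ("summary statistics"):
one row per SNP with its effect allele, other allele, effect-allele frequency,
additive effect estimate (log-odds for case-control traits), standard error,
p-value and sample size.  There is no single community standard for column
names, so reading accepts a ``column_map`` translating arbitrary headers onto
the package dialect::

    snp  effect_allele  other_allele  eaf  beta  se  pval  n

Auxiliary tables use the same delimited-text conventions: a proxy table
(``missing_snp, proxy_snp, r2, a1_missing, a1_proxy, a2_missing, a2_proxy``)
for substituting variants absent from an outcome GWAS, and a confounder table
(``snp, trait, pval``) listing known variant-confounder associations.

Validation is total: every malformed row raises a located error rather than
being silently dropped.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, DuplicateVariantError, RowError, ValidationError

__all__ = [
    "VariantAssociation",
    "ProxyRecord",
    "ConfounderHit",
    "read_sumstats",
    "write_sumstats",
    "read_proxy_table",
    "read_confounder_table",
]

_NUCLEOTIDES = frozenset("ACGT")

#: canonical column order of the package dialect
DEFAULT_COLUMNS = ("snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's marginal association with one trait (a GWAS row).

    ``beta`` is the additive per-effect-allele estimate: a log odds ratio for
    binary traits, trait units otherwise.  ``eaf`` and ``n`` are optional;
    downstream steps that need them (palindrome inference, power) degrade per
    their own rules when they are absent.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None
    trait_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if not self.snp_id:
            raise ValidationError("empty snp_id")
        for allele in (self.effect_allele, self.other_allele):
            if allele not in _NUCLEOTIDES:
                raise ValidationError(
                    f"{self.snp_id}: allele {allele!r} is not a single A/C/G/T base "
                    "(indels and multi-allelic variants are not supported)"
                )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.snp_id}: se must be a positive finite number, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: beta must be finite, got {self.beta}")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.snp_id}: pval must lie in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(f"{self.snp_id}: eaf must lie in (0, 1), got {self.eaf}")
        if self.n is not None and (self.n <= 0 or int(self.n) != self.n):
            raise ValidationError(f"{self.snp_id}: n must be a positive integer, got {self.n}")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.effect_allele, self.other_allele)

    def with_trait(self, trait_id: str) -> "VariantAssociation":
        return replace(self, trait_id=trait_id)


@dataclass(frozen=True)
class ProxyRecord:
    """A substitute variant in high LD with one missing from an outcome GWAS.

    ``allele_map`` pairs each allele of the missing SNP with the allele of the
    proxy that travels with it on the same haplotype; it must be a bijection
    over the two alleles of each variant.
    """

    missing_snp: str
    proxy_snp: str
    r2: float
    allele_map: Mapping[str, str]

    def __post_init__(self):
        if not (0 <= self.r2 <= 1):
            raise ValidationError(f"proxy {self.proxy_snp}: r2 must lie in [0, 1], got {self.r2}")
        amap = {k.upper(): v.upper() for k, v in self.allele_map.items()}
        if len(amap) != 2 or len(set(amap.values())) != 2:
            raise ValidationError(
                f"proxy {self.proxy_snp}: allele_map must be a bijection over two alleles"
            )
        object.__setattr__(self, "allele_map", amap)


@dataclass(frozen=True)
class ConfounderHit:
    """A reported association between an instrument SNP and a confounder trait."""

    snp_id: str
    confounder_trait: str
    pval: float

    def __post_init__(self):
        if not (0 < self.pval <= 1):
            raise ValidationError(
                f"{self.snp_id}/{self.confounder_trait}: pval must lie in (0, 1], got {self.pval}"
            )


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _parse_float(token: str, field: str) -> float | None:
    token = token.strip()
    if token in ("", "NA", "NaN", "nan", "."):
        return None
    try:
        return float(token)
    except ValueError:
        raise ValidationError(f"field {field!r}: cannot parse {token!r} as a number")


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str = "",
) -> list[VariantAssociation]:
    """Read a delimited summary-statistics table into validated records.

    Parameters
    ----------
    path
        TSV or CSV file with a header row (delimiter sniffed from the header).
    column_map
        Mapping from package-dialect names (``snp``, ``effect_allele``, ...)
        to the column names actually present in the file.  Unmapped names
        default to themselves.  ``eaf`` and ``n`` are optional columns.
    trait_id
        Trait label attached to every record.

    Raises
    ------
    ConfigError
        If a required mapped column is absent from the header.
    RowError
        If any row violates a record invariant (carries the line number).
    DuplicateVariantError
        If the same snp_id occurs twice.
    """
    path = Path(path)
    cmap = {name: name for name in DEFAULT_COLUMNS}
    if column_map:
        cmap.update(column_map)

    with path.open(newline="") as fh:
        first = fh.readline()
        if not first:
            raise ConfigError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        header = [h.strip() for h in first.rstrip("\n").split(delim)]
        required = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")
        for name in required:
            if cmap[name] not in header:
                raise ConfigError(f"{path}: required column {cmap[name]!r} (for {name!r}) not in header")
        idx = {name: header.index(cmap[name]) for name in DEFAULT_COLUMNS if cmap[name] in header}

        records: list[VariantAssociation] = []
        seen: set[str] = set()
        reader = csv.reader(fh, delimiter=delim)
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                eaf = _parse_float(row[idx["eaf"]], "eaf") if "eaf" in idx else None
                n_val = _parse_float(row[idx["n"]], "n") if "n" in idx else None
                rec = VariantAssociation(
                    snp_id=row[idx["snp"]].strip(),
                    effect_allele=row[idx["effect_allele"]].strip(),
                    other_allele=row[idx["other_allele"]].strip(),
                    beta=_parse_float(row[idx["beta"]], "beta"),
                    se=_parse_float(row[idx["se"]], "se"),
                    pval=_parse_float(row[idx["pval"]], "pval"),
                    eaf=eaf,
                    n=int(n_val) if n_val is not None else None,
                    trait_id=trait_id,
                )
            except (ValidationError, IndexError, TypeError) as exc:
                raise RowError(line_no, str(exc)) from exc
            if rec.snp_id in seen:
                raise DuplicateVariantError(
                    f"{path}: duplicate snp_id {rec.snp_id!r} at line {line_no}"
                )
            seen.add(rec.snp_id)
            records.append(rec)
    return records


def _fmt(x: float | int | None) -> str:
    if x is None:
        return "NA"
    if isinstance(x, int):
        return str(x)
    return format(x, ".12g")


def write_sumstats(records: Sequence[VariantAssociation], path: str | Path) -> None:
    """Write records as a TSV in the package dialect.

    Floats are serialized to 12 significant digits, so a read-write cycle is
    the identity on valid records to that precision.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("\t".join(DEFAULT_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.snp_id,
                        rec.effect_allele,
                        rec.other_allele,
                        _fmt(rec.eaf),
                        _fmt(rec.beta),
                        _fmt(rec.se),
                        _fmt(rec.pval),
                        _fmt(rec.n),
                    ]
                )
                + "\n"
            )


def read_proxy_table(path: str | Path) -> list[ProxyRecord]:
    """Read a proxy table: missing_snp, proxy_snp, r2, and four allele columns.

    ``a1_missing``/``a1_proxy`` (and ``a2_*``) give the allele pairing between
    the missing SNP and its proxy.
    """
    path = Path(path)
    out: list[ProxyRecord] = []
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first:
            raise ConfigError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        header = [h.strip() for h in first.rstrip("\n").split(delim)]
        needed = ["missing_snp", "proxy_snp", "r2", "a1_missing", "a1_proxy", "a2_missing", "a2_proxy"]
        for name in needed:
            if name not in header:
                raise ConfigError(f"{path}: required column {name!r} not in header")
        ix = {name: header.index(name) for name in needed}
        for line_no, row in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                out.append(
                    ProxyRecord(
                        missing_snp=row[ix["missing_snp"]].strip(),
                        proxy_snp=row[ix["proxy_snp"]].strip(),
                        r2=float(row[ix["r2"]]),
                        allele_map={
                            row[ix["a1_missing"]].strip(): row[ix["a1_proxy"]].strip(),
                            row[ix["a2_missing"]].strip(): row[ix["a2_proxy"]].strip(),
                        },
                    )
                )
            except (ValidationError, ValueError, IndexError) as exc:
                raise RowError(line_no, str(exc)) from exc
    return out


def read_confounder_table(path: str | Path) -> list[ConfounderHit]:
    """Read a confounder-association table with columns snp, trait, pval."""
    path = Path(path)
    out: list[ConfounderHit] = []
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first:
            raise ConfigError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        header = [h.strip() for h in first.rstrip("\n").split(delim)]
        for name in ("snp", "trait", "pval"):
            if name not in header:
                raise ConfigError(f"{path}: required column {name!r} not in header")
        ix = {name: header.index(name) for name in ("snp", "trait", "pval")}
        for line_no, row in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                out.append(
                    ConfounderHit(
                        snp_id=row[ix["snp"]].strip(),
                        confounder_trait=row[ix["trait"]].strip(),
                        pval=float(row[ix["pval"]]),
                    )
                )
            except (ValidationError, ValueError, IndexError) as exc:
                raise RowError(line_no, str(exc)) from exc
    return out
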