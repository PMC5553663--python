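"""Core domain model: the five named HBB-cluster haplotypes and the
tag-SNP lookup classification of a single phased chromosome.

Each of the five classical sickle-cell haplotype backgrounds (Benin,
Central African Republic, Senegal, Cameroon, Arab-Indian) is defined by
a fixed allele vector over four tag variants spanning the beta-globin
gene cluster (rs3834466, rs28440105, rs10128556, rs968857).  A phased
chromosome is classified by exact lookup of its allele vector in that
table; anything that matches no row is UNKNOWN.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

#: Sentinel for an unobserved allele (site absent from the VCF,
#: half-call, or masked genotype).
MISSING = "."

_ALLELE_RE = re.compile(r"^[ACGT]+$")


class Haplotype(str, enum.Enum):
    """The five named beta-globin cluster haplotypes plus UNKNOWN."""

    BEN = "BEN"  # Benin
    CAR = "CAR"  # Central African Republic (Bantu)
    SEN = "SEN"  # Senegal
    CAM = "CAM"  # Cameroon
    AI = "AI"    # Arab-Indian
    UNKNOWN = "UNKNOWN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The named haplotypes, in canonical precedence order (most common in
#: African-American sickle-cell cohorts first); UNKNOWN always sorts last.
NAMED_HAPLOTYPES: tuple[Haplotype, ...] = (
    Haplotype.BEN,
    Haplotype.CAR,
    Haplotype.SEN,
    Haplotype.CAM,
    Haplotype.AI,
)

PRECEDENCE: dict[Haplotype, int] = {
    h: i for i, h in enumerate((*NAMED_HAPLOTYPES, Haplotype.UNKNOWN))
}


class MatchMode(str, enum.Enum):
    EXACT = "exact"
    PARTIAL = "partial"
    NONE = "none"


class InputError(ValueError):
    """Malformed user input (bad allele vector, bad label, bad config)."""


class TableError(InputError):
    """A haplotype allele table violates its invariants."""


@dataclass(frozen=True)
class SiteDefinition:
    """One tag variant of the classification panel.

    ``alleles`` is ordered; by convention the first allele is used as the
    VCF REF allele when synthetic cohorts are written out.  Membership
    tests treat it as a set.
    """

    rsid: str
    alleles: tuple[str, ...]
    chrom: Optional[str] = None
    pos: Optional[int] = None
    enzyme: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        if not self.rsid:
            raise InputError("site rsid must be non-empty")
        if len(self.alleles) < 2:
            raise InputError(f"site {self.rsid}: needs >=2 alleles")
        for a in self.alleles:
            if not _ALLELE_RE.match(a):
                raise InputError(
                    f"site {self.rsid}: allele {a!r} is not an uppercase "
                    "ACGT string"
                )
        if len(set(self.alleles)) != len(self.alleles):
            raise InputError(f"site {self.rsid}: duplicate alleles")

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset(self.alleles)


@dataclass(frozen=True)
class HaplotypeTable:
    """Haplotype x site allele matrix driving all classification.

    ``rows`` maps each named haplotype to its allele vector, one allele
    per panel site, in site order.  UNKNOWN is never a row.
    """

    sites: tuple[SiteDefinition, ...]
    rows: Mapping[Haplotype, tuple[str, ...]]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def row(self, haplotype: Haplotype) -> tuple[str, ...]:
        return tuple(self.rows[haplotype])

    def haplotypes(self) -> tuple[Haplotype, ...]:
        return tuple(self.rows.keys())


@dataclass(frozen=True)
class ValidationReport:
    errors: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_table(table: HaplotypeTable) -> ValidationReport:
    """Check a haplotype table against its structural invariants.

    Returns a report listing every violation: UNKNOWN used as a row,
    row length != number of sites, alleles outside a site's allele set,
    and duplicate rows (named by the colliding haplotypes).
    """
    errors: list[str] = []
    n = table.n_sites
    for hap, row in table.rows.items():
        if hap is Haplotype.UNKNOWN:
            errors.append("UNKNOWN may not be a table row")
        if len(row) != n:
            errors.append(
                f"row {hap.value}: {len(row)} alleles for {n} sites"
            )
            continue
        for site, allele in zip(table.sites, row):
            if allele not in site.allele_set:
                errors.append(
                    f"row {hap.value}: allele {allele!r} not in "
                    f"{site.rsid} alleles {sorted(site.allele_set)}"
                )
    seen: dict[tuple[str, ...], Haplotype] = {}
    for hap, row in table.rows.items():
        key = tuple(row)
        if key in seen:
            errors.append(
                f"duplicate rows: {seen[key].value} and {hap.value} share "
                f"allele vector {'/'.join(key)}"
            )
        else:
            seen[key] = hap
    return ValidationReport(tuple(errors))


def check_table(table: HaplotypeTable) -> HaplotypeTable:
    """Validate and return the table, raising :class:`TableError` on issues."""
    report = validate_table(table)
    if not report.ok:
        raise TableError("; ".join(report.errors))
    return table


@dataclass(frozen=True)
class HaplotypeCall:
    """Per-chromosome classification outcome."""

    haplotype: Haplotype
    observed_alleles: tuple[str, ...]
    match_mode: MatchMode
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class DiplotypeCall:
    """The two per-chromosome calls plus an order-normalized pair label."""

    call_a: HaplotypeCall
    call_b: HaplotypeCall
    canonical_label: str

    @property
    def haplotype_pair(self) -> tuple[Haplotype, Haplotype]:
        return canonical_pair(self.call_a.haplotype, self.call_b.haplotype)

    def same_diplotype(self, other: "DiplotypeCall") -> bool:
        return self.haplotype_pair == other.haplotype_pair


def canonical_pair(h1: Haplotype, h2: Haplotype) -> tuple[Haplotype, Haplotype]:
    """Order a haplotype pair by the fixed precedence BEN < CAR < SEN <
    CAM < AI < UNKNOWN.  Symmetric and idempotent, so pair labels are
    diffable regardless of chromosome order."""
    return tuple(sorted((h1, h2), key=PRECEDENCE.__getitem__))  # type: ignore[return-value]


def pair_label(h1: Haplotype, h2: Haplotype) -> str:
    a, b = canonical_pair(h1, h2)
    return f"{a.value}/{b.value}"


def classify_chromosome(
    alleles: Sequence[str],
    table: HaplotypeTable,
    *,
    lenient: bool = False,
) -> HaplotypeCall:
    """Classify one phased chromosome by table lookup.

    An exact row match returns that haplotype with ``match_mode=exact``.
    Alleles not in the corresponding site's allele set set the
    ``unrecognized_allele`` flag and force UNKNOWN.  MISSING entries set
    ``missing_site``; under the default strict policy any MISSING entry
    forces UNKNOWN, while ``lenient=True`` salvages the call when the
    observed alleles match exactly one row (``match_mode=partial``).
    """
    observed = tuple(alleles)
    if len(observed) != table.n_sites:
        raise InputError(
            f"expected {table.n_sites} alleles, got {len(observed)}"
        )
    flags: set[str] = set()
    for site, allele in zip(table.sites, observed):
        if allele == MISSING:
            flags.add("missing_site")
        elif allele not in site.allele_set:
            flags.add("unrecognized_allele")

    def unknown() -> HaplotypeCall:
        return HaplotypeCall(
            Haplotype.UNKNOWN, observed, MatchMode.NONE, frozenset(flags)
        )

    if "unrecognized_allele" in flags:
        return unknown()
    if "missing_site" in flags:
        if not lenient:
            return unknown()
        candidates = [
            hap
            for hap, row in table.rows.items()
            if all(o == MISSING or o == r for o, r in zip(observed, row))
        ]
        if len(candidates) == 1:
            return HaplotypeCall(
                candidates[0], observed, MatchMode.PARTIAL, frozenset(flags)
            )
        return unknown()
    for hap, row in table.rows.items():
        if observed == tuple(row):
            return HaplotypeCall(hap, observed, MatchMode.EXACT, frozenset(flags))
    return unknown()


def classify_diplotype(
    alleles_a: Sequence[str],
    alleles_b: Sequence[str],
    table: HaplotypeTable,
    *,
    lenient: bool = False,
) -> DiplotypeCall:
    """Classify both chromosomes of a sample and build the canonical
    pair label (e.g. ``BEN/CAR``)."""
    call_a = classify_chromosome(alleles_a, table, lenient=lenient)
    call_b = classify_chromosome(alleles_b, table, lenient=lenient)
    return DiplotypeCall(
        call_a, call_b, pair_label(call_a.haplotype, call_b.haplotype)
    )


def table_from_rows(
    sites: Iterable[SiteDefinition],
    rows: Mapping[Haplotype, Sequence[str]],
) -> HaplotypeTable:
    """Build and validate a table from site definitions and allele rows."""
    table = HaplotypeTable(
        tuple(sites), {h: tuple(r) for h, r in rows.items()}
    )
    return check_table(table)
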