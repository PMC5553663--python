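"""Model of the legacy RFLP representation of HBB-cluster haplotypes.

Historically, haplotypes were typed by digesting DNA with restriction
endonucleases and recording, per site, whether cleavage occurred (+) or
not (-).  Without family data the assay is unphased: it observes only
how many of a sample's two chromosomes cut at each site (0, 1 or 2),
not which chromosome carries which pattern.  This module builds the
per-haplotype +/- pattern table from an allele table, forward-models an
error-free assay, and enumerates every diplotype consistent with an
observed unphased signature, exposing when the legacy representation is
unique, ambiguous, or atypical (consistent with nothing).
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .haplotype_model import (
    MISSING,
    Haplotype,
    HaplotypeTable,
    InputError,
    canonical_pair,
)

CUT = "+"
UNCUT = "-"


class PatternConfigError(InputError):
    """Allele->cut map does not cover the table's alleles."""


class PatternCollisionWarning(UserWarning):
    """Two haplotypes share the same +/- pattern under the given map."""


@dataclass(frozen=True)
class RFLPPatternTable:
    """Per-haplotype +/- restriction patterns over an ordered site list."""

    sites: tuple[str, ...]
    patterns: Mapping[Haplotype, tuple[str, ...]]

    def __post_init__(self) -> None:
        n = len(self.sites)
        for hap, pat in self.patterns.items():
            if hap is Haplotype.UNKNOWN:
                raise InputError("UNKNOWN has no RFLP pattern")
            if len(pat) != n:
                raise InputError(
                    f"pattern for {hap.value} has {len(pat)} symbols for {n} sites"
                )
            for sym in pat:
                if sym not in (CUT, UNCUT):
                    raise InputError(f"bad pattern symbol {sym!r} (want + or -)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def haplotypes(self) -> tuple[Haplotype, ...]:
        return tuple(self.patterns.keys())


class RFLPStatus(str, enum.Enum):
    UNIQUE = "unique"
    AMBIGUOUS = "ambiguous"
    ATYPICAL = "atypical"


Pair = tuple[Haplotype, Haplotype]


@dataclass(frozen=True)
class RFLPCall:
    """Outcome of unphased enumeration: every haplotype pair consistent
    with the observed cut counts.  ``unique`` iff exactly one pair,
    ``atypical`` iff none."""

    status: RFLPStatus
    consistent_pairs: frozenset[Pair]

    @staticmethod
    def from_pairs(pairs: frozenset[Pair]) -> "RFLPCall":
        if not pairs:
            status = RFLPStatus.ATYPICAL
        elif len(pairs) == 1:
            status = RFLPStatus.UNIQUE
        else:
            status = RFLPStatus.AMBIGUOUS
        return RFLPCall(status, pairs)


def pattern_from_alleles(
    table: HaplotypeTable,
    cut_allele_map: Mapping[str, Mapping[str, str]],
) -> RFLPPatternTable:
    """Derive the +/- pattern table from an allele table.

    ``cut_allele_map`` maps rsid -> allele -> '+'/'-'.  Every allele of
    every site must be covered.  If the map sends both alleles of a site
    to the same symbol the site becomes uninformative; any resulting
    pattern collision between haplotypes is reported as a
    :class:`PatternCollisionWarning` (the table is still returned).
    """
    patterns: dict[Haplotype, tuple[str, ...]] = {}
    for site in table.sites:
        site_map = cut_allele_map.get(site.rsid)
        if site_map is None:
            raise PatternConfigError(f"cut map missing site {site.rsid}")
        for allele in site.allele_set:
            if allele not in site_map:
                raise PatternConfigError(
                    f"cut map for {site.rsid} does not cover allele {allele}"
                )
            if site_map[allele] not in (CUT, UNCUT):
                raise PatternConfigError(
                    f"cut map for {site.rsid}: symbol for {allele} must be + or -"
                )
    for hap, row in table.rows.items():
        patterns[hap] = tuple(
            cut_allele_map[site.rsid][allele]
            for site, allele in zip(table.sites, row)
        )
    ptable = RFLPPatternTable(
        tuple(f"{s.enzyme or s.rsid}" for s in table.sites), patterns
    )
    for (h1, p1), (h2, p2) in itertools.combinations(patterns.items(), 2):
        if p1 == p2:
            warnings.warn(
                f"haplotypes {h1.value} and {h2.value} collide on pattern "
                f"{''.join(p1)} under this cut map",
                PatternCollisionWarning,
                stacklevel=2,
            )
    return ptable


def genotype_signature(
    h1: Haplotype, h2: Haplotype, patterns: RFLPPatternTable
) -> tuple[int, ...]:
    """Error-free forward model of the assay: per-site count of cut
    chromosomes for diplotype (h1, h2).  Symmetric in its arguments."""
    try:
        p1, p2 = patterns.patterns[h1], patterns.patterns[h2]
    except KeyError as exc:
        raise InputError(f"haplotype {exc.args[0]} not in pattern table") from None
    return tuple(int(a == CUT) + int(b == CUT) for a, b in zip(p1, p2))


def enumerate_unphased(
    counts: Sequence[Optional[int]],
    patterns: RFLPPatternTable,
    *,
    allow_atypical: bool = False,
) -> RFLPCall:
    """Enumerate all unordered haplotype pairs consistent with observed
    cut counts (entries in {0,1,2} or None for an untyped site).

    Untyped sites impose no constraint, so masking a site can only
    enlarge the consistent set.  With ``allow_atypical=True`` and no
    fully-known pair consistent, pairs of one known haplotype plus one
    wildcard chromosome (reported as UNKNOWN) are also tried, mirroring
    partial calls like BEN/UNKNOWN.
    """
    counts = tuple(counts)
    if len(counts) != patterns.n_sites:
        raise InputError(
            f"expected {patterns.n_sites} counts, got {len(counts)}"
        )
    for c in counts:
        if c is not None and c not in (0, 1, 2):
            raise InputError(f"cut count must be 0, 1, 2 or None, got {c!r}")
    haps = patterns.haplotypes()
    pairs = set()
    for h1, h2 in itertools.combinations_with_replacement(haps, 2):
        sig = genotype_signature(h1, h2, patterns)
        if all(c is None or c == s for c, s in zip(counts, sig)):
            pairs.add(canonical_pair(h1, h2))
    if not pairs and allow_atypical:
        for h in haps:
            pat = patterns.patterns[h]
            ok = all(
                c is None or 0 <= c - int(p == CUT) <= 1
                for c, p in zip(counts, pat)
            )
            if ok:
                pairs.add(canonical_pair(h, Haplotype.UNKNOWN))
    return RFLPCall.from_pairs(frozenset(pairs))


def enumerate_unphased_alleles(
    site_allele_pairs: Sequence[tuple[str, str]],
    table: HaplotypeTable,
) -> frozenset[Pair]:
    """Enumerate haplotype pairs consistent with unphased allele-level
    genotypes: per site, the unordered pair of observed alleles (either
    may be MISSING, which unconstrains the site).  Used to route
    unphased VCF samples through the same ambiguity logic as RFLP
    counts."""
    if len(site_allele_pairs) != table.n_sites:
        raise InputError(
            f"expected {table.n_sites} allele pairs, got {len(site_allele_pairs)}"
        )
    observed = [
        None if MISSING in (a, b) else tuple(sorted((a, b)))
        for a, b in site_allele_pairs
    ]
    pairs = set()
    for h1, h2 in itertools.combinations_with_replacement(table.haplotypes(), 2):
        r1, r2 = table.rows[h1], table.rows[h2]
        if all(
            obs is None or obs == tuple(sorted((a, b)))
            for obs, a, b in zip(observed, r1, r2)
        ):
            pairs.add(canonical_pair(h1, h2))
    return frozenset(pairs)


PATTERN_HEADER_FIRST = "haplotype"


def write_pattern_table(patterns: RFLPPatternTable, path) -> None:
    from .util import atomic_write_text

    lines = ["\t".join((PATTERN_HEADER_FIRST, *patterns.sites))]
    for hap, pat in patterns.patterns.items():
        lines.append("\t".join((hap.value, *pat)))
    atomic_write_text(path, "\n".join(lines) + "\n")


def load_pattern_table(path) -> RFLPPatternTable:
    """Read a pattern TSV: header = 'haplotype' + site labels, one row
    per haplotype with +/- symbols."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != PATTERN_HEADER_FIRST:
            raise InputError(f"{path}: first column must be '{PATTERN_HEADER_FIRST}'")
        sites = tuple(header[1:])
        patterns: dict[Haplotype, tuple[str, ...]] = {}
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(sites) + 1:
                raise InputError(f"{path}: row {fields[0]!r} has wrong width")
            hap = Haplotype(fields[0])
            if hap in patterns:
                raise InputError(f"{path}: duplicate haplotype {hap.value}")
            patterns[hap] = tuple(fields[1:])
    return RFLPPatternTable(sites, patterns)
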