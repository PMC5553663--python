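"""Extract phased alleles at the panel sites from VCF files and write
classification results.

The upstream pipeline (array genotyping, imputation, statistical
phasing) is out of scope: this module consumes an already-phased VCF 4.x
with ``|``-separated GT fields and rsIDs in the ID column, pulls out the
two per-chromosome allele vectors at the panel sites, and hands them to
the lookup classifier.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pysam
import yaml

from .haplotype_model import (
    MISSING,
    DiplotypeCall,
    Haplotype,
    HaplotypeTable,
    InputError,
    SiteDefinition,
    classify_diplotype,
    pair_label,
)
from .util import atomic_write_text

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class LookupMode(str, enum.Enum):
    BY_RSID = "by_rsid"
    BY_POSITION = "by_position"
    RSID_THEN_POSITION = "rsid_then_position"


class PanelError(InputError):
    """Site panel config violates its schema."""


@dataclass(frozen=True)
class SitePanel:
    """Ordered tag-variant panel plus the VCF lookup policy."""

    sites: tuple[SiteDefinition, ...]
    lookup_mode: LookupMode = LookupMode.BY_RSID

    def __post_init__(self) -> None:
        rsids = [s.rsid for s in self.sites]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise PanelError(f"duplicate rsids in panel: {', '.join(dupes)}")
        if self.lookup_mode in (LookupMode.BY_POSITION, LookupMode.RSID_THEN_POSITION):
            for s in self.sites:
                if s.chrom is None or s.pos is None:
                    raise PanelError(
                        f"lookup_mode={self.lookup_mode.value} requires "
                        f"chrom+pos for every site; {s.rsid} lacks them"
                    )

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.sites)

    def __len__(self) -> int:
        return len(self.sites)


def load_site_panel(path: PathLike) -> SitePanel:
    """Load and validate a YAML site panel.

    Schema: optional ``lookup_mode`` plus ``sites``, a list of mappings
    with ``rsid`` and ordered ``alleles`` (first allele is the REF used
    when synthetic VCFs are written), and optional ``chrom``, ``pos``,
    ``enzyme``, ``region``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "sites" not in raw:
        raise PanelError(f"{path}: panel file must be a mapping with a 'sites' list")
    try:
        mode = LookupMode(raw.get("lookup_mode", "by_rsid"))
    except ValueError as exc:
        raise PanelError(f"{path}: bad lookup_mode: {exc}") from None
    sites = []
    for i, entry in enumerate(raw["sites"]):
        if not isinstance(entry, dict) or "rsid" not in entry or "alleles" not in entry:
            raise PanelError(f"{path}: sites[{i}] needs 'rsid' and 'alleles'")
        sites.append(
            SiteDefinition(
                rsid=str(entry["rsid"]),
                alleles=tuple(str(a).upper() for a in entry["alleles"]),
                chrom=str(entry["chrom"]) if entry.get("chrom") is not None else None,
                pos=int(entry["pos"]) if entry.get("pos") is not None else None,
                enzyme=str(entry.get("enzyme", "")),
                region=str(entry.get("region", "")),
            )
        )
    return SitePanel(tuple(sites), mode)


class SiteStatus(str, enum.Enum):
    FOUND = "found"
    MISSING = "missing"      # site absent from the VCF
    HALF_CALL = "half_call"  # one or both GT fields '.'
    UNPHASED = "unphased"    # heterozygous with '/' separator


@dataclass(frozen=True)
class PhasedSampleGenotype:
    """Per-sample phased allele vectors over the panel sites.

    ``hapA_alleles[i]`` is the allele indexed by the left GT field at
    panel site ``i`` (MISSING when the site is absent or half-called);
    ``phase_ok`` is False when any site carried an unphased heterozygous
    genotype, in which case per-chromosome assignment is meaningless.
    """

    sample_id: str
    hapA_alleles: tuple[str, ...]
    hapB_alleles: tuple[str, ...]
    phase_ok: bool
    site_status: tuple[SiteStatus, ...]


@dataclass(frozen=True)
class ClassificationRecord:
    sample_id: str
    hap1: Haplotype
    hap2: Haplotype
    canonical_label: str
    flags: frozenset[str] = frozenset()


def _find_panel_records(vcf: "pysam.VariantFile", panel: SitePanel):
    """Single streaming pass over the VCF collecting the panel records."""
    by_rsid = {s.rsid: i for i, s in enumerate(panel.sites)}
    by_pos = {
        (s.chrom, s.pos): i
        for s in panel.sites
        if s.chrom is not None and s.pos is not None
        for i in (by_rsid[s.rsid],)
    }
    use_rsid = panel.lookup_mode in (LookupMode.BY_RSID, LookupMode.RSID_THEN_POSITION)
    use_pos = panel.lookup_mode in (LookupMode.BY_POSITION, LookupMode.RSID_THEN_POSITION)
    records: list[Optional[pysam.VariantRecord]] = [None] * len(panel)
    for rec in vcf:
        idx = None
        if use_rsid and rec.id in by_rsid:
            idx = by_rsid[rec.id]
        elif use_pos and (rec.chrom, rec.pos) in by_pos:
            idx = by_pos[(rec.chrom, rec.pos)]
        if idx is None:
            continue
        if records[idx] is not None:
            raise InputError(
                f"site {panel.sites[idx].rsid} found twice in VCF "
                f"(ambiguous record at {rec.chrom}:{rec.pos})"
            )
        records[idx] = rec
    return records


def extract_phased_alleles(
    vcf_path: PathLike, panel: SitePanel
) -> list[PhasedSampleGenotype]:
    """Read the panel sites from a phased VCF.

    For each sample, haplotype A takes the allele indexed by the left GT
    field and haplotype B the right.  Sites absent from the VCF yield
    MISSING; half-calls are MISSING at that site; an unphased ('/')
    heterozygous genotype marks the whole sample ``phase_ok=False``
    (unphased homozygous genotypes are accepted — phase is immaterial
    there).  Raises on an unreadable VCF or a panel site matched by two
    records.
    """
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read VCF {vcf_path}: {exc}") from exc
    with vcf:
        samples = list(vcf.header.samples)
        records = _find_panel_records(vcf, panel)
        missing = [panel.sites[i].rsid for i, r in enumerate(records) if r is None]
        if missing:
            log.warning(
                "panel sites absent from %s: %s", vcf_path, ", ".join(missing)
            )
        out: list[PhasedSampleGenotype] = []
        for sample in samples:
            hap_a: list[str] = []
            hap_b: list[str] = []
            status: list[SiteStatus] = []
            phase_ok = True
            for rec in records:
                if rec is None:
                    hap_a.append(MISSING)
                    hap_b.append(MISSING)
                    status.append(SiteStatus.MISSING)
                    continue
                call = rec.samples[sample]
                gt = call.get("GT") or ()
                alleles_here = (rec.ref, *(rec.alts or ()))
                if len(gt) != 2 or gt[0] is None or gt[1] is None:
                    hap_a.append(MISSING)
                    hap_b.append(MISSING)
                    status.append(SiteStatus.HALF_CALL)
                    continue
                a = str(alleles_here[gt[0]]).upper()
                b = str(alleles_here[gt[1]]).upper()
                if not call.phased and a != b:
                    phase_ok = False
                    status.append(SiteStatus.UNPHASED)
                else:
                    status.append(SiteStatus.FOUND)
                hap_a.append(a)
                hap_b.append(b)
            out.append(
                PhasedSampleGenotype(
                    sample, tuple(hap_a), tuple(hap_b), phase_ok, tuple(status)
                )
            )
    return out


def classify_vcf(
    vcf_path: PathLike,
    panel: SitePanel,
    table: HaplotypeTable,
    *,
    lenient: bool = False,
    unphased: str = "skip",
) -> list[ClassificationRecord]:
    """Classify every sample of a phased VCF into a diplotype.

    Samples with an unphased heterozygous site are, by default, excluded
    with a warning (``unphased='skip'``); ``unphased='enumerate'``
    instead routes them through the unphased-genotype enumerator, which
    reports the diplotype only when the unordered allele counts are
    consistent with a single haplotype pair.  Output order follows VCF
    sample order.
    """
    if unphased not in ("skip", "enumerate"):
        raise InputError(f"unphased policy must be 'skip' or 'enumerate', got {unphased!r}")
    genotypes = extract_phased_alleles(vcf_path, panel)
    records: list[ClassificationRecord] = []
    for geno in genotypes:
        if not geno.phase_ok:
            if unphased == "skip":
                log.warning(
                    "sample %s has unphased heterozygous genotypes; skipped",
                    geno.sample_id,
                )
                continue
            records.append(_enumerate_unphased_sample(geno, table))
            continue
        call = classify_diplotype(
            geno.hapA_alleles, geno.hapB_alleles, table, lenient=lenient
        )
        flags = frozenset(call.call_a.flags | call.call_b.flags)
        h1, h2 = call.haplotype_pair
        records.append(
            ClassificationRecord(geno.sample_id, h1, h2, call.canonical_label, flags)
        )
    return records


def _enumerate_unphased_sample(
    geno: PhasedSampleGenotype, table: HaplotypeTable
) -> ClassificationRecord:
    # Local import: rflp_model depends on haplotype_model only, but this
    # keeps vcf_io importable without the enumeration machinery.
    from .rflp_model import enumerate_unphased_alleles

    call = enumerate_unphased_alleles(
        tuple(zip(geno.hapA_alleles, geno.hapB_alleles)), table
    )
    if len(call) == 1:
        h1, h2 = next(iter(call))
        return ClassificationRecord(
            geno.sample_id, h1, h2, pair_label(h1, h2),
            frozenset({"unphased_enumerated"}),
        )
    flag = "unphased_ambiguous" if call else "unphased_atypical"
    return ClassificationRecord(
        geno.sample_id,
        Haplotype.UNKNOWN,
        Haplotype.UNKNOWN,
        "UNKNOWN/UNKNOWN",
        frozenset({"unphased_enumerated", flag}),
    )


CLASSIFICATION_HEADER = ("sample_id", "hap1", "hap2", "diplotype", "flags")


def write_classification(
    records: Sequence[ClassificationRecord], path: PathLike
) -> None:
    """Write classification records as a TSV (one row per sample; flags
    semicolon-joined, sorted).  Round-trips through
    :func:`read_classification`."""
    lines = ["\t".join(CLASSIFICATION_HEADER)]
    for r in records:
        lines.append(
            "\t".join(
                (
                    r.sample_id,
                    r.hap1.value,
                    r.hap2.value,
                    r.canonical_label,
                    ";".join(sorted(r.flags)),
                )
            )
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_classification(path: PathLike) -> list[ClassificationRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CLASSIFICATION_HEADER:
            raise InputError(f"{path}: unexpected header {header}")
        for line in fh:
            sample_id, h1, h2, label, flags = line.rstrip("\n").split("\t")
            records.append(
                ClassificationRecord(
                    sample_id,
                    Haplotype(h1),
                    Haplotype(h2),
                    label,
                    frozenset(f for f in flags.split(";") if f),
                )
            )
    return records
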