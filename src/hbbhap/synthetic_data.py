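"""Seeded generator of haplotype-structured cohorts.

Forward model of the study design every other module consumes: each
sample carries a true diplotype (drawn from explicit diplotype
frequencies, or by random mating from haplotype frequencies), two phased
allele vectors from the haplotype table, an HbF phenotype drawn from a
per-diplotype Normal truncated below at 0, and — via
:func:`simulate_rflp_assay` — an error-prone unphased RFLP readout where
each chromosome's +/- state flips independently per site.  Everything is
bit-for-bit reproducible from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import yaml
from scipy import stats

from .haplotype_model import (
    MISSING,
    Haplotype,
    HaplotypeTable,
    InputError,
    pair_label,
)
from .rflp_model import CUT, RFLPPatternTable, genotype_signature
from .util import PathLike, atomic_write_text
from .vcf_io import SitePanel

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class CohortConfig:
    """Simulation parameters for one synthetic cohort.

    Exactly one of ``diplotype_freqs`` (explicit class probabilities) or
    ``haplotype_freqs`` with ``random_mating=True`` (Hardy-Weinberg
    pairing) must be given.  ``hbf_params`` maps diplotype label ->
    (mean %, sd %); a ``"default"`` entry is the fallback for classes
    without their own estimate.  ``rflp_flip_eps`` is the per-site,
    per-chromosome probability that the assay reports the wrong +/-
    state; ``genotype_missing_rate`` is the per-sample, per-site
    probability of a ``./.`` genotype in the emitted VCF.
    """

    n: int
    diplotype_freqs: Optional[Mapping[str, float]] = None
    haplotype_freqs: Optional[Mapping[str, float]] = None
    random_mating: bool = False
    hbf_params: Optional[Mapping[str, tuple[float, float]]] = None
    rflp_flip_eps: Union[float, Sequence[float]] = 0.0
    genotype_missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 0:
            raise InputError("cohort size n must be >= 0")
        has_dip = self.diplotype_freqs is not None
        has_hap = self.haplotype_freqs is not None and self.random_mating
        if has_dip == has_hap:
            raise InputError(
                "give either diplotype_freqs or haplotype_freqs with "
                "random_mating=True (exactly one)"
            )
        freqs = self.diplotype_freqs if has_dip else self.haplotype_freqs
        assert freqs is not None
        if any(p < 0 for p in freqs.values()):
            raise InputError("frequencies must be non-negative")
        total = float(sum(freqs.values()))
        if not math.isclose(total, 1.0, abs_tol=_FREQ_TOL):
            raise InputError(f"frequencies must sum to 1 (got {total!r})")
        if self.hbf_params is not None:
            for label, (mu, sd) in self.hbf_params.items():
                if sd < 0:
                    raise InputError(f"hbf_params[{label}]: sd must be >= 0")
        eps = self.rflp_flip_eps
        eps_values = [eps] if isinstance(eps, (int, float)) else list(eps)
        if any(not 0.0 <= e <= 1.0 for e in eps_values):
            raise InputError("rflp_flip_eps must lie in [0, 1]")
        if not 0.0 <= self.genotype_missing_rate <= 1.0:
            raise InputError("genotype_missing_rate must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticSample:
    sample_id: str
    hap_a: Haplotype
    hap_b: Haplotype
    alleles_a: tuple[str, ...]
    alleles_b: tuple[str, ...]
    hbf: float
    missing_mask: tuple[bool, ...]  # per panel site, applied at VCF emission

    @property
    def true_label(self) -> str:
        return pair_label(self.hap_a, self.hap_b)


@dataclass(frozen=True)
class SyntheticCohort:
    samples: tuple[SyntheticSample, ...]
    config: CohortConfig
    table: HaplotypeTable

    def __len__(self) -> int:
        return len(self.samples)

    def true_labels(self) -> dict[str, str]:
        return {s.sample_id: s.true_label for s in self.samples}


def _parse_pair(label: str) -> tuple[Haplotype, Haplotype]:
    a, b = label.split("/")
    return Haplotype(a), Haplotype(b)


def _hbf_lookup(
    params: Mapping[str, tuple[float, float]], label: str
) -> tuple[float, float]:
    if label in params:
        return params[label]
    if "default" in params:
        return params["default"]
    raise InputError(f"no HbF parameters for diplotype {label} and no default")


def _draw_truncated_normal(
    rng: np.random.Generator, mu: float, sd: float, size: int
) -> np.ndarray:
    """Normal(mu, sd) truncated below at 0 (HbF is a percentage)."""
    if sd == 0.0:
        return np.full(size, max(mu, 0.0))
    a = (0.0 - mu) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=size, random_state=rng)


def simulate_cohort(
    config: CohortConfig, table: Optional[HaplotypeTable] = None
) -> SyntheticCohort:
    """Draw a cohort from the configured generative model.

    A single RNG stream seeded from ``config.seed`` is consumed in a
    fixed, documented order — (1) diplotypes for all samples, (2) HbF
    per class in sorted class order, (3) the genotype missing mask — so
    cohorts are stable across runs and releases.
    """
    config.validate()
    if table is None:
        from .defaults import default_table

        table = default_table()
    rng = np.random.default_rng(config.seed)
    n = config.n

    # (1) true diplotypes
    if config.diplotype_freqs is not None:
        labels_sorted = sorted(config.diplotype_freqs)
        probs = np.array([config.diplotype_freqs[l] for l in labels_sorted])
        idx = rng.choice(len(labels_sorted), size=n, p=probs / probs.sum())
        pairs = [_parse_pair(labels_sorted[i]) for i in idx]
    else:
        haps_sorted = sorted(config.haplotype_freqs)  # type: ignore[arg-type]
        probs = np.array([config.haplotype_freqs[h] for h in haps_sorted])  # type: ignore[index]
        idx = rng.choice(len(haps_sorted), size=(n, 2), p=probs / probs.sum())
        pairs = [
            (Haplotype(haps_sorted[i]), Haplotype(haps_sorted[j])) for i, j in idx
        ]
    for a, b in pairs:
        if a not in table.rows or b not in table.rows:
            raise InputError(f"haplotype {a.value}/{b.value} not in allele table")

    # (2) HbF, drawn per class (sorted order) and scattered back
    hbf_params = config.hbf_params
    if hbf_params is None:
        from .defaults import default_hbf_params

        hbf_params = default_hbf_params()
    labels = [pair_label(a, b) for a, b in pairs]
    hbf = np.zeros(n)
    for label in sorted(set(labels)):
        sel = np.flatnonzero(np.array(labels, dtype=object) == label)
        mu, sd = _hbf_lookup(hbf_params, label)
        hbf[sel] = _draw_truncated_normal(rng, mu, sd, sel.size)

    # (3) missing-genotype mask
    n_sites = table.n_sites
    if config.genotype_missing_rate > 0:
        mask = rng.random((n, n_sites)) < config.genotype_missing_rate
    else:
        mask = np.zeros((n, n_sites), dtype=bool)

    width = max(4, len(str(max(n, 1))))
    samples = tuple(
        SyntheticSample(
            sample_id=f"S{i + 1:0{width}d}",
            hap_a=a,
            hap_b=b,
            alleles_a=table.row(a),
            alleles_b=table.row(b),
            hbf=float(hbf[i]),
            missing_mask=tuple(bool(x) for x in mask[i]),
        )
        for i, (a, b) in enumerate(pairs)
    )
    return SyntheticCohort(samples, config, table)


# ---------------------------------------------------------------------------
# emission

_SYNTH_CHROM = "11"
_SYNTH_POS0 = 5_200_000
_SYNTH_STEP = 10_000


def _site_coordinates(panel: SitePanel) -> list[tuple[str, int]]:
    """Panel coordinates, or deterministic placeholder positions on
    chr11 when the panel carries none (synthetic output only)."""
    if all(s.chrom is not None and s.pos is not None for s in panel.sites):
        return [(s.chrom, s.pos) for s in panel.sites]  # type: ignore[misc]
    return [
        (_SYNTH_CHROM, _SYNTH_POS0 + i * _SYNTH_STEP)
        for i in range(len(panel.sites))
    ]


def emit_phased_vcf(
    cohort: SyntheticCohort, panel: SitePanel, path: PathLike
) -> None:
    """Write the cohort as a phased VCF 4.2 (plain text).

    One record per panel site; REF is the first configured allele and
    ALTs the rest; GT fields are '|'-phased with haplotype A on the
    left.  Sites masked by the cohort's missing mask are emitted as
    ``.|.``.
    """
    coords = _site_coordinates(panel)
    allele_index = [
        {a: i for i, a in enumerate(site.alleles)} for site in panel.sites
    ]
    columns = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if cohort.samples:
        columns += "\tFORMAT\t" + "\t".join(s.sample_id for s in cohort.samples)
    header = [
        "##fileformat=VCFv4.2",
        "##source=hbbhap-synthetic",
        f"##contig=<ID={coords[0][0]}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        columns,
    ]
    body = []
    for j, site in enumerate(panel.sites):
        chrom, pos = coords[j]
        ref = site.alleles[0]
        alts = ",".join(site.alleles[1:])
        gts = []
        for s in cohort.samples:
            if s.missing_mask[j]:
                gts.append(".|.")
            else:
                gts.append(
                    f"{allele_index[j][s.alleles_a[j]]}|{allele_index[j][s.alleles_b[j]]}"
                )
        row = f"{chrom}\t{pos}\t{site.rsid}\t{ref}\t{alts}\t.\tPASS\t."
        if gts:
            row += "\tGT\t" + "\t".join(gts)
        body.append(row)
    atomic_write_text(path, "\n".join(header + body) + "\n")


def write_truth(cohort: SyntheticCohort, path: PathLike) -> None:
    lines = ["sample_id\tdiplotype"]
    lines += [f"{s.sample_id}\t{s.true_label}" for s in cohort.samples]
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_phenotypes(cohort: SyntheticCohort, path: PathLike) -> None:
    lines = ["sample_id\tdiplotype\thbf"]
    lines += [
        f"{s.sample_id}\t{s.true_label}\t{s.hbf:.4f}" for s in cohort.samples
    ]
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# RFLP assay

def simulate_rflp_assay(
    cohort: SyntheticCohort,
    patterns: RFLPPatternTable,
    eps: Union[float, Sequence[float]],
    seed: int,
) -> list[tuple[int, ...]]:
    """Simulate an unphased RFLP assay with per-site flip error.

    Per chromosome and site, the true +/- state is read wrongly with
    probability ``eps`` (scalar or per-site); the observed value is the
    per-site count of chromosomes read as cut.  ``eps=0`` reproduces
    :func:`genotype_signature` exactly.
    """
    n_sites = patterns.n_sites
    eps_arr = np.broadcast_to(np.asarray(eps, dtype=float), (n_sites,))
    if np.any((eps_arr < 0) | (eps_arr > 1)):
        raise InputError("flip probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for s in cohort.samples:
        counts = []
        pa = patterns.patterns[s.hap_a]
        pb = patterns.patterns[s.hap_b]
        flips = rng.random((2, n_sites)) < eps_arr
        for j in range(n_sites):
            a = (pa[j] == CUT) ^ flips[0, j]
            b = (pb[j] == CUT) ^ flips[1, j]
            counts.append(int(a) + int(b))
        out.append(tuple(counts))
    return out


def write_rflp_counts(
    cohort: SyntheticCohort,
    counts: Sequence[tuple[int, ...]],
    patterns: RFLPPatternTable,
    path: PathLike,
) -> None:
    lines = ["\t".join(("sample_id", *patterns.sites))]
    for s, c in zip(cohort.samples, counts):
        lines.append("\t".join((s.sample_id, *(str(x) for x in c))))
    atomic_write_text(path, "\n".join(lines) + "\n")


def load_cohort_config(path: PathLike) -> CohortConfig:
    """Load a cohort config YAML; omitted fields take the packaged
    defaults (class frequencies and HbF parameters)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict) or "n" not in raw:
        raise InputError(f"{path}: cohort config must be a mapping with 'n'")
    hbf = raw.get("hbf_params")
    if hbf is not None:
        hbf = {
            label: (float(v["mean"]), float(v["sd"])) for label, v in hbf.items()
        }
    cfg = CohortConfig(
        n=int(raw["n"]),
        diplotype_freqs=raw.get("diplotype_freqs"),
        haplotype_freqs=raw.get("haplotype_freqs"),
        random_mating=bool(raw.get("random_mating", False)),
        hbf_params=hbf,
        rflp_flip_eps=raw.get("rflp_flip_eps", 0.0),
        genotype_missing_rate=float(raw.get("genotype_missing_rate", 0.0)),
        seed=int(raw.get("seed", 0)),
    )
    if cfg.diplotype_freqs is None and cfg.haplotype_freqs is None:
        from .defaults import default_diplotype_freqs

        cfg = replace(cfg, diplotype_freqs=default_diplotype_freqs())
    cfg.validate()
    return cfg
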