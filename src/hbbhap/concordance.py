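"""Concordance between two diplotype labelings of the same samples.

Produces a per-class agreement table (grouped by the reference labeling,
typically the legacy RFLP assignment) with an overall summary, plus the
"rescue rate": among samples the reference method left partially or
wholly unclassified, the fraction the test method fully resolves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .haplotype_model import PRECEDENCE, Haplotype, InputError
from .util import PathLike, atomic_write_text

#: Reports normalize the unknown token to the short form.
UNK = "UNK"

_TOKEN_ALIASES = {"UNK": UNK, "UNKNOWN": UNK}


def _normalize_token(token: str) -> str:
    t = token.strip().upper()
    t = _TOKEN_ALIASES.get(t, t)
    if t != UNK and t not in Haplotype.__members__:
        raise InputError(f"unrecognized haplotype token {token!r}")
    return t


def parse_label(label: str) -> tuple[str, str]:
    """Parse 'H1/H2' into two normalized tokens (UNK and UNKNOWN are
    synonyms)."""
    parts = label.split("/")
    if len(parts) != 2:
        raise InputError(f"diplotype label {label!r} must have two '/'-separated tokens")
    return _normalize_token(parts[0]), _normalize_token(parts[1])


def _token_rank(token: str) -> int:
    if token == UNK:
        return PRECEDENCE[Haplotype.UNKNOWN]
    return PRECEDENCE[Haplotype[token]]


def canonical_label(label: str) -> str:
    """Order-normalize a label: BEN < CAR < SEN < CAM < AI < UNK."""
    a, b = sorted(parse_label(label), key=_token_rank)
    return f"{a}/{b}"


def compare_pair(label1: str, label2: str) -> bool:
    """Order-insensitive diplotype equality: true iff the unordered
    multisets of haplotype tokens agree."""
    return sorted(parse_label(label1)) == sorted(parse_label(label2))


@dataclass(frozen=True)
class PairedLabels:
    sample_id: str
    ref_label: str
    test_label: str


@dataclass(frozen=True)
class ClassRow:
    ref_class: str
    n: int
    n_agree: int

    @property
    def concordance(self) -> float:
        return self.n_agree / self.n


@dataclass(frozen=True)
class ConcordanceReport:
    per_class: tuple[ClassRow, ...]
    overall_n: int
    overall_agree: int
    discordant: tuple[PairedLabels, ...]

    @property
    def overall_concordance(self) -> float:
        return self.overall_agree / self.overall_n

    def class_row(self, label: str) -> ClassRow:
        key = canonical_label(label)
        for row in self.per_class:
            if row.ref_class == key:
                return row
        raise KeyError(key)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.ref_class, r.n, r.n_agree, r.concordance)
                for r in self.per_class
            ],
            columns=["ref_class", "n", "n_agree", "concordance"],
        )

    def summary_line(self) -> str:
        return (
            f"overall concordance {self.overall_agree}/{self.overall_n} "
            f"= {100.0 * self.overall_concordance:.1f}% "
            f"({len(self.discordant)} discordant)"
        )


def concordance_table(pairs: Sequence[PairedLabels]) -> ConcordanceReport:
    """Group samples by canonicalized reference label and count
    order-insensitive agreements; concordances are kept at full float
    precision.  Invariant to sample order and within-pair token order."""
    if not pairs:
        raise InputError("concordance_table requires at least one sample")
    by_class: dict[str, list[PairedLabels]] = {}
    for p in pairs:
        by_class.setdefault(canonical_label(p.ref_label), []).append(p)
    rows = []
    discordant: list[PairedLabels] = []
    for ref_class in sorted(by_class, key=lambda c: tuple(map(_token_rank, c.split("/")))):
        members = by_class[ref_class]
        agree = 0
        for p in members:
            if compare_pair(p.ref_label, p.test_label):
                agree += 1
            else:
                discordant.append(p)
        rows.append(ClassRow(ref_class, len(members), agree))
    discordant.sort(key=lambda p: p.sample_id)
    return ConcordanceReport(
        tuple(rows),
        overall_n=len(pairs),
        overall_agree=sum(r.n_agree for r in rows),
        discordant=tuple(discordant),
    )


@dataclass(frozen=True)
class RescueResult:
    """Rescue of reference-unclassified samples by the test method.

    ``defined`` is False when no reference label contains an UNK token
    (denominator zero); ``rate`` is then None rather than an error."""

    rescued: int
    unclassified: int

    @property
    def defined(self) -> bool:
        return self.unclassified > 0

    @property
    def rate(self) -> Optional[float]:
        return self.rescued / self.unclassified if self.defined else None


def rescue_rate(pairs: Iterable[PairedLabels]) -> RescueResult:
    """Among samples whose reference label carries >=1 UNK token, count
    those whose test label carries none."""
    unclassified = 0
    rescued = 0
    for p in pairs:
        if UNK in parse_label(p.ref_label):
            unclassified += 1
            if UNK not in parse_label(p.test_label):
                rescued += 1
    return RescueResult(rescued, unclassified)


PAIRS_HEADER = ("sample_id", "ref_label", "test_label")


def read_pairs(path: PathLike) -> list[PairedLabels]:
    """Read a paired-label TSV with columns sample_id, ref_label,
    test_label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PAIRS_HEADER) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return [
        PairedLabels(r.sample_id, r.ref_label, r.test_label)
        for r in df.itertuples(index=False)
    ]


def write_report(report: ConcordanceReport, path: PathLike) -> None:
    """Write the per-class table plus a one-line overall summary."""
    lines = ["\t".join(("ref_class", "n", "n_agree", "concordance"))]
    for r in report.per_class:
        lines.append(f"{r.ref_class}\t{r.n}\t{r.n_agree}\t{r.concordance!r}")
    lines.append(f"# {report.summary_line()}")
    atomic_write_text(path, "\n".join(lines) + "\n")
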