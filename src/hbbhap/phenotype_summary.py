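"""Per-diplotype summaries of fetal hemoglobin (HbF) levels.

HbF, expressed as percent of total hemoglobin, is the main modulator of
sickle cell disease severity and runs at characteristic levels per
haplotype background (BEN/CAR/CAM homozygotes around 5-7%, SEN around
10%, AI around 20%).  This module groups samples by canonical diplotype
label and reports n, mean and sample standard deviation, plus an
optional quartile table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .concordance import canonical_label
from .haplotype_model import InputError
from .util import PathLike, atomic_write_text


@dataclass(frozen=True)
class PhenotypeRecord:
    sample_id: str
    diplotype_label: str
    hbf: float  # percent of total hemoglobin


@dataclass(frozen=True)
class SummaryRow:
    diplotype_label: str
    n: int
    mean: float
    sd: Optional[float]  # absent (None) when n == 1


def summarize_hbf(records: Sequence[PhenotypeRecord]) -> list[SummaryRow]:
    """Group by canonical diplotype and summarize HbF.

    Mean is arithmetic; sd uses the sample (n-1) convention and is
    absent for singleton classes.  Rows are sorted by n descending, then
    label.  UNK-containing labels form their own classes.  Negative HbF
    raises, naming the offending sample.
    """
    if not records:
        raise InputError("summarize_hbf requires at least one record")
    for r in records:
        if r.hbf < 0 or math.isnan(r.hbf):
            raise InputError(
                f"sample {r.sample_id}: HbF must be a non-negative percent, got {r.hbf}"
            )
    df = pd.DataFrame(
        {
            "label": [canonical_label(r.diplotype_label) for r in records],
            "hbf": [r.hbf for r in records],
        }
    )
    # sort within class so float reductions are input-order independent
    df = df.sort_values(["label", "hbf"], kind="mergesort")
    grouped = df.groupby("label")["hbf"].agg(["count", "mean", "std"])
    rows = [
        SummaryRow(
            label,
            int(g["count"]),
            float(g["mean"]),
            None if g["count"] == 1 else float(g["std"]),
        )
        for label, g in grouped.iterrows()
    ]
    rows.sort(key=lambda r: (-r.n, r.diplotype_label))
    return rows


def quartile_table(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    """Distribution summary per class (min, Q1, median, mean, Q3, max) —
    the tabular stand-in for a boxplot."""
    df = pd.DataFrame(
        {
            "label": [canonical_label(r.diplotype_label) for r in records],
            "hbf": [r.hbf for r in records],
        }
    )
    out = df.groupby("label")["hbf"].agg(
        n="count",
        min="min",
        q1=lambda s: s.quantile(0.25),
        median="median",
        mean="mean",
        q3=lambda s: s.quantile(0.75),
        max="max",
    )
    return out.reset_index()


PHENO_HEADER = ("sample_id", "diplotype", "hbf")


def read_phenotypes(path: PathLike) -> list[PhenotypeRecord]:
    """Read a phenotype TSV with columns sample_id, diplotype, hbf."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "diplotype": str})
    missing = set(PHENO_HEADER) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return [
        PhenotypeRecord(r.sample_id, r.diplotype, float(r.hbf))
        for r in df.itertuples(index=False)
    ]


def write_summary(rows: Sequence[SummaryRow], path: PathLike) -> None:
    lines = ["\t".join(("diplotype", "n", "mean", "sd"))]
    for r in rows:
        sd = "" if r.sd is None else f"{r.sd:.6g}"
        lines.append(f"{r.diplotype_label}\t{r.n}\t{r.mean:.6g}\t{sd}")
    atomic_write_text(path, "\n".join(lines) + "\n")
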