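"""Packaged default configurations.

The default panel, allele table, RFLP cut map and HbF distribution
parameters ship as plain data files so users can override any of them by
path (e.g. to append the XmnI site rs7482144) without code changes.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .haplotype_model import Haplotype, HaplotypeTable, table_from_rows
from .rflp_model import RFLPPatternTable, pattern_from_alleles
from .vcf_io import SitePanel, load_site_panel


def _data_path(name: str):
    return resources.files("hbbhap.data").joinpath(name)


@lru_cache(maxsize=None)
def default_panel() -> SitePanel:
    """The four-variant tag panel in 5'->3' gene-cluster order."""
    with resources.as_file(_data_path("site_panel.yaml")) as p:
        return load_site_panel(p)


@lru_cache(maxsize=None)
def default_table() -> HaplotypeTable:
    """The five-haplotype allele matrix over the default panel."""
    panel = default_panel()
    text = _data_path("haplotype_table.tsv").read_text()
    return load_haplotype_table_text(text, panel)


def load_haplotype_table_text(text: str, panel: SitePanel) -> HaplotypeTable:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if tuple(header[1:]) != panel.rsids:
        raise ValueError(
            f"table columns {header[1:]} do not match panel {list(panel.rsids)}"
        )
    rows: dict[Haplotype, tuple[str, ...]] = {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        rows[Haplotype(fields[0])] = tuple(fields[1:])
    return table_from_rows(panel.sites, rows)


def load_haplotype_table(path, panel: SitePanel | None = None) -> HaplotypeTable:
    """Load an allele table TSV (header: haplotype + rsids) against a
    panel (default panel if omitted)."""
    with open(path) as fh:
        return load_haplotype_table_text(fh.read(), panel or default_panel())


@lru_cache(maxsize=None)
def default_cut_map() -> dict:
    with _data_path("rflp_cut_map.yaml").open() as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def default_patterns() -> RFLPPatternTable:
    """The +/- pattern table derived from the default allele table under
    the shipped cut map."""
    return pattern_from_alleles(default_table(), default_cut_map())


@lru_cache(maxsize=None)
def default_hbf_params() -> dict[str, tuple[float, float]]:
    """Per-diplotype (mean, sd) of HbF in percent, plus a 'default'
    fallback entry."""
    with _data_path("hbf_params.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    params = {
        label: (float(v["mean"]), float(v["sd"]))
        for label, v in raw["classes"].items()
    }
    params["default"] = (
        float(raw["default"]["mean"]),
        float(raw["default"]["sd"]),
    )
    return params


@lru_cache(maxsize=None)
def default_diplotype_freqs() -> dict[str, float]:
    """Diplotype frequencies proportional to the default cohort class
    sizes (the n column of the shipped HbF parameter file)."""
    with _data_path("hbf_params.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    counts = {label: float(v["n"]) for label, v in raw["classes"].items()}
    total = sum(counts.values())
    return {label: c / total for label, c in counts.items()}
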