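import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hbbhap import defaults


@pytest.fixture(scope="session")
def panel():
    return defaults.default_panel()


@pytest.fixture(scope="session")
def table():
    return defaults.default_table()


@pytest.fixture(scope="session")
def patterns():
    return defaults.default_patterns()


@pytest.fixture()
def write_vcf(tmp_path):
    """Write a minimal phased VCF over the default panel sites.

    ``genotypes`` maps rsid -> list of GT strings (one per sample); sites
    omitted from the mapping are left out of the file entirely.
    """

    def _write(samples, genotypes, name="test.vcf"):
        site_meta = {
            "rs3834466": ("11", 5200000, "G", "GT"),
            "rs28440105": ("11", 5210000, "C", "A"),
            "rs10128556": ("11", 5220000, "C", "T"),
            "rs968857": ("11", 5230000, "T", "C"),
        }
        columns = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if samples:
            columns += "\tFORMAT\t" + "\t".join(samples)
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=11>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            columns,
        ]
        for rsid, gts in genotypes.items():
            chrom, pos, ref, alt = site_meta[rsid]
            row = f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t."
            if samples:
                row += "\tGT\t" + "\t".join(gts)
            lines.append(row)
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
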