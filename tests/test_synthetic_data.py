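"""Synthetic cohort generator: determinism, distributions, round trips."""

import math

import numpy as np
import pytest

from hbbhap.defaults import default_panel, default_patterns, default_table
from hbbhap.haplotype_model import Haplotype, InputError
from hbbhap.rflp_model import enumerate_unphased, genotype_signature
from hbbhap.synthetic_data import (
    CohortConfig,
    emit_phased_vcf,
    load_cohort_config,
    simulate_cohort,
    simulate_rflp_assay,
)
from hbbhap.vcf_io import classify_vcf


class TestConfigValidation:
    def test_needs_exactly_one_frequency_source(self):
        with pytest.raises(InputError, match="exactly one"):
            CohortConfig(n=10).validate()
        with pytest.raises(InputError, match="exactly one"):
            CohortConfig(
                n=10,
                diplotype_freqs={"BEN/BEN": 1.0},
                haplotype_freqs={"BEN": 1.0},
                random_mating=True,
            ).validate()

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(InputError, match="sum to 1"):
            CohortConfig(n=5, diplotype_freqs={"BEN/BEN": 0.7}).validate()

    def test_rates_bounded(self):
        ok = {"BEN/BEN": 1.0}
        with pytest.raises(InputError):
            CohortConfig(n=5, diplotype_freqs=ok, rflp_flip_eps=1.5).validate()
        with pytest.raises(InputError):
            CohortConfig(n=5, diplotype_freqs=ok, genotype_missing_rate=-0.1).validate()


class TestSimulateCohort:
    def test_single_class_cohort(self):
        cfg = CohortConfig(n=30, diplotype_freqs={"AI/AI": 1.0}, seed=5)
        cohort = simulate_cohort(cfg)
        assert len(cohort) == 30
        assert {s.true_label for s in cohort.samples} == {"AI/AI"}

    def test_determinism_and_seed_sensitivity(self):
        cfg = CohortConfig(
            n=100, diplotype_freqs={"BEN/BEN": 0.5, "BEN/CAR": 0.5}, seed=9
        )
        c1, c2 = simulate_cohort(cfg), simulate_cohort(cfg)
        assert c1.samples == c2.samples
        c3 = simulate_cohort(CohortConfig(**{**cfg.__dict__, "seed": 10}))
        assert c1.samples != c3.samples

    def test_class_counts_within_binomial_bound(self):
        n, p = 10_000, 0.5
        cfg = CohortConfig(
            n=n, diplotype_freqs={"BEN/BEN": p, "BEN/CAR": 1 - p}, seed=3
        )
        cohort = simulate_cohort(cfg)
        k = sum(s.true_label == "BEN/BEN" for s in cohort.samples)
        assert abs(k - n * p) <= 4 * math.sqrt(n * p * (1 - p))

    def test_random_mating_pairs_haplotypes(self):
        cfg = CohortConfig(
            n=500,
            haplotype_freqs={"BEN": 0.8, "CAR": 0.2},
            random_mating=True,
            seed=2,
        )
        cohort = simulate_cohort(cfg)
        labels = {s.true_label for s in cohort.samples}
        assert labels <= {"BEN/BEN", "BEN/CAR", "CAR/CAR"}
        # heterozygote frequency near 2pq = 0.32
        het = sum(s.true_label == "BEN/CAR" for s in cohort.samples) / 500
        assert abs(het - 0.32) < 4 * math.sqrt(0.32 * 0.68 / 500)

    def test_hbf_nonnegative_and_lln(self):
        """HbF stays >= 0 under truncation and class means converge to
        the configured mu at large n."""
        mu, sd = 6.39, 5.14
        cfg = CohortConfig(
            n=100_000,
            diplotype_freqs={"BEN/BEN": 1.0},
            hbf_params={"BEN/BEN": (mu, sd)},
            seed=1,
        )
        cohort = simulate_cohort(cfg)
        hbf = np.array([s.hbf for s in cohort.samples])
        assert (hbf >= 0).all()
        # truncation at 0 shifts the mean of N(6.39, 5.14) upward ~ +0.5;
        # compare against the analytic truncated mean instead of mu
        from scipy import stats

        a = (0 - mu) / sd
        expected = stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd)
        assert abs(hbf.mean() - expected) <= 3 * sd / math.sqrt(len(hbf))

    def test_alleles_match_table_rows(self, table):
        cfg = CohortConfig(n=20, diplotype_freqs={"SEN/AI": 1.0}, seed=4)
        cohort = simulate_cohort(cfg)
        for s in cohort.samples:
            assert {tuple(s.alleles_a), tuple(s.alleles_b)} == {
                table.row(Haplotype.SEN),
                table.row(Haplotype.AI),
            }


class TestEmitPhasedVcf:
    def test_ben_car_het_only_at_rs968857(self, panel, table, tmp_path):
        cfg = CohortConfig(n=1, diplotype_freqs={"BEN/CAR": 1.0}, seed=0)
        cohort = simulate_cohort(cfg)
        path = tmp_path / "one.vcf"
        emit_phased_vcf(cohort, panel, path)
        gt_by_site = {}
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            gt_by_site[fields[2]] = fields[9]
        het = {r for r, gt in gt_by_site.items() if gt[0] != gt[2]}
        assert het == {"rs968857"}

    def test_round_trip_recovers_truth_at_zero_error(self, panel, table, tmp_path):
        cfg = CohortConfig(n=1000, diplotype_freqs=None, seed=6,
                           haplotype_freqs={"BEN": 0.4, "CAR": 0.25, "SEN": 0.15,
                                            "CAM": 0.1, "AI": 0.1},
                           random_mating=True)
        cohort = simulate_cohort(cfg)
        path = tmp_path / "cohort.vcf"
        emit_phased_vcf(cohort, panel, path)
        records = classify_vcf(path, panel, table)
        truth = cohort.true_labels()
        assert len(records) == 1000
        assert all(r.canonical_label == truth[r.sample_id] for r in records)

    def test_full_missingness_gives_all_unknown(self, panel, table, tmp_path):
        cfg = CohortConfig(
            n=5, diplotype_freqs={"BEN/BEN": 1.0}, genotype_missing_rate=1.0, seed=0
        )
        cohort = simulate_cohort(cfg)
        path = tmp_path / "missing.vcf"
        emit_phased_vcf(cohort, panel, path)
        records = classify_vcf(path, panel, table)
        assert all(r.canonical_label == "UNKNOWN/UNKNOWN" for r in records)


class TestSimulateRflpAssay:
    def test_zero_error_matches_signature(self, patterns):
        cfg = CohortConfig(
            n=50,
            diplotype_freqs={"BEN/CAR": 0.5, "SEN/SEN": 0.5},
            seed=8,
        )
        cohort = simulate_cohort(cfg)
        counts = simulate_rflp_assay(cohort, patterns, 0.0, seed=1)
        for s, c in zip(cohort.samples, counts):
            assert c == genotype_signature(s.hap_a, s.hap_b, patterns)

    def test_eps_one_flips_deterministically(self, patterns):
        cfg = CohortConfig(n=10, diplotype_freqs={"BEN/BEN": 1.0}, seed=8)
        cohort = simulate_cohort(cfg)
        eps = [1.0, 0.0, 0.0, 0.0]
        counts = simulate_rflp_assay(cohort, patterns, eps, seed=1)
        truth = genotype_signature(Haplotype.BEN, Haplotype.BEN, patterns)
        for c in counts:
            assert c[0] == 2 - truth[0]
            assert c[1:] == truth[1:]

    def test_car_flips_to_ben_at_expected_rate(self, patterns):
        """With eps=0.2 at rs968857 only, a CAR chromosome misreads as
        BEN; ~1-(1-eps)^2 = 36% of CAR/CAR samples gain a BEN-containing
        consistent pair."""
        n = 2000
        cfg = CohortConfig(n=n, diplotype_freqs={"CAR/CAR": 1.0}, seed=12)
        cohort = simulate_cohort(cfg)
        eps = [0.0, 0.0, 0.0, 0.2]
        counts = simulate_rflp_assay(cohort, patterns, eps, seed=2)
        ben_containing = 0
        for c in counts:
            call = enumerate_unphased(c, patterns)
            if any(Haplotype.BEN in pair for pair in call.consistent_pairs):
                ben_containing += 1
        expected = 1 - 0.8**2
        assert abs(ben_containing / n - expected) < 4 * math.sqrt(
            expected * (1 - expected) / n
        )

    def test_discordance_monotone_in_flip_error(self, patterns):
        """Agreement between enumerated RFLP calls and truth degrades
        monotonically over eps in {0, 0.05, 0.2}."""
        cfg = CohortConfig(
            n=600,
            diplotype_freqs={"BEN/BEN": 0.4, "BEN/CAR": 0.3, "CAR/CAR": 0.2,
                             "SEN/SEN": 0.1},
            seed=21,
        )
        cohort = simulate_cohort(cfg)
        discordance = []
        for eps in (0.0, 0.05, 0.2):
            counts = simulate_rflp_assay(cohort, patterns, eps, seed=31)
            wrong = 0
            for s, c in zip(cohort.samples, counts):
                call = enumerate_unphased(c, patterns)
                truth_pair = frozenset({(s.hap_a, s.hap_b), (s.hap_b, s.hap_a)})
                unique_correct = (
                    len(call.consistent_pairs) == 1
                    and next(iter(call.consistent_pairs)) in truth_pair
                )
                wrong += not unique_correct
            discordance.append(wrong / len(cohort))
        assert discordance[0] == 0.0
        assert discordance[0] < discordance[1] < discordance[2]


def test_load_cohort_config_defaults(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("n: 25\nseed: 3\n")
    cfg = load_cohort_config(path)
    assert cfg.n == 25
    assert cfg.diplotype_freqs is not None
    assert abs(sum(cfg.diplotype_freqs.values()) - 1.0) < 1e-9
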