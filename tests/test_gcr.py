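"""Genotype-criteria scanning and the 1/3^(n+m) expectation."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import binom

from abdmap.gcr import (
    GCRConfig,
    expected_gcr_count,
    min_animals_for_unique_site,
    round_half_away,
    scan_gcr,
    site_meets_gcr,
)
from abdmap.vcfio import GenotypeCall, PhenotypeMap, VariantRecord


def record(genotypes, gq=99, dp=30, chrom="1", pos=100, samples=None):
    """Build an in-memory biallelic record from (a, b) allele pairs."""
    calls = [GenotypeCall(a, b, gq=gq, dp=dp) for a, b in genotypes]
    samples = samples or tuple(f"s{i}" for i in range(len(calls)))
    return VariantRecord(
        chrom=chrom, pos=pos, id=None, ref="A", alts=("T",), qual=100.0,
        info={}, calls=calls, samples=tuple(samples),
    )


@pytest.fixture
def phen():
    return PhenotypeMap(
        cases=["s0", "s1", "s2"], controls=[f"s{i}" for i in range(3, 9)]
    )


HOM_ALT, HET, HOM_REF = (1, 1), (0, 1), (0, 0)


class TestSiteMeetsGcr:
    def test_canonical_recessive_pattern(self, phen):
        rec = record([HOM_ALT] * 3 + [HET] * 6)
        assert site_meets_gcr(rec, phen) == (True, 1)

    def test_one_hom_ref_control_breaks_pattern(self, phen):
        rec = record([HOM_ALT] * 3 + [HET] * 5 + [HOM_REF])
        assert site_meets_gcr(rec, phen) == (False, None)

    def test_gq_threshold_is_strict(self, phen):
        calls = [GenotypeCall(1, 1, gq=12, dp=30)] + [
            GenotypeCall(1, 1, gq=99, dp=30)
        ] * 2 + [GenotypeCall(0, 1, gq=99, dp=30)] * 6
        rec = record([HOM_ALT] * 9)
        rec.calls = calls
        assert site_meets_gcr(rec, phen) == (False, None)
        # GQ=13 passes the >12 gate
        rec.calls[0] = GenotypeCall(1, 1, gq=13, dp=30)
        assert site_meets_gcr(rec, phen)[0] is True

    def test_dp_threshold_is_strict(self, phen):
        rec = record([HOM_ALT] * 3 + [HET] * 6, dp=11)
        assert site_meets_gcr(rec, phen) == (False, None)

    def test_reference_homozygote_depends_on_allele_mode(self, phen):
        rec = record([HOM_REF] * 3 + [HET] * 6)
        either = GCRConfig(allele_mode="either_homozygote")
        alt_only = GCRConfig(allele_mode="alt_only")
        assert site_meets_gcr(rec, phen, either) == (True, 0)
        assert site_meets_gcr(rec, phen, alt_only) == (False, None)

    def test_missing_genotype_fails(self, phen):
        rec = record([(None, None)] + [HOM_ALT] * 2 + [HET] * 6)
        assert site_meets_gcr(rec, phen) == (False, None)

    def test_control_must_carry_case_allele(self, phen):
        # controls het 1/2 do not carry the case allele 1? they do; use 0/2
        rec = record([HOM_ALT] * 3 + [(0, 2)] * 6)
        rec.alts = ("T", "G")
        assert site_meets_gcr(rec, phen) == (False, None)

    def test_absent_sample_raises(self, phen):
        rec = record([HOM_ALT] * 3 + [HET] * 5, samples=[f"s{i}" for i in range(8)])
        with pytest.raises(KeyError, match="s8"):
            site_meets_gcr(rec, phen)


def brute_force_gcr(rec, phen, cfg):
    """Independent textual re-statement of the criterion, checked literally:
    every genotype passes GQ>min_gq and DP>min_dp; all cases are homozygous
    for the same allele; all controls are heterozygous containing it."""
    for s in phen.all_samples:
        c = rec.call_for(s)
        if not (c.gq > cfg.min_gq and c.dp > cfg.min_dp):
            return False
    case_gts = [rec.call_for(s).alleles for s in phen.cases]
    for gt in case_gts:
        if None in gt or gt[0] != gt[1]:
            return False
    if len({gt[0] for gt in case_gts}) != 1:
        return False
    allele = case_gts[0][0]
    if cfg.allele_mode == "alt_only" and allele == 0:
        return False
    for s in phen.controls:
        gt = rec.call_for(s).alleles
        if None in gt or gt[0] == gt[1] or allele not in gt:
            return False
    return True


class TestScanAgainstOracle:
    @pytest.mark.parametrize("mode", ["either_homozygote", "alt_only"])
    def test_scan_matches_brute_force_on_random_records(self, mode, phen):
        rng = np.random.default_rng(202)
        cfg = GCRConfig(allele_mode=mode)
        records = []
        pairs = [(0, 0), (0, 1), (1, 1), (None, None)]
        for pos in range(1, 401):
            gts = [pairs[i] for i in rng.integers(0, 4, size=9)]
            gq = int(rng.integers(0, 40))
            dp = int(rng.integers(0, 40))
            records.append(record(gts, gq=gq, dp=dp, pos=pos))
        # bias part of the stream toward the pattern so hits actually occur
        for pos in range(401, 461):
            records.append(record([(1, 1)] * 3 + [(0, 1)] * 6, pos=pos))
        for pos in range(461, 501):
            gts = [(1, 1)] * 3 + [pairs[i] for i in rng.integers(0, 2, size=6)]
            records.append(record(gts, pos=pos))
        hits, _ = scan_gcr(records, phen, cfg)
        expected = {r.pos for r in records if brute_force_gcr(r, phen, cfg)}
        assert {h.pos for h in hits} == expected
        assert expected  # the oracle found something to compare

    def test_scan_is_deterministic(self, phen):
        records = [record([HOM_ALT] * 3 + [HET] * 6, pos=p) for p in (1, 2)]
        first = scan_gcr(records, phen)
        second = scan_gcr(records, phen)
        assert [h.key for h in first[0]] == [h.key for h in second[0]]

    def test_quality_gate_monotonicity(self, phen):
        rng = np.random.default_rng(7)
        records = []
        for pos in range(1, 201):
            gts = [(1, 1)] * 3 + [(0, 1)] * 6
            records.append(
                record(gts, gq=int(rng.integers(0, 30)),
                       dp=int(rng.integers(0, 30)), pos=pos)
            )
        loose, _ = scan_gcr(records, phen, GCRConfig(min_gq=5, min_dp=5))
        tight, _ = scan_gcr(records, phen, GCRConfig(min_gq=15, min_dp=15))
        assert {h.pos for h in tight} <= {h.pos for h in loose}


class TestExpectedCounts:
    def test_worked_example_14_million_sites_15_animals(self):
        assert round(expected_gcr_count(14_000_000, 5, 10), 2) == 0.98

    def test_nine_animal_genome_total(self):
        total = 8_234_367 + 1_523_928
        assert round_half_away(expected_gcr_count(total, 3, 6)) == 496

    @pytest.mark.parametrize(
        "snv,indel,expected",
        [(535_135, 101_947, 32), (142_293, 25_212, 9)],  # chr 1 and chr 25
    )
    def test_per_chromosome_rounding(self, snv, indel, expected):
        assert round_half_away(expected_gcr_count(snv + indel, 3, 6)) == expected

    def test_zero_animals_returns_site_count(self):
        assert expected_gcr_count(12345, 0, 0) == 12345

    def test_uniform_null_hit_rate_within_binomial_bounds(self, tmp_path):
        """On genotypes drawn uniformly from the three zygosity states the
        observed hit count must fall in the central 99% binomial band
        around 2S/3^(n+m) (either-homozygote) and S/3^(n+m) (alt-only)."""
        from abdmap.simdata import SimConfig, null_simulate
        from abdmap.vcfio import read_vcf

        cfg = SimConfig(
            n_chromosomes=2, chrom_length_bp=10_000_000, snv_density=100.0,
            n_cases=2, n_controls=2, causal_chrom="1", causal_pos=5_000_000,
            seed=33,
        )
        res = null_simulate(cfg, tmp_path, uniform_thirds=True)
        records = list(read_vcf(res.vcf_path))
        S = len(records)
        base = S / 3 ** 4
        for mode, expectation in [("either_homozygote", 2 * base),
                                  ("alt_only", base)]:
            hits, _ = scan_gcr(records, res.phenotypes, GCRConfig(allele_mode=mode))
            p = expectation / S
            lo, hi = binom.ppf([0.005, 0.995], S, p)
            assert lo <= len(hits) <= hi, (mode, len(hits), expectation)


class TestMinAnimals:
    def test_fourteen_million_sites_need_fifteen_animals(self):
        assert min_animals_for_unique_site(14_000_000) == 15

    def test_single_site_needs_nobody(self):
        assert min_animals_for_unique_site(1) == 0

    @pytest.mark.parametrize("k", range(1, 13))
    def test_exact_powers_of_three(self, k):
        assert min_animals_for_unique_site(3**k) == k
        assert min_animals_for_unique_site(3**k + 1) == k + 1

    def test_monotone_in_site_count(self):
        values = [min_animals_for_unique_site(s) for s in range(1, 2000, 37)]
        assert values == sorted(values)

    def test_rejects_empty_file(self):
        with pytest.raises(ValueError):
            min_animals_for_unique_site(0)
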