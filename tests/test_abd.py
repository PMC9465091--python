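"""Autozygosity-by-difference track, permutation threshold, regions."""

from __future__ import annotations

import numpy as np
import pytest

from abdmap.abd import (
    ABDTrack,
    AutozygosityDifferenceModel,
    abd_track,
    permutation_threshold,
    significant_regions,
)
from abdmap.roh import HET, HOM_ALT, HOM_REF, GenotypeMatrix
from abdmap.vcfio import PhenotypeMap


def matrix_from(codes: np.ndarray, positions=None, chrom="1") -> GenotypeMatrix:
    codes = np.asarray(codes, dtype=np.uint8)
    if positions is None:
        positions = np.arange(1, codes.shape[1] + 1) * 1000
    samples = tuple(f"s{i}" for i in range(codes.shape[0]))
    return GenotypeMatrix(
        samples=samples,
        positions={chrom: np.asarray(positions, dtype=np.int64)},
        codes={chrom: codes},
    )


def split_phen(n_cases, n_total):
    return PhenotypeMap(
        cases=[f"s{i}" for i in range(n_cases)],
        controls=[f"s{i}" for i in range(n_cases, n_total)],
    )


class TestTrack:
    def test_identical_groups_give_zero_everywhere(self):
        row = [HOM_REF, HET, HOM_ALT, HOM_ALT, HET]
        codes = np.array([row] * 4)
        track = abd_track(matrix_from(codes), split_phen(2, 4))
        assert np.allclose(track.scores, 0.0)

    def test_constructed_contrast_scores_run_length_inside_region(self):
        # cases homozygous over sites 1..3 (positions 2000..4000),
        # controls heterozygous there; everyone heterozygous outside.
        case_row = [HET, HOM_ALT, HOM_ALT, HOM_ALT, HET]
        ctrl_row = [HET, HET, HET, HET, HET]
        codes = np.array([case_row, case_row, ctrl_row, ctrl_row])
        track = abd_track(matrix_from(codes), split_phen(2, 4))
        run_kb = (4000 - 2000 + 1) / 1000.0
        assert track.scores == pytest.approx([0, run_kb, run_kb, run_kb, 0])

    def test_label_swap_negates_track(self):
        rng = np.random.default_rng(11)
        codes = rng.integers(0, 3, size=(6, 80)).astype(np.uint8)
        m = matrix_from(codes)
        fwd = abd_track(m, split_phen(3, 6))
        samples = list(m.samples)
        swapped = PhenotypeMap(cases=samples[3:], controls=samples[:3])
        rev = abd_track(m, swapped)
        assert np.allclose(fwd.scores, -rev.scores)

    def test_mean_difference_recomputable_from_group_means(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, size=(5, 40)).astype(np.uint8)
        track = abd_track(matrix_from(codes), split_phen(2, 5))
        d = track.data
        assert np.allclose(d["abd_kb"], d["mean_case_kb"] - d["mean_ctrl_kb"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            abd_track(matrix_from(np.zeros((2, 5))),
                      PhenotypeMap(cases=["s0", "s1"], controls=[]))


class TestPermutationThreshold:
    def test_same_seed_reproduces_threshold_and_pvalues(self):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 3, size=(6, 60)).astype(np.uint8)
        m = matrix_from(codes)
        phen = split_phen(3, 6)
        t1, p1 = permutation_threshold(m, phen, n_perm=50, seed=42)
        t2, p2 = permutation_threshold(m, phen, n_perm=50, seed=42)
        assert t1 == t2 and np.array_equal(p1, p2)

    def test_identical_samples_are_never_significant(self):
        """With genetically identical animals every permuted track equals
        the observed one, so empirical p-values stay at 1."""
        row = [HOM_ALT, HOM_ALT, HET, HOM_REF, HET, HOM_ALT]
        codes = np.array([row] * 6)
        m = matrix_from(codes)
        phen = split_phen(3, 6)
        _, pvalues = permutation_threshold(m, phen, n_perm=100, alpha=0.01,
                                           seed=1)
        assert (pvalues == 1.0).all()

    def test_invalid_parameters_rejected(self):
        m = matrix_from(np.zeros((4, 5)))
        phen = split_phen(2, 4)
        with pytest.raises(ValueError):
            permutation_threshold(m, phen, n_perm=0)
        with pytest.raises(ValueError):
            permutation_threshold(m, phen, alpha=1.5)

    def test_null_significance_fraction_is_super_uniform(self, tmp_path):
        """Random labels on structureless data: the fraction of sites called
        significant at alpha stays at or below alpha, within Monte-Carlo
        error across replicate null datasets."""
        from abdmap.roh import zygosity_matrix
        from abdmap.simdata import SimConfig, null_simulate
        from abdmap.vcfio import read_vcf

        alpha = 0.01
        fractions = []
        for seed in (101, 102, 103, 104, 105):
            cfg = SimConfig(n_chromosomes=2, chrom_length_bp=10_000_000,
                            snv_density=40.0, causal_chrom="1",
                            causal_pos=5_000_000, seed=seed)
            res = null_simulate(cfg, tmp_path / str(seed))
            m = zygosity_matrix(read_vcf(res.vcf_path), res.phenotypes)
            _, pvalues = permutation_threshold(
                m, res.phenotypes, n_perm=100, alpha=alpha, seed=seed
            )
            fractions.append(float(np.mean(pvalues <= alpha)))
        mean = float(np.mean(fractions))
        se = float(np.std(fractions, ddof=1) / np.sqrt(len(fractions)))
        assert mean <= alpha + 3 * max(se, 1e-4), fractions


class TestSignificantRegions:
    def track(self, scores, positions=None):
        scores = np.asarray(scores, dtype=float)
        if positions is None:
            positions = np.arange(1, len(scores) + 1) * 1000
        import pandas as pd

        data = pd.DataFrame(
            {"chrom": "1", "pos": positions,
             "mean_case_kb": scores, "mean_ctrl_kb": 0.0, "abd_kb": scores}
        )
        return ABDTrack(data=data, n_cases=1, n_controls=1)

    def test_all_below_threshold_is_empty(self):
        regions = significant_regions(self.track([1, 1, 1]), threshold=5)
        assert regions.empty

    def test_single_site_region_spans_one_bp(self):
        regions = significant_regions(self.track([0, 9, 0]), threshold=5)
        assert len(regions) == 1
        assert regions.loc[0, "length_bp"] == 1
        assert regions.loc[0, "start_pos"] == 2000

    def test_sub_threshold_gap_splits_regions(self):
        regions = significant_regions(
            self.track([9, 9, 1, 9, 9]), threshold=5
        )
        assert len(regions) == 2
        assert list(regions["n_sites"]) == [2, 2]

    def test_threshold_is_inclusive(self):
        regions = significant_regions(self.track([5.0]), threshold=5.0)
        assert len(regions) == 1


class TestModelSurface:
    def test_fit_from_vcf_and_summary(self, tmp_path):
        from abdmap.simdata import SimConfig, simulate

        cfg = SimConfig(n_chromosomes=2, chrom_length_bp=8_000_000,
                        snv_density=20.0, causal_chrom="1",
                        causal_pos=4_000_000, ibd_halflength_bp=1_500_000,
                        seed=9)
        res = simulate(cfg, tmp_path)
        model = AutozygosityDifferenceModel.from_vcf(
            res.vcf_path, res.phenotypes
        )
        fitted = model.fit(n_perm=50, alpha=0.01, seed=4)
        text = fitted.summary()
        assert "threshold" in text and "cases" in text
        out = tmp_path / "track.tsv"
        fitted.to_tsv(out)
        assert out.exists() and "abd_kb" in out.read_text()
        png = tmp_path / "manhattan.png"
        fitted.plot_manhattan(out=png)
        assert png.stat().st_size > 0

    def test_top_site_recovers_planted_region_across_seeds(self, tmp_path):
        """The argmax of the ABD track lies inside the true homozygous-IBD
        region of the planted variant in >= 95% of simulations."""
        from abdmap.roh import zygosity_matrix
        from abdmap.simdata import SimConfig, simulate
        from abdmap.vcfio import read_vcf

        hits = 0
        n_seeds = 20
        for seed in range(300, 300 + n_seeds):
            cfg = SimConfig(seed=seed)
            res = simulate(cfg, tmp_path / str(seed))
            m = zygosity_matrix(read_vcf(res.vcf_path), res.phenotypes)
            track = abd_track(m, res.phenotypes)
            top = track.data.iloc[int(np.argmax(track.scores))]
            lo = min(r[0] for r in res.truth.ibd_regions.values())
            hi = max(r[1] for r in res.truth.ibd_regions.values())
            if top["chrom"] == res.truth.causal_chrom and lo <= top["pos"] <= hi:
                hits += 1
        assert hits >= 0.95 * n_seeds
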