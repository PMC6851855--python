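"""Diversity, F_ST, window scans and haplotype tables."""

import math

import numpy as np
import pandas as pd
import pytest

from triadkit import popgen, simulate
from triadkit.popgen import (
    SNPMatrix,
    compare_haplotype_freqs,
    extract_haplotypes,
    frequencies_from_counts,
    hudson_fst,
    site_pi,
    window_scan,
)


def _snp_matrix(positions, genotypes, populations):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    return SNPMatrix(
        chrom="chr1",
        positions=np.asarray(positions),
        genotypes=genotypes,
        accessions=[f"a{i}" for i in range(genotypes.shape[1])],
        populations=list(populations),
    )


class TestSitePi:
    def test_single_heterozygous_pair(self):
        # n=2 allele copies, one ref one alt: the only pair differs
        assert site_pi(2, 1) == pytest.approx(1.0)

    def test_monomorphic_site_zero(self):
        assert site_pi(8, 0) == 0.0
        assert site_pi(8, 8) == 0.0

    def test_four_copies_p_quarter(self):
        # 3 differing pairs out of 6
        assert site_pi(4, 1) == pytest.approx(0.5)

    def test_needs_two_copies(self):
        with pytest.raises(ValueError):
            site_pi(1, 0)

    def test_allele_label_swap_invariant(self):
        assert site_pi(10, 3) == pytest.approx(site_pi(10, 7))


class TestHudsonFst:
    def test_fixed_different_alleles(self):
        assert hudson_fst(1.0, 20, 0.0, 20) == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        assert abs(hudson_fst(0.5, 10**9, 0.5, 10**9)) < 1e-6

    def test_hand_computed_infinite_n(self):
        f = hudson_fst(0.8, 10**9, 0.2, 10**9)
        assert f == pytest.approx((0.68 - 0.32) / 0.68, abs=1e-6)

    def test_both_fixed_same_allele_uninformative(self):
        assert hudson_fst(0.0, 10, 0.0, 12) is None

    def test_label_swap_invariant(self):
        assert hudson_fst(0.7, 30, 0.2, 40) == pytest.approx(
            hudson_fst(0.3, 30, 0.8, 40)
        )


class TestWindowScan:
    def test_three_snp_window_matches_per_site_oracle(self):
        # population 1: two accessions; population 2: two accessions
        geno = np.array(
            [
                [2, 0, 0, 0],
                [2, 2, 0, 2],
                [0, 0, 2, 2],
            ]
        )
        snp = _snp_matrix([100, 200, 300], geno, ["p1", "p1", "p2", "p2"])
        scan = window_scan(snp, window=1000, step=1000, chrom_length=1000)
        row = scan.iloc[0]
        # per-site oracle for pi in p1 (4 allele copies, alt copies summed)
        pis = [site_pi(4, int(g[:2].sum())) for g in geno]
        assert row.pi_p1 == pytest.approx(np.mean(pis))
        # ratio-of-averages F_ST oracle
        hw_sum = hb_sum = 0.0
        for g in geno:
            p1 = g[:2].sum() / 4
            p2 = g[2:].sum() / 4
            hb = p1 * (1 - p2) + p2 * (1 - p1)
            if hb == 0:
                continue
            hw = (2 * p1 * (1 - p1) * 4 / 3 + 2 * p2 * (1 - p2) * 4 / 3) / 2
            hw_sum += hw
            hb_sum += hb
        assert row.fst == pytest.approx(1 - hw_sum / hb_sum)

    def test_windows_tile_at_step(self):
        rng = np.random.default_rng(0)
        positions = np.sort(rng.choice(10_000_000, 300, replace=False)) + 1
        geno = 2 * rng.integers(0, 2, size=(300, 10)).astype(np.int8)
        snp = _snp_matrix(positions, geno, ["p1"] * 5 + ["p2"] * 5)
        scan = window_scan(snp, window=2_000_000, step=400_000,
                           chrom_length=10_000_000)
        assert (scan.end - scan.start == 2_000_000).all()
        assert (np.diff(scan.start) == 400_000).all()

    def test_empty_window_reports_missing(self):
        snp = _snp_matrix([100], [[2, 0, 2, 0]], ["p1", "p1", "p2", "p2"])
        scan = window_scan(snp, window=50, step=50, chrom_length=200)
        empty = scan[scan.n_snps == 0]
        assert len(empty) > 0
        assert empty.pi_p1.isna().all()

    def test_window_stats_equal_per_site_oracle_on_random_matrices(self):
        """Ratio-of-averages windows recompute exactly from per-site terms."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            n_snp = rng.integers(3, 30)
            n_acc = int(rng.integers(4, 12)) * 2
            positions = np.sort(rng.choice(5000, n_snp, replace=False)) + 1
            geno = rng.choice([0, 2, -1], p=[0.45, 0.45, 0.1],
                              size=(n_snp, n_acc)).astype(np.int8)
            pops = ["p1"] * (n_acc // 2) + ["p2"] * (n_acc // 2)
            snp = _snp_matrix(positions, geno, pops)
            scan = window_scan(snp, window=5000, step=5000, chrom_length=5000)
            row = scan.iloc[0]
            pis, hws, hbs = [], [], []
            for g in geno:
                g1, g2 = g[: n_acc // 2], g[n_acc // 2:]
                stats = []
                for gg in (g1, g2):
                    called = gg[gg >= 0]
                    n = 2 * called.size
                    alt = int(called.sum())
                    stats.append((n, alt))
                (n1, a1), (n2, a2) = stats
                if n1 >= 2:
                    pis.append(site_pi(n1, a1))
                if n1 >= 2 and n2 >= 2:
                    f = hudson_fst(a1 / n1, n1, a2 / n2, n2)
                    if f is not None:
                        p1, p2 = a1 / n1, a2 / n2
                        hbs.append(p1 * (1 - p2) + p2 * (1 - p1))
                        hws.append(
                            (2 * p1 * (1 - p1) * n1 / (n1 - 1)
                             + 2 * p2 * (1 - p2) * n2 / (n2 - 1)) / 2
                        )
            if pis:
                assert row.pi_p1 == pytest.approx(np.mean(pis))
            if hbs:
                assert row.fst == pytest.approx(1 - sum(hws) / sum(hbs))


class TestHaplotypes:
    def test_identical_vectors_collapse(self):
        geno = np.array([[2, 2, 0], [0, 0, 2]])
        snp = _snp_matrix([10, 20], geno, ["p1", "p1", "p1"])
        table = extract_haplotypes(snp, (0, 30))
        assert set(table["count"]) == {2, 1}
        assert table.loc[table["count"] == 2, "haplotype"].iloc[0] == "H1"

    def test_accessions_with_missing_calls_excluded(self):
        geno = np.array([[2, -1, 0], [0, 0, 2]])
        snp = _snp_matrix([10, 20], geno, ["p1", "p1", "p1"])
        table = extract_haplotypes(snp, (0, 30))
        assert table["count"].sum() == 2

    def test_heterozygous_calls_excluded(self):
        geno = np.array([[2, 1, 0], [0, 0, 2]])
        snp = _snp_matrix([10, 20], geno, ["p1", "p1", "p1"])
        table = extract_haplotypes(snp, (0, 30))
        assert table["count"].sum() == 2

    def test_frequencies_sum_to_one_per_population(self):
        sim = simulate.gen_popgen_vcf(simulate.SimConfig(seed=3, missing_rate=0.0))
        snp = _snp_matrix(sim.positions, sim.genotypes, sim.populations)
        table = extract_haplotypes(snp, sim.gene_region)
        sums = table.groupby("population")["frequency"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_exact_recovery_against_truth_without_missingness(self):
        sim = simulate.gen_popgen_vcf(simulate.SimConfig(seed=4, missing_rate=0.0))
        snp = _snp_matrix(sim.positions, sim.genotypes, sim.populations)
        table = extract_haplotypes(snp, sim.gene_region)
        truth = sim.truth_haplotypes.groupby(["population", "haplotype"]).size()
        got = table.set_index(["population", "haplotype"])["count"].sort_index()
        assert sorted(got.to_numpy()) == sorted(truth.to_numpy())
        assert got.sum() == truth.sum()

    def test_region_without_snps_rejected(self):
        snp = _snp_matrix([100], [[2, 0]], ["p1", "p2"])
        with pytest.raises(ValueError):
            extract_haplotypes(snp, (500, 600))

    def test_frequencies_from_counts(self):
        freqs = frequencies_from_counts({"H1": 306, "H2": 39, "H3": 17, "H4": 1})
        assert freqs["H1"] == pytest.approx(306 / 363)


class TestCompareHaplotypeFreqs:
    def _table(self):
        return pd.DataFrame(
            {
                "gene": ["g"] * 4,
                "population": ["wild", "wild", "dom", "dom"],
                "haplotype": ["H1", "H2", "H1", "H2"],
                "key": ["00", "11", "00", "11"],
                "count": [6, 25, 28, 0],
                "frequency": [6 / 31, 25 / 31, 1.0, 0.0],
            }
        )

    def test_strong_differentiation_small_p(self):
        p = compare_haplotype_freqs(self._table(), "H1", "wild", "dom")
        assert p < 0.0001

    def test_equal_balanced_counts_p_one(self):
        table = self._table()
        table["count"] = [10, 10, 10, 10]
        assert compare_haplotype_freqs(table, "H1", "wild", "dom") == pytest.approx(1.0)

    def test_absent_haplotype_p_one(self):
        assert compare_haplotype_freqs(self._table(), "H9", "wild", "dom") == 1.0

    def test_unknown_population_rejected(self):
        with pytest.raises(ValueError):
            compare_haplotype_freqs(self._table(), "H1", "wild", "landrace")


class TestVcfRoundTrip:
    def test_generated_vcf_reads_back_unchanged(self, tmp_path):
        sim = simulate.gen_popgen_vcf(simulate.SimConfig(seed=5, n_snps=250))
        vcf, pops = tmp_path / "sim.vcf", tmp_path / "pops.tsv"
        sim.write_vcf(vcf)
        sim.write_populations(pops)
        snp = SNPMatrix.from_vcf(vcf, pops)
        assert np.array_equal(snp.positions, sim.positions)
        assert np.array_equal(snp.genotypes, sim.genotypes)
        assert snp.populations == sim.populations
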