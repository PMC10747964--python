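"""Sliding windows, haplotype counting (phased and EM), Gabriel blocks,
runs of homozygosity and the Fisher homozygosity test."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from lymphmap.core import GenotypeMatrix, InputError, MISSING
from lymphmap.haplo import (
    fisher_exact_2x2,
    haplotype_blocks,
    homozygosity_test,
    roh_in_region,
    sliding_windows,
    window_haplotype_freqs,
)


def _gm(doses, haps=None, alleles=None):
    doses = np.asarray(doses)
    n, m = doses.shape
    aa = [a[0] for a in alleles] if alleles else ["A"] * m
    ab = [a[1] for a in alleles] if alleles else ["C"] * m
    st = pd.DataFrame(
        {
            "chrom": 1, "pos": np.arange(1, m + 1), "snp_id": [f"s{j}" for j in range(m)],
            "allele_a": aa, "allele_b": ab,
        }
    )
    return GenotypeMatrix([f"i{k}" for k in range(n)], st, doses, haplotypes=haps)


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "n_snps,expected",
        [(8, 28), (2, 1), (10, 42)],  # sum over widths 2..8 of (L - w + 1)
    )
    def test_window_counts_closed_form(self, n_snps, expected):
        assert len(sliding_windows(n_snps)) == expected

    def test_too_few_snps_empty(self):
        assert sliding_windows(1) == []

    def test_windows_stay_in_bounds(self):
        for start, width in sliding_windows(12):
            assert start + width <= 12


class TestWindowHaplotypes:
    def test_phased_counts_are_direct_tallies(self):
        h1 = np.array([[0, 0], [1, 1], [0, 1]], dtype=np.uint8)
        h2 = np.array([[0, 1], [1, 1], [0, 1]], dtype=np.uint8)
        gm = _gm(h1 + h2, haps=(h1, h2), alleles=[("G", "C"), ("A", "T")])
        win = window_haplotype_freqs(gm, (0, 2), {f"i{k}": "case" for k in range(3)})
        assert win.counts["case"] == {"GA": 1, "GT": 3, "CT": 2}

    def test_counts_sum_to_twice_complete_samples(self, small_bundle):
        gm = small_bundle.genotypes
        cohorts = dict(
            zip(small_bundle.phenotypes["sample_id"], small_bundle.phenotypes["status"])
        )
        win = window_haplotype_freqs(gm, (10, 4), cohorts)
        n_case = (small_bundle.phenotypes["status"] == "case").sum()
        n_ctrl = (small_bundle.phenotypes["status"] == "control").sum()
        assert sum(win.counts.get("case", {}).values()) == 2 * n_case
        assert sum(win.counts.get("control", {}).values()) == 2 * n_ctrl

    def test_em_double_heterozygote_splits_evenly(self):
        # one individual het at both SNPs: the two phase resolutions are
        # unidentifiable and EM leaves mass split between them
        gm = _gm(np.array([[1, 1]]))
        win = window_haplotype_freqs(gm, (0, 2), {"i0": "x"})
        tallies = sorted(win.counts["x"].values())
        assert len(win.counts["x"]) == 4
        assert np.allclose(tallies, 0.5)

    def test_em_recovers_known_haplotype_frequencies(self):
        # simulate unphased genotypes from known 3-SNP haplotype frequencies
        rng = np.random.default_rng(0)
        haps = np.array([[0, 0, 0], [1, 1, 0], [0, 1, 1], [1, 0, 1]], dtype=np.uint8)
        freqs = np.array([0.4, 0.3, 0.2, 0.1])
        n = 200
        draws = rng.choice(4, size=(n, 2), p=freqs)
        h1, h2 = haps[draws[:, 0]], haps[draws[:, 1]]
        gm = _gm(h1 + h2)  # unphased: no haplotypes attached
        win = window_haplotype_freqs(gm, (0, 3), {f"i{k}": "x" for k in range(n)})
        total = sum(win.counts["x"].values())
        est = {h: c / total for h, c in win.counts["x"].items()}
        truth = {"AAA": 0.4, "CCA": 0.3, "ACC": 0.2, "CAC": 0.1}
        for hap, f in truth.items():
            assert est.get(hap, 0.0) == pytest.approx(f, abs=0.05)


class TestHaplotypeBlocks:
    def test_perfect_ld_block_detected(self):
        rng = np.random.default_rng(1)
        # 5 SNPs in perfect LD: only two complementary haplotypes segregate
        draws = rng.integers(0, 2, size=(60, 2))
        base = np.array([[0, 0, 0, 0, 0], [1, 1, 1, 1, 1]], dtype=np.uint8)
        h1, h2 = base[draws[:, 0]], base[draws[:, 1]]
        gm = _gm(h1 + h2, haps=(h1, h2))
        assert haplotype_blocks(gm) == [(0, 4)]

    def test_independent_snps_give_no_blocks(self):
        rng = np.random.default_rng(2)
        h1 = rng.integers(0, 2, size=(120, 6)).astype(np.uint8)
        h2 = rng.integers(0, 2, size=(120, 6)).astype(np.uint8)
        gm = _gm(h1 + h2, haps=(h1, h2))
        assert haplotype_blocks(gm) == []

    def test_single_snp_no_blocks(self):
        h = np.array([[0], [1]], dtype=np.uint8)
        gm = _gm(h + h, haps=(h, h))
        assert haplotype_blocks(gm, (0, 0)) == []

    def test_blocks_never_overlap(self, small_bundle):
        gm = small_bundle.genotypes
        blocks = haplotype_blocks(gm, (0, 39))
        for (a1, b1), (a2, b2) in zip(blocks, blocks[1:]):
            assert b1 < a2


class TestRoh:
    def test_all_heterozygous_no_runs(self):
        gm = _gm(np.ones((1, 10), dtype=int))
        assert roh_in_region(gm)["i0"] == []

    def test_all_homozygous_single_run(self):
        gm = _gm(np.full((1, 7), 2))
        assert roh_in_region(gm)["i0"] == [(0, 6)]

    def test_matches_rescan_oracle(self):
        rng = np.random.default_rng(3)
        doses = rng.integers(0, 3, size=(20, 60))
        doses[rng.random(doses.shape) < 0.05] = MISSING
        gm = _gm(doses)
        got = roh_in_region(gm, min_run_snps=3)
        for i, sid in enumerate(gm.sample_ids):
            runs = []
            k = 0
            while k < 60:
                if doses[i, k] in (0, 2):
                    start = k
                    while k < 60 and doses[i, k] in (0, 2):
                        k += 1
                    if k - start >= 3:
                        runs.append((start, k - 1))
                else:
                    k += 1
            assert got[sid] == runs


def _fisher_oracle(a, b, c, d):
    """Exact-rational enumeration of the two-sided Fisher p."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    def pmf(k):
        return Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), math.comb(n, c1))
    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        if pmf(k) <= p_obs:
            total += pmf(k)
    return float(total)


class TestFisher:
    @pytest.mark.parametrize(
        "table",
        [(3, 20, 52, 36), (0, 10, 10, 0), (5, 5, 5, 5), (1, 9, 7, 3), (2, 0, 3, 11)],
    )
    def test_matches_exact_enumeration_oracle(self, table):
        assert fisher_exact_2x2(*table) == pytest.approx(_fisher_oracle(*table), abs=1e-12)

    def test_equal_proportions_p_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_symmetric_under_row_swap(self):
        assert fisher_exact_2x2(3, 20, 52, 36) == pytest.approx(
            fisher_exact_2x2(52, 36, 3, 20), abs=1e-12
        )


class TestHomozygosityTest:
    def _data(self):
        # 4 cases (1 fully homozygous), 6 controls (4 fully homozygous)
        doses = np.array(
            [
                [0, 2, 0], [1, 2, 0], [0, 1, 0], [2, 2, 1],
                [0, 0, 0], [2, 2, 2], [0, 2, 2], [2, 0, 0], [1, 1, 1], [0, 1, 2],
            ]
        )
        gm = _gm(doses)
        phen = pd.DataFrame(
            {
                "sample_id": gm.sample_ids,
                "status": ["case"] * 4 + ["control"] * 6,
                "age_years": 5.0,
            }
        )
        return gm, phen

    def test_counts_and_margins(self):
        gm, phen = self._data()
        t = homozygosity_test(gm, [0, 1, 2], phen)
        assert (t.case_hom, t.case_not) == (1, 3)
        assert (t.control_hom, t.control_not) == (4, 2)
        assert t.case_hom + t.case_not == 4

    def test_p_matches_oracle(self):
        gm, phen = self._data()
        t = homozygosity_test(gm, [0, 1, 2], phen)
        assert t.p_value == pytest.approx(_fisher_oracle(1, 3, 4, 2), abs=1e-12)

    def test_missing_dose_excludes_sample(self):
        gm, phen = self._data()
        gm.doses[0, 1] = MISSING
        t = homozygosity_test(gm, [0, 1, 2], phen)
        assert t.case_hom + t.case_not == 3

    def test_empty_cohort_rejected(self):
        gm, phen = self._data()
        with pytest.raises(InputError):
            homozygosity_test(gm, [0], phen.iloc[0:0])
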