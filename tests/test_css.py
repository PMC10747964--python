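"""Composite selection signals: component statistics, rank combination,
smoothing and region calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lymphmap.core import GenotypeMatrix, InputError
from lymphmap.css import (
    composite_css,
    delta_daf,
    ehh_curve,
    fst_per_snp,
    significant_regions,
    smooth_css,
    xpehh,
)


def _gm(doses, haps=None, chrom=None, pos=None):
    doses = np.asarray(doses)
    n, m = doses.shape
    st = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else 1,
            "pos": pos if pos is not None else np.arange(1, m + 1),
            "snp_id": [f"s{j}" for j in range(m)],
            "allele_a": "A",
            "allele_b": "C",
        }
    )
    return GenotypeMatrix([f"i{k}" for k in range(n)], st, doses, haplotypes=haps)


def _hwe(rng, p, n):
    return rng.binomial(2, p[None, :].repeat(n, axis=0))


class TestFst:
    def test_fixed_difference_gives_theta_one(self):
        a = _gm(np.full((20, 3), 2))
        b = _gm(np.zeros((20, 3), dtype=int))
        assert np.allclose(fst_per_snp(a, b), 1.0)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.8, 400)
        a = _gm(_hwe(rng, p, 500))
        b = _gm(_hwe(rng, p, 500))
        assert np.nanmean(fst_per_snp(a, b)) < 0.01

    def test_random_split_of_pooled_population_near_zero(self):
        rng = np.random.default_rng(1)
        pool = _hwe(rng, rng.uniform(0.2, 0.8, 500), 200)
        perm = rng.permutation(200)
        theta = fst_per_snp(_gm(pool[perm[:100]]), _gm(pool[perm[100:]]))
        assert abs(np.nanmean(theta)) < 0.005

    def test_monomorphic_in_both_flagged_invalid(self):
        a = _gm(np.zeros((5, 1), dtype=int))
        b = _gm(np.zeros((5, 1), dtype=int))
        assert np.isnan(fst_per_snp(a, b)[0])


class TestDeltaDaf:
    def test_directional_difference(self):
        out = delta_daf(np.array([0.9]), np.array([0.1]), np.array([0.0]))
        assert out[0] == pytest.approx(0.8)

    def test_equal_frequencies_zero(self):
        out = delta_daf(np.array([0.4]), np.array([0.4]), np.array([0.0]))
        assert out[0] == 0.0

    def test_flipping_ancestral_call_negates(self):
        t, r = np.array([0.7]), np.array([0.2])
        assert delta_daf(t, r, np.array([0.0]))[0] == pytest.approx(
            -delta_daf(t, r, np.array([1.0]))[0]
        )

    def test_unresolvable_ancestral_flagged(self):
        out = delta_daf(np.array([0.5]), np.array([0.5]), np.array([np.nan]))
        assert np.isnan(out[0])


class TestEhh:
    def test_identical_haplotypes_keep_ehh_one(self):
        haps = np.tile(np.array([[0, 1, 0, 1, 1]], dtype=np.uint8), (6, 1))
        d, e = ehh_curve(haps, np.arange(5) * 100, core_snp=2, direction="right")
        assert np.allclose(e, 1.0)
        assert len(e) == 3  # core + 2 to the right

    def test_all_distinct_at_adjacent_snp_truncates(self):
        haps = np.array([[0, 0], [0, 1]], dtype=np.uint8)
        # after the adjacent SNP every haplotype is unique: EHH = 0 < cutoff
        d, e = ehh_curve(haps, np.array([0, 50]), core_snp=0, direction="right")
        assert len(e) == 1 and e[0] == 1.0

    def test_matches_pair_counting_oracle(self):
        # oracle: O(n^2) enumeration of identical haplotype pairs
        rng = np.random.default_rng(2)
        haps = rng.integers(0, 2, size=(30, 25)).astype(np.uint8)
        pos = np.sort(rng.choice(10_000, size=25, replace=False))
        core = 12
        for direction, step in (("left", -1), ("right", 1)):
            d, e = ehh_curve(haps, pos, core, direction, min_ehh=0.0)
            n = len(haps)
            assert e[0] == 1.0  # at the core by definition
            for k in range(1, len(e)):
                j = core + step * k
                lo, hi = sorted((core, j))
                seg = haps[:, lo : hi + 1]
                pairs = 0
                for a in range(n):
                    for b in range(a + 1, n):
                        pairs += int(np.array_equal(seg[a], seg[b]))
                assert e[k] == pytest.approx(pairs / (n * (n - 1) / 2))

    def test_fewer_than_two_haplotypes_rejected(self):
        with pytest.raises(InputError):
            ehh_curve(np.zeros((1, 5), dtype=np.uint8), np.arange(5), 2, "left")


class TestXpehh:
    def test_identical_populations_give_zero(self):
        rng = np.random.default_rng(3)
        haps = rng.integers(0, 2, size=(20, 15)).astype(np.uint8)
        pos = np.arange(15) * 1000.0
        v = xpehh(haps, haps.copy(), pos, core_snp=7)
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_target_sweep_positive_at_core(self):
        rng = np.random.default_rng(4)
        m = 21
        pos = np.arange(m) * 1000.0
        ref = rng.integers(0, 2, size=(40, m)).astype(np.uint8)
        sweep = np.tile(rng.integers(0, 2, size=(1, m)).astype(np.uint8), (36, 1))
        target = np.vstack([sweep, rng.integers(0, 2, size=(4, m)).astype(np.uint8)])
        assert xpehh(target, ref, pos, core_snp=10) > 0.5

    def test_standardization_over_valid_snps(self):
        from lymphmap.css import xpehh_scan

        rng = np.random.default_rng(5)
        m = 1200
        h1 = rng.integers(0, 2, size=(30, m)).astype(np.uint8)
        h2 = rng.integers(0, 2, size=(30, m)).astype(np.uint8)
        r1 = rng.integers(0, 2, size=(30, m)).astype(np.uint8)
        r2 = rng.integers(0, 2, size=(30, m)).astype(np.uint8)
        gm_t = _gm((h1 + h2), haps=(h1, h2), pos=np.arange(1, m + 1) * 500)
        gm_r = _gm((r1 + r2), haps=(r1, r2), pos=np.arange(1, m + 1) * 500)
        raw, std = xpehh_scan(gm_t, gm_r)
        valid = ~np.isnan(std)
        assert valid.sum() >= 1000
        assert np.nanmean(std) == pytest.approx(0.0, abs=0.05)
        assert np.nanstd(std) == pytest.approx(1.0, abs=0.05)


class TestCompositeCss:
    def test_median_rank_closed_form(self):
        comp = np.tile(np.arange(999, dtype=float)[:, None], (1, 3))
        t = composite_css(comp)
        assert t["css"].iloc[499] == pytest.approx(-np.log10(0.5), abs=1e-12)

    def test_three_snp_fractional_ranks(self):
        comp = np.array([[1.0], [2.0], [3.0]])
        t = composite_css(comp)
        z = stats.norm.ppf([0.25, 0.5, 0.75])
        assert np.allclose(t["zbar"], z)

    def test_top_rank_closed_form(self):
        comp = np.tile(np.arange(999, dtype=float)[:, None], (1, 3))
        t = composite_css(comp)
        expected = -np.log10(stats.norm.sf(np.sqrt(3) * stats.norm.ppf(0.999)))
        assert t["css"].iloc[-1] == pytest.approx(expected, rel=1e-6)

    def test_invalid_component_reduces_m(self):
        comp = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, np.nan]])
        t = composite_css(comp)
        assert (t["m"] == 1).all()

    def test_all_invalid_gives_missing(self):
        comp = np.full((3, 2), np.nan)
        comp[:2, 0] = [1.0, 2.0]
        t = composite_css(comp)
        assert np.isnan(t["css"].iloc[2])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        comp = rng.normal(size=(200, 3))
        t1 = composite_css(comp)
        warped = np.column_stack(
            [np.exp(comp[:, 0]), comp[:, 1] ** 3, np.arctan(comp[:, 2])]
        )
        t2 = composite_css(warped)
        assert np.allclose(t1["css"], t2["css"])

    def test_null_pvalues_uniform(self):
        from lymphmap.studies import css_combiner_null_uniformity

        ks = css_combiner_null_uniformity(n_reps=20, seed=0)
        assert np.sum(ks > 0.01) >= 19


class TestSmoothing:
    def test_constant_vector_unchanged(self):
        css = np.full(50, 2.5)
        out = smooth_css(css, np.ones(50), np.arange(50) * 10_000)
        assert np.allclose(out, 2.5)

    def test_isolated_snp_keeps_own_value(self):
        css = np.array([1.0, 5.0])
        pos = np.array([0, 10_000_000])
        out = smooth_css(css, np.ones(2), pos, window_bp=1_000_000)
        assert np.allclose(out, css)

    def test_matches_brute_force_window_mean(self):
        rng = np.random.default_rng(7)
        n = 400
        chrom = np.r_[np.ones(200, int), np.full(200, 2)]
        pos = np.concatenate(
            [np.sort(rng.choice(20_000_000, 200, replace=False)) for _ in range(2)]
        ).astype(float)
        css = rng.uniform(0, 8, n)
        out = smooth_css(css, chrom, pos, window_bp=1_000_000)
        for j in range(n):
            sel = (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= 500_000)
            assert out[j] == pytest.approx(css[sel].mean(), abs=1e-12)


class TestRegions:
    def test_single_snp_region(self):
        s = np.zeros(200)
        s[37] = 10.0
        regions, thr = significant_regions(s, np.ones(200), np.arange(200) * 100.0)
        assert len(regions) == 1
        assert regions[0].snp_indices.tolist() == [37]
        assert regions[0].regional_average == 10.0

    def test_fraction_above_quantile_bounded(self):
        rng = np.random.default_rng(8)
        s = rng.uniform(size=10_000)
        regions, thr = significant_regions(s, np.ones(10_000), np.arange(10_000.0))
        assert np.mean(s > thr) <= 0.005

    def test_runs_split_by_gap(self):
        s = np.zeros(20)
        s[[3, 4, 6]] = 5.0  # gap at index 5
        regions, _ = significant_regions(s, np.ones(20), np.arange(20.0), quantile=0.8)
        starts = sorted(r.snp_indices[0] for r in regions)
        assert len(regions) == 2 and starts == [3, 6]


class TestSweepRecovery:
    def test_planted_sweep_reaches_top_half_percent(self):
        from lymphmap.studies import css_sweep_recovery

        assert css_sweep_recovery(n_reps=20, seed=0) >= 0.8
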