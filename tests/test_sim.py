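"""Synthetic-cohort generator: pedigree structure, gene dropping,
phenotype model and reference panel."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lymphmap.core import ConfigError, MISSING
from lymphmap.css import fst_per_snp
from lymphmap.sim import (
    SimConfig,
    assign_phenotypes,
    gene_drop,
    risk_genotype,
    simulate_cohort,
    simulate_pedigree,
    simulate_reference_panel,
)


def _tiny(seed=0, **kw):
    defaults = dict(
        n_chromosomes=2, snps_per_chromosome=40, risk_chromosome=1,
        risk_haplotype_span=(10, 19), n_founders=10, n_generations=3,
        n_offspring_per_generation=20, seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimConfig:
    def test_penetrance_ordering_enforced(self):
        with pytest.raises(ConfigError):
            _tiny(baseline_penetrance_f0=0.5, heterozygote_penetrance_f1=0.1)

    def test_risk_span_must_fit_chromosome(self):
        with pytest.raises(ConfigError):
            _tiny(risk_haplotype_span=(30, 45))

    def test_breed_divergence_bounds(self):
        with pytest.raises(ConfigError):
            _tiny(breed_divergence_f=1.0)

    def test_single_founder_rejected(self):
        with pytest.raises(ConfigError):
            _tiny(n_founders=1)


class TestPedigree:
    def test_two_founders_one_generation_gives_full_sibs(self):
        ped = simulate_pedigree(_tiny(n_founders=2, n_generations=1))
        offspring = [i for i in range(len(ped)) if ped.sire[i] is not None]
        sires = {ped.sire[i] for i in offspring}
        dams = {ped.dam[i] for i in offspring}
        assert sires == {"F000"} and dams == {"F001"}

    def test_same_seed_reproduces_pedigree(self):
        a = simulate_pedigree(_tiny(seed=5))
        b = simulate_pedigree(_tiny(seed=5))
        assert a.ids == b.ids and a.sire == b.sire and a.dam == b.dam

    def test_parents_precede_offspring_topologically(self):
        # oracle: explicit topological check over the parent DAG
        ped = simulate_pedigree(_tiny(n_founders=10, n_generations=3))
        position = {pid: i for i, pid in enumerate(ped.ids)}
        for i, pid in enumerate(ped.ids):
            for parent in (ped.sire[i], ped.dam[i]):
                if parent is not None:
                    assert position[parent] < i

    def test_shared_ancestor_exists(self):
        ped = simulate_pedigree(_tiny())
        kids = ped.children_of()
        assert any(len(v) >= 2 for v in kids.values())


class TestGeneDrop:
    def test_mendelian_consistency_everywhere(self, small_bundle):
        gm = small_bundle.genotypes
        ped = small_bundle.pedigree
        h1, h2 = gm.haplotypes
        idx = {p: i for i, p in enumerate(ped.ids)}
        errors = 0
        for i, pid in enumerate(ped.ids):
            s, d = ped.sire[i], ped.dam[i]
            if s is None:
                continue
            si, di = idx[s], idx[d]
            # each transmitted haplotype must be drawable from the parent pair
            for hap, pi in ((h1[i], si), (h2[i], di)):
                ok = (hap == h1[pi]) | (hap == h2[pi])
                errors += int(not ok.all())
        assert errors == 0

    def test_doses_equal_haplotype_sums(self, small_bundle):
        gm = small_bundle.genotypes
        h1, h2 = gm.haplotypes
        assert np.array_equal(gm.doses, (h1 + h2).astype(gm.doses.dtype))

    def test_homozygous_parents_force_offspring_dose(self):
        cfg = _tiny(seed=3)
        ped = simulate_pedigree(cfg)
        gm = gene_drop(ped, cfg)
        idx = {p: i for i, p in enumerate(ped.ids)}
        checked = 0
        for i in range(len(ped.ids)):
            s, d = ped.sire[i], ped.dam[i]
            if s is None:
                continue
            both0 = (gm.doses[idx[s]] == 0) & (gm.doses[idx[d]] == 0)
            both2 = (gm.doses[idx[s]] == 2) & (gm.doses[idx[d]] == 2)
            assert np.all(gm.doses[i][both0] == 0)
            assert np.all(gm.doses[i][both2] == 2)
            checked += both0.sum() + both2.sum()
        assert checked > 0

    def test_seed_determinism_bytes(self):
        cfg = _tiny(seed=9)
        a = gene_drop(simulate_pedigree(cfg), cfg)
        b = gene_drop(simulate_pedigree(cfg), cfg)
        assert a.doses.tobytes() == b.doses.tobytes()
        assert a.snp_table.equals(b.snp_table)

    def test_unknown_parent_raises(self):
        cfg = _tiny()
        ped = simulate_pedigree(cfg)
        ped.sire[-1] = "NOBODY"
        ped._index.pop("NOBODY", None)
        from lymphmap.core import InputError

        with pytest.raises(InputError, match="unknown"):
            gene_drop(ped, cfg)

    def test_founder_frequencies_recovered_in_cohort(self):
        # frequency-recovery: founder pool vs whole-cohort frequencies agree
        # within drift + binomial error at n ~ 500
        cfg = _tiny(n_founders=250, n_generations=1, n_offspring_per_generation=250, seed=2)
        b = simulate_cohort(cfg, with_reference=False)
        founders = [i for i, s in enumerate(b.pedigree.sire) if s is None]
        f_freq = b.genotypes.subset_samples(np.array(founders)).allele_freqs()
        c_freq = b.genotypes.allele_freqs()
        assert np.nanmean(np.abs(f_freq - c_freq)) < 0.03
        assert np.nanquantile(np.abs(f_freq - c_freq), 0.95) < 0.08

    def test_missing_rate_masks_doses(self):
        cfg = _tiny(missing_rate=0.1, seed=4)
        b = simulate_cohort(cfg, with_reference=False)
        frac = np.mean(b.genotypes.doses == MISSING)
        assert 0.05 < frac < 0.15


class TestPhenotypes:
    def test_degenerate_penetrance_marks_exact_homozygotes(self):
        cfg = _tiny(
            baseline_penetrance_f0=0.0,
            heterozygote_penetrance_f1=0.0,
            homozygote_penetrance_f2=1.0,
        )
        b = simulate_cohort(cfg, with_reference=False)
        rg = risk_genotype(b.genotypes, cfg)
        assert np.array_equal(b.phenotypes["status"] == "case", rg == 2)

    def test_flat_penetrance_breaks_association(self):
        # with f0 = f1 = f2 the 2x3 genotype/status table is null
        passes = 0
        for seed in range(5):
            cfg = _tiny(
                seed=seed,
                n_founders=60, n_generations=1, n_offspring_per_generation=140,
                baseline_penetrance_f0=0.3,
                heterozygote_penetrance_f1=0.3,
                homozygote_penetrance_f2=0.3,
            )
            b = simulate_cohort(cfg, with_reference=False)
            rg = risk_genotype(b.genotypes, cfg)
            tab = pd.crosstab(rg, b.phenotypes["status"])
            if tab.shape[0] < 2:
                passes += 1
                continue
            p = stats.chi2_contingency(tab)[1]
            passes += p > 0.01
        assert passes >= 4

    def test_case_fraction_calibrated_to_cohort(self):
        from lymphmap.studies import DEFAULT_CASE_TARGET, case_fraction

        fr = case_fraction(n_reps=10, seed=0)
        assert abs(fr.mean() - DEFAULT_CASE_TARGET) <= 0.05

    def test_case_ages_truncated(self, small_bundle):
        phe = small_bundle.phenotypes
        cases = phe[phe["status"] == "case"]
        assert ((cases["age_years"] > 0) & (cases["age_years"] <= 14)).all()
        ctrl = phe[phe["status"] == "control"]
        assert ((ctrl["age_years"] >= 7) & (ctrl["age_years"] <= 12)).all()


class TestReferencePanel:
    def test_f_near_zero_keeps_ancestral_frequencies(self):
        cfg = _tiny(breed_divergence_f=1e-4, n_ref_breeds=4, n_ref_per_breed=50)
        p = np.full(200, 0.3)
        panel = simulate_reference_panel(p, cfg)
        assert abs(panel.allele_freqs().mean() - 0.3) < 0.02

    def test_fixed_ancestral_allele_stays_fixed(self):
        cfg = _tiny()
        panel = simulate_reference_panel(np.zeros(50), cfg)
        assert np.all(panel.doses == 0)

    def test_breed_labels_and_size(self):
        cfg = _tiny(n_ref_breeds=5, n_ref_per_breed=7)
        panel = simulate_reference_panel(np.full(30, 0.4), cfg)
        assert panel.n_samples == 35
        assert panel.sample_meta["breed"].nunique() == 5

    def test_divergence_increases_fst_between_breeds(self):
        # monotonicity: mean Weir-Cockerham theta grows with F
        means = []
        for F in (0.02, 0.30):
            cfg = _tiny(breed_divergence_f=F, n_ref_breeds=2, n_ref_per_breed=60, seed=8)
            panel = simulate_reference_panel(np.full(400, 0.5), cfg)
            b0 = panel.sample_meta["breed"] == "breed00"
            theta = fst_per_snp(
                panel.subset_samples(b0.to_numpy()),
                panel.subset_samples((~b0).to_numpy()),
            )
            means.append(np.nanmean(theta))
        assert means[1] > means[0] + 0.05
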