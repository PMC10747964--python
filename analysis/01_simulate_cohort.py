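#!/usr/bin/env python
"""Simulate the study cohort: multi-generation pedigree, 38 autosomes of
block-LD genotypes with a planted recessive risk haplotype on chromosome
13, penetrance-model phenotypes, and a 26-breed low-risk reference panel.

Writes PED/MAP, phased haplotypes, pedigree and phenotype tables under
results/cohort/ and prints the realized cohort composition.
"""

from pathlib import Path

import numpy as np

from lymphmap import formats, kinship
from lymphmap.sim import SimConfig, simulate_cohort, risk_genotype, write_run_manifest

OUT = Path("results/cohort")
OUT.mkdir(parents=True, exist_ok=True)

cfg = SimConfig(seed=1)
bundle = simulate_cohort(cfg)
gm, phe, ped = bundle.genotypes, bundle.phenotypes, bundle.pedigree

formats.write_ped_map(OUT / "cohort.ped", OUT / "cohort.map", gm, phe, ped)
formats.write_haplotypes(OUT / "cohort.haps", gm)
formats.write_phenotypes(OUT / "phenotypes.tsv", phe)
kinship.write_pedigree(OUT / "pedigree.tsv", ped)
formats.write_ped_map(OUT / "panel.ped", OUT / "panel.map", bundle.reference)
formats.write_haplotypes(OUT / "panel.haps", bundle.reference)
write_run_manifest(OUT / "manifest.json", cfg, {"dir": str(OUT)})

n_cases = int((phe["status"] == "case").sum())
rg = risk_genotype(gm, cfg)
print(f"cohort: {gm.n_samples} dogs, {gm.n_snps} SNPs on {cfg.n_chromosomes} autosomes")
print(f"cases: {n_cases} ({100 * n_cases / gm.n_samples:.1f}%)")
print(f"risk-haplotype copies 0/1/2: {np.bincount(rg, minlength=3).tolist()}")
print(f"reference panel: {bundle.reference.n_samples} dogs, "
      f"{bundle.reference.sample_meta['breed'].nunique()} breeds")
print(f"mean case age {phe.loc[phe.status == 'case', 'age_years'].mean():.1f} y")
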