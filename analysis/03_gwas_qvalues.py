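#!/usr/bin/env python
"""Mixed-linear-model association scans of the simulated cohort: the full
cohort, then the young-onset design (cases diagnosed at 6 years or less vs
controls above 7 years), with genome-wide and chromosome-wise Storey
q-values.

Reads results/cohort/, writes association tables under results/gwas/.
"""

from pathlib import Path

from lymphmap import formats, gwas, qvalue

IN = Path("results/cohort")
OUT = Path("results/gwas")
OUT.mkdir(parents=True, exist_ok=True)

gm, _ = formats.read_ped_map(IN / "cohort.ped", IN / "cohort.map")
phe = formats.read_phenotypes(IN / "phenotypes.tsv")

for label, phen in (
    ("full", phe),
    ("young_onset", gwas.subset_young_onset(phe)),
):
    n_case = int((phen["status"] == "case").sum())
    assoc = gwas.gwas_pipeline(gm, phen, maf=0.02)
    assoc = qvalue.add_qvalues(assoc)
    assoc.to_csv(OUT / f"assoc_{label}.tsv", sep="\t", index=False)
    top = assoc.nsmallest(3, "p")
    print(f"[{label}] {n_case} cases / {len(phen) - n_case} controls, "
          f"{len(assoc)} SNPs, pi0 = {assoc.attrs['pi0_genome']:.2f}")
    for _, r in top.iterrows():
        print(f"  chr{r.chrom}:{int(r.pos):,}  p={r.p:.2e}  q_gw={r.q_genome:.3f}  "
              f"q_chr={r.q_chrom:.3f}")
    n_sig = int((assoc["q_chrom"] < 0.01).sum())
    print(f"  {n_sig} SNPs at chromosome-wise q < 0.01")
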