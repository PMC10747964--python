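#!/usr/bin/env python
"""Fine-scale look at the associated region: sliding-window haplotype
frequencies (2-8 SNP windows) by cohort, Gabriel-style LD blocks, runs of
homozygosity, and the case/control homozygosity 2x2 Fisher test at the top
SNPs.

Reads results/cohort/, writes tables under results/haplo/.
"""

from pathlib import Path

import pandas as pd

from lymphmap import formats, haplo
from lymphmap.sim import SimConfig

IN = Path("results/cohort")
OUT = Path("results/haplo")
OUT.mkdir(parents=True, exist_ok=True)

cfg = SimConfig(seed=1)  # same configuration as 01_simulate_cohort
gm, _ = formats.read_ped_map(IN / "cohort.ped", IN / "cohort.map")
gm = formats.read_haplotypes(IN / "cohort.haps", gm)
phe = formats.read_phenotypes(IN / "phenotypes.tsv")
cohorts = dict(zip(phe["sample_id"], phe["status"]))

lo, hi = cfg.risk_haplotype_span
off = (cfg.risk_chromosome - 1) * cfg.snps_per_chromosome
region = (off + lo, off + hi)

rows = []
for start, width in haplo.sliding_windows(hi - lo + 1):
    win = haplo.window_haplotype_freqs(gm, (region[0] + start, width), cohorts)
    for cohort, tally in win.counts.items():
        for hap, count in tally.items():
            rows.append({"start": win.start, "width": width, "cohort": cohort,
                         "haplotype": hap, "count": count})
pd.DataFrame(rows).to_csv(OUT / "window_haplotypes.tsv", sep="\t", index=False)

widest = [r for r in rows if r["width"] == 8 and r["start"] == region[0] and r["cohort"] == "case"]
top = max(widest, key=lambda r: r["count"])
print(f"most frequent case haplotype over the first 8-SNP window of the risk span: "
      f"{top['haplotype']} ({top['count']:.0f} of {2 * (phe.status == 'case').sum()} chromosomes)")

blocks = haplo.haplotype_blocks(gm, region)
pd.DataFrame(blocks, columns=["start_snp", "end_snp"]).to_csv(
    OUT / "blocks.tsv", sep="\t", index=False)
print(f"LD blocks in the region: {blocks}")

roh = haplo.roh_in_region(gm, region, min_run_snps=3)
n_runs = {s: len(r) for s, r in roh.items()}
case_mean = pd.Series({s: n_runs[s] for s in phe.loc[phe.status == 'case', 'sample_id']}).mean()
ctrl_mean = pd.Series({s: n_runs[s] for s in phe.loc[phe.status == 'control', 'sample_id']}).mean()
print(f"mean homozygous runs (>=3 SNPs) per dog: cases {case_mean:.2f}, controls {ctrl_mean:.2f}")

test = haplo.homozygosity_test(gm, list(range(region[0], region[0] + 3)), phe)
pd.DataFrame([test.__dict__]).to_csv(OUT / "homozygosity_test.tsv", sep="\t", index=False)
print(f"homozygosity at the top 3 SNPs: cases {test.case_hom}/{test.case_hom + test.case_not} "
      f"({100 * test.case_fraction:.0f}%), controls {test.control_hom}/"
      f"{test.control_hom + test.control_not} ({100 * test.control_fraction:.0f}%), "
      f"Fisher p = {test.p_value:.4g}")
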