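"""End-to-end orchestration: simulate -> kinship -> network -> gwas ->
qvalue -> css -> haplo -> variants, with a run manifest.

Stages communicate only through declared files; every parameter, every
derived seed and a content hash of every output land in the manifest, so a
rerun with the same configuration reproduces identical hashes for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import css as css_mod
from . import formats, gwas, haplo, kinship, network, qvalue, sim, variants
from .core import ConfigError, InputError

logger = logging.getLogger(__name__)

ALL_STAGES = ["simulate", "kinship", "network", "gwas", "qvalue", "css", "haplo", "variants"]


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    sim: dict = field(default_factory=dict)
    maf: float = 0.02
    young_onset: bool = False
    knn_k: int = 10
    css_window_bp: int = 1_000_000
    css_quantile: float = 0.995
    q_thresholds: tuple[float, float] = (0.01, 0.05)
    haplo_widths: tuple[int, int] = (2, 8)
    roh_min_snps: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }
    bundle = None

    def record(stage: str, paths: dict[str, Path]) -> None:
        manifest["stages"][stage] = "ok"
        for name, p in paths.items():
            manifest["outputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    try:
        sim_cfg = sim.SimConfig(seed=config.seed, **config.sim)
        bundle = sim.simulate_cohort(sim_cfg)

        if "simulate" in config.stages:
            ped_p, map_p = out / "cohort.ped", out / "cohort.map"
            formats.write_ped_map(ped_p, map_p, bundle.genotypes, bundle.phenotypes, bundle.pedigree)
            hap_p = out / "cohort.haps"
            formats.write_haplotypes(hap_p, bundle.genotypes)
            phe_p = out / "phenotypes.tsv"
            formats.write_phenotypes(phe_p, bundle.phenotypes)
            ped_tsv = out / "pedigree.tsv"
            kinship.write_pedigree(ped_tsv, bundle.pedigree)
            man_p = out / "simulate_manifest.json"
            sim.write_run_manifest(man_p, sim_cfg, {"ped": ped_p.name, "map": map_p.name})
            record("simulate", {"ped": ped_p, "map": map_p, "haps": hap_p,
                                "phenotypes": phe_p, "pedigree": ped_tsv, "sim_manifest": man_p})

        if "kinship" in config.stages:
            phi = kinship.kinship_matrix(bundle.pedigree)
            kin_p = out / "kinship.tsv"
            kinship.write_matrix(kin_p, phi)
            record("kinship", {"kinship": kin_p})

        if "network" in config.stages:
            dist = network.ibs_distance(bundle.genotypes)
            status = dict(zip(bundle.phenotypes["sample_id"], bundle.phenotypes["status"]))
            g = network.mutual_knn_network(dist, k=config.knn_k, status=status)
            e_p, n_p = out / "network_edges.tsv", out / "network_nodes.tsv"
            network.write_network(e_p, n_p, g)
            record("network", {"edges": e_p, "nodes": n_p})

        assoc = None
        if "gwas" in config.stages:
            phen = bundle.phenotypes
            if config.young_onset:
                phen = gwas.subset_young_onset(phen)
            assoc = gwas.gwas_pipeline(bundle.genotypes, phen, maf=config.maf)
            assoc_p = out / "assoc.tsv"
            assoc.to_csv(assoc_p, sep="\t", index=False)
            record("gwas", {"assoc": assoc_p})

        if "qvalue" in config.stages:
            if assoc is None:
                raise ConfigError("qvalue stage requires the gwas stage")
            assoc = qvalue.add_qvalues(assoc)
            assoc_q_p = out / "assoc_qvalues.tsv"
            assoc.to_csv(assoc_q_p, sep="\t", index=False)
            manh = assoc[["chrom", "pos", "p"]].copy()
            offsets = {}
            running = 0
            for c, grp in assoc.groupby("chrom", sort=False):
                offsets[c] = running
                running += int(grp["pos"].max()) + 1
            manh["cum_pos"] = [offsets[c] + p for c, p in zip(assoc["chrom"], assoc["pos"])]
            manh["neglog10p"] = -np.log10(manh["p"])
            manh_p = out / "manhattan.tsv"
            manh.to_csv(manh_p, sep="\t", index=False)
            record("qvalue", {"assoc_qvalues": assoc_q_p, "manhattan": manh_p})

        if "css" in config.stages:
            cases = bundle.phenotypes.loc[bundle.phenotypes["status"] == "case", "sample_id"]
            target = bundle.genotypes.subset_samples(
                np.array([bundle.genotypes.by_sample_index(s) for s in cases])
            )
            table, regions, threshold = css_mod.css_scan(
                target, bundle.reference,
                window_bp=config.css_window_bp, quantile=config.css_quantile,
            )
            css_p = out / "css.tsv"
            table.to_csv(css_p, sep="\t", index=False)
            reg_p = out / "css_regions.tsv"
            pd.DataFrame(
                [
                    {
                        "chrom": r.chromosome, "start_bp": r.start_bp, "end_bp": r.end_bp,
                        "n_snps": len(r.snp_indices), "regional_avg_css": r.regional_average,
                    }
                    for r in regions
                ]
            ).to_csv(reg_p, sep="\t", index=False)
            record("css", {"css": css_p, "css_regions": reg_p})

        if "haplo" in config.stages:
            scfg = bundle.config
            lo, hi = scfg.risk_haplotype_span
            off = (scfg.risk_chromosome - 1) * scfg.snps_per_chromosome
            region = (off + lo, off + hi)
            cohorts = dict(zip(bundle.phenotypes["sample_id"], bundle.phenotypes["status"]))
            rows = []
            for start, width in haplo.sliding_windows(hi - lo + 1, *config.haplo_widths):
                win = haplo.window_haplotype_freqs(bundle.genotypes, (region[0] + start, width), cohorts)
                for cohort, tally in win.counts.items():
                    for hap, count in tally.items():
                        rows.append(
                            {"start": win.start, "width": width, "cohort": cohort,
                             "haplotype": hap, "count": count}
                        )
            hapfreq_p = out / "window_haplotypes.tsv"
            pd.DataFrame(rows).to_csv(hapfreq_p, sep="\t", index=False)
            blocks = haplo.haplotype_blocks(bundle.genotypes, region)
            blocks_p = out / "haplotype_blocks.tsv"
            pd.DataFrame(blocks, columns=["start_snp", "end_snp"]).to_csv(blocks_p, sep="\t", index=False)
            roh = haplo.roh_in_region(bundle.genotypes, region, min_run_snps=config.roh_min_snps)
            roh_p = out / "roh.tsv"
            pd.DataFrame(
                [
                    {"sample_id": s, "start_snp": a, "end_snp": b}
                    for s, runs in roh.items() for a, b in runs
                ]
            ).to_csv(roh_p, sep="\t", index=False)
            test = haplo.homozygosity_test(
                bundle.genotypes, list(range(region[0], region[0] + 3)), bundle.phenotypes
            )
            test_p = out / "homozygosity_test.tsv"
            pd.DataFrame(
                [
                    {
                        "case_hom": test.case_hom, "case_not": test.case_not,
                        "control_hom": test.control_hom, "control_not": test.control_not,
                        "odds_ratio": test.odds_ratio, "fisher_p": test.p_value,
                    }
                ]
            ).to_csv(test_p, sep="\t", index=False)
            record("haplo", {"window_haplotypes": hapfreq_p, "blocks": blocks_p,
                             "roh": roh_p, "homozygosity_test": test_p})

        if "variants" in config.stages:
            recs = formats.load_table1()
            trio = [
                (r, variants.TrioGenotypes("hom-alt", "het", "hom-ref")) for r in recs
            ]
            retained, n_missing = variants.recessive_filter(trio)
            fine = variants.region_filter(retained, "13", 25_200_000, 26_400_000)
            var_p = out / "variants_retained.tsv"
            formats.write_variant_table(var_p, retained)
            fine_p = out / "variants_fine_region.tsv"
            formats.write_variant_table(fine_p, fine)
            record("variants", {"variants_retained": var_p, "variants_fine_region": fine_p})

    except Exception as exc:
        stage = next((s for s in ALL_STAGES if s not in manifest["stages"] and s in config.stages), "?")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        raise

    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
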