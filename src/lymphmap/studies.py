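"""Replicate simulation studies used to validate the pipeline.

Each function runs a self-contained simulation experiment at desk scale
and returns summary numbers; the test suite asserts on them and the
analysis scripts report them.  All randomness is derived from the caller's
seed.

Two cohort designs recur:

* the *default* cohort — the cohort-emulating :class:`~lymphmap.sim.SimConfig`
  defaults (multi-generation pedigree, LD blocks, planted recessive
  haplotype);
* a *null calibration* cohort — founder-dominated and LD-free
  (``block_size_snps=1``), so the per-SNP p-values are approximately
  independent draws and distributional checks (Kolmogorov–Smirnov) are
  meaningful.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from . import gwas
from .css import composite_css, css_scan
from .sim import SimConfig, simulate_cohort

DEFAULT_CASE_TARGET = 49 / 330  # cohort case fraction the defaults emulate


def _null_config(seed: int, n_chromosomes: int = 4, snps_per_chromosome: int = 500) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_chromosomes=n_chromosomes,
        snps_per_chromosome=snps_per_chromosome,
        block_size_snps=1,
        risk_chromosome=min(2, n_chromosomes),
        risk_haplotype_span=(snps_per_chromosome // 2, snps_per_chromosome // 2 + 9),
        n_founders=150,
        n_generations=1,
        n_offspring_per_generation=50,
    )


def case_fraction(n_reps: int = 10, seed: int = 0) -> np.ndarray:
    """Realized case fractions of the default cohort across seeds."""
    out = []
    for rep in range(n_reps):
        b = simulate_cohort(SimConfig(seed=seed + rep), with_reference=False)
        out.append(float((b.phenotypes["status"] == "case").mean()))
    return np.array(out)


def planted_locus_recovery(n_reps: int = 20, seed: int = 0) -> float:
    """Fraction of replicates whose top mixed-model SNP falls within the
    planted risk span +- 250 kb on the risk chromosome (default cohort)."""
    hits = 0
    for rep in range(n_reps):
        b = simulate_cohort(SimConfig(seed=seed + rep), with_reference=False)
        assoc = gwas.gwas_pipeline(b.genotypes, b.phenotypes)
        top = assoc.loc[assoc["p"].idxmin()]
        cfg = b.config
        lo, hi = cfg.risk_haplotype_span
        span_pos = (
            b.genotypes.snp_table.query("chrom == @cfg.risk_chromosome")["pos"]
            .to_numpy()[lo : hi + 1]
        )
        if (
            str(top["chrom"]) == str(cfg.risk_chromosome)
            and span_pos[0] - 250_000 <= top["pos"] <= span_pos[-1] + 250_000
        ):
            hits += 1
    return hits / n_reps


def mlma_null_uniformity(n_reps: int = 20, seed: int = 0) -> np.ndarray:
    """KS p-values of the MLMA p-value distribution under the null.

    A Gaussian phenotype independent of the genotypes is scanned over the
    LD-free calibration cohort; under the null the per-SNP p-values are
    uniform, so the KS statistic against U(0,1) should be unremarkable.
    """
    ks = []
    for rep in range(n_reps):
        b = simulate_cohort(_null_config(seed + rep), with_reference=False)
        gm = gwas.filter_maf(b.genotypes)
        y = np.random.default_rng(seed + 1000 + rep).normal(size=gm.n_samples)
        grm = gwas.compute_grm(gm)
        vc = gwas.reml_null(y, grm)
        assoc = gwas.mlma_scan(gm, y, grm, vc)
        p = assoc["p"].dropna().to_numpy()
        ks.append(stats.kstest(p, "uniform").pvalue)
    return np.array(ks)


def mlma_type1_error(n_reps: int = 20, seed: int = 0) -> tuple[float, float]:
    """(pooled rejection rate at 0.05, median null heritability estimate).

    The case/control labels are permuted so the binary trait keeps its
    prevalence but loses any genotype association; 10,000 SNPs and 200
    samples per replicate.
    """
    rates = []
    h2s = []
    for rep in range(n_reps):
        b = simulate_cohort(
            _null_config(seed + rep, n_chromosomes=10, snps_per_chromosome=1000),
            with_reference=False,
        )
        gm = gwas.filter_maf(b.genotypes)
        rng = np.random.default_rng(seed + 2000 + rep)
        y = rng.permutation((b.phenotypes["status"] == "case").to_numpy(float))
        grm = gwas.compute_grm(gm)
        vc = gwas.reml_null(y, grm)
        h2s.append(vc.h2)
        assoc = gwas.mlma_scan(gm, y, grm, vc)
        p = assoc["p"].dropna().to_numpy()
        rates.append(float(np.mean(p < 0.05)))
    return float(np.mean(rates)), float(np.median(h2s))


def css_combiner_null_uniformity(n_reps: int = 20, seed: int = 0, n_snps: int = 2000) -> np.ndarray:
    """KS p-values of composite-CSS p-values under exchangeable null
    components (three independent Gaussian statistics per SNP)."""
    ks = []
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        comp = rng.normal(size=(n_snps, 3))
        table = composite_css(comp)
        ks.append(stats.kstest(table["p"].to_numpy(), "uniform").pvalue)
    return np.array(ks)


def _sweep_pair(seed: int, n_chromosomes: int = 4, snps_per_chromosome: int = 240):
    """Target cohort carrying a near-fixed sweep haplotype and a reference
    cohort from the same founder block pool without the sweep."""
    common = dict(
        n_chromosomes=n_chromosomes,
        snps_per_chromosome=snps_per_chromosome,
        risk_chromosome=min(3, n_chromosomes),
        risk_haplotype_span=(snps_per_chromosome // 2, snps_per_chromosome // 2 + 9),
        n_founders=30,
        n_generations=1,
        n_offspring_per_generation=50,
        seed=seed,
    )
    target_cfg = SimConfig(risk_block_freqs=(0.91, 0.03, 0.03, 0.03), **common)
    ref_cfg = SimConfig(risk_block_freqs=(0.25, 0.25, 0.25, 0.25), **common)
    target = simulate_cohort(target_cfg, with_reference=False)
    reference = simulate_cohort(ref_cfg, with_reference=False)
    return target, reference


def css_sweep_recovery(n_reps: int = 20, seed: int = 0) -> float:
    """Fraction of replicates in which at least one SNP of the swept span
    reaches the top-0.5% of smoothed CSS."""
    hits = 0
    for rep in range(n_reps):
        target, reference = _sweep_pair(seed + rep)
        table, regions, _ = css_scan(target.genotypes, reference.genotypes)
        cfg = target.config
        lo, hi = cfg.risk_haplotype_span
        off = (cfg.risk_chromosome - 1) * cfg.snps_per_chromosome
        span = table.index[(table.index >= off + lo) & (table.index <= off + hi)]
        if table.loc[span, "significant"].any():
            hits += 1
    return hits / n_reps


def css_top_fraction(seed: int = 0, n_chromosomes: int = 10, snps_per_chromosome: int = 1000) -> tuple[float, int]:
    """(fraction of SNPs strictly above the 99.5% smoothed-CSS threshold,
    number of SNPs scanned) for one default-parameter cohort-vs-panel run."""
    cfg = SimConfig(
        seed=seed,
        n_chromosomes=n_chromosomes,
        snps_per_chromosome=snps_per_chromosome,
        risk_chromosome=min(5, n_chromosomes),
        risk_haplotype_span=(snps_per_chromosome // 2, snps_per_chromosome // 2 + 9),
    )
    b = simulate_cohort(cfg)
    cases = b.phenotypes.loc[b.phenotypes["status"] == "case", "sample_id"]
    target = b.genotypes.subset_samples(
        np.array([b.genotypes.by_sample_index(s) for s in cases])
    )
    table, _, threshold = css_scan(target, b.reference)
    smoothed = table["smoothed"].to_numpy()
    valid = np.isfinite(smoothed)
    frac = float(np.mean(smoothed[valid] > threshold))
    return frac, int(valid.sum())
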