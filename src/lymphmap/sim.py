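"""Synthetic cohort generator: pedigree, LD-structured genotypes with a
planted recessive risk haplotype, phenotypes, and a multi-breed low-risk
reference panel.

The generator emulates a pure-breed case/control cohort of ~330 dogs with
~15% lymphoma cases, a multi-generation pedigree with shared ancestors, 38
autosomes of SNPs arranged in LD blocks, a recessive risk haplotype on one
chromosome, and a 26-breed reference panel of ~494 dogs for the selection
contrast.  Everything is driven by a single integer seed, so a fixed seed
reproduces the whole bundle byte-for-byte.

Founder linkage disequilibrium follows a haplotype-block model: within each
block of ``block_size_snps`` SNPs, founder haplotypes are drawn from four
block haplotypes whose frequencies come from a Dirichlet(1,1,1,1); blocks
are independent.  On the risk chromosome one block carries the planted risk
haplotype at a controlled frequency, and that haplotype is given private
marker alleles at two SNPs — the analogue of the tag SNPs by which real
fine-mapped risk haplotypes are recognised.

Meiosis places exactly one crossover per chromosome at a uniform physical
position; no genetic map is modelled.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, ConfigError, GenotypeMatrix, InputError, make_phenotype_table
from .kinship import Pedigree

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort, with cohort-emulating defaults.

    Penetrances are P(case | 0/1/2 copies of the planted risk haplotype);
    defaults realise a predominantly recessive disease with a ~15% case
    fraction at the default planted-haplotype frequency.
    """

    n_founders: int = 30
    n_generations: int = 4
    n_offspring_per_generation: int = 75
    n_chromosomes: int = 38
    snps_per_chromosome: int = 150
    chromosome_length_bp: int = 60_000_000
    block_size_snps: int = 10
    risk_chromosome: int = 13
    risk_haplotype_span: tuple[int, int] = (70, 79)  # inclusive SNP indices within chromosome
    risk_block_freqs: tuple[float, ...] = (0.40, 0.20, 0.20, 0.20)
    baseline_penetrance_f0: float = 0.04
    heterozygote_penetrance_f1: float = 0.12
    homozygote_penetrance_f2: float = 0.75
    case_age_mean: float = 5.7
    case_age_sd: float = 2.0
    control_age_low: float = 7.0
    control_age_high: float = 12.0
    breed_divergence_f: float = 0.10
    n_ref_breeds: int = 26
    n_ref_per_breed: int = 19
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_founders": self.n_founders,
            "n_generations": self.n_generations,
            "n_offspring_per_generation": self.n_offspring_per_generation,
            "n_chromosomes": self.n_chromosomes,
            "snps_per_chromosome": self.snps_per_chromosome,
            "chromosome_length_bp": self.chromosome_length_bp,
            "block_size_snps": self.block_size_snps,
            "n_ref_breeds": self.n_ref_breeds,
            "n_ref_per_breed": self.n_ref_per_breed,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.n_founders < 2:
            raise ConfigError("need at least 2 founders to mate")
        f0, f1, f2 = (
            self.baseline_penetrance_f0,
            self.heterozygote_penetrance_f1,
            self.homozygote_penetrance_f2,
        )
        if not (0 <= f0 <= f1 <= f2 <= 1):
            raise ConfigError(f"penetrances must satisfy 0 <= f0 <= f1 <= f2 <= 1, got {f0}, {f1}, {f2}")
        if not (0 < self.breed_divergence_f < 1):
            raise ConfigError(f"breed_divergence_f must lie in (0,1), got {self.breed_divergence_f}")
        lo, hi = self.risk_haplotype_span
        if not (0 <= lo <= hi < self.snps_per_chromosome):
            raise ConfigError(f"risk span {self.risk_haplotype_span} outside chromosome of {self.snps_per_chromosome} SNPs")
        if not (1 <= self.risk_chromosome <= self.n_chromosomes):
            raise ConfigError(f"risk_chromosome {self.risk_chromosome} outside 1..{self.n_chromosomes}")
        if abs(sum(self.risk_block_freqs) - 1.0) > 1e-9:
            raise ConfigError("risk_block_freqs must sum to 1")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must lie in [0,1)")

    def rng(self, label: str) -> np.random.Generator:
        """Independent stream per stage, derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{label}".encode()).digest()
        return np.random.default_rng(int.from_bytes(h[:4], "big"))


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Multi-generation pedigree with full-sib litters and shared ancestors.

    Founders form generation 0 with alternating sexes; each later generation
    draws a small number of mating pairs (sire from earlier males, dam from
    earlier females) and distributes its offspring among them, which
    concentrates lineages on a few ancestors the way registry pedigrees do.
    """
    rng = config.rng("pedigree")
    ids: list[str] = []
    sires: list[str | None] = []
    dams: list[str | None] = []
    sexes: list[int] = []  # 1 male, 2 female
    generation: list[int] = []

    for i in range(config.n_founders):
        ids.append(f"F{i:03d}")
        sires.append(None)
        dams.append(None)
        sexes.append(1 if i % 2 == 0 else 2)
        generation.append(0)
    if 1 not in sexes or 2 not in sexes:
        raise ConfigError("founders must include both sexes")

    for g in range(1, config.n_generations + 1):
        males = [ids[i] for i in range(len(ids)) if sexes[i] == 1 and generation[i] < g]
        females = [ids[i] for i in range(len(ids)) if sexes[i] == 2 and generation[i] < g]
        n_off = config.n_offspring_per_generation
        n_pairs = max(2, min(n_off // 4, len(males), len(females)))
        pair_sires = rng.choice(males, size=n_pairs, replace=len(males) < n_pairs)
        pair_dams = rng.choice(females, size=n_pairs, replace=len(females) < n_pairs)
        assignment = rng.integers(0, n_pairs, size=n_off)
        for j in range(n_off):
            k = assignment[j]
            ids.append(f"G{g}_{j:03d}")
            sires.append(str(pair_sires[k]))
            dams.append(str(pair_dams[k]))
            sexes.append(int(rng.integers(1, 3)))
            generation.append(g)

    return Pedigree(
        ids=ids,
        sire=sires,
        dam=dams,
        sex=sexes,
        generation=generation,
    )


def _founder_haplotype_pool(config: SimConfig, rng: np.random.Generator):
    """Block haplotype patterns and frequencies for every chromosome.

    Returns (patterns, freqs, snp_table, risk_pattern).  ``patterns`` maps
    chromosome -> list of (block_slice, 4 x block_len allele array);
    ``freqs`` the matching Dirichlet frequencies.
    """
    n_snps = config.snps_per_chromosome
    spacing = config.chromosome_length_bp // (n_snps + 1)
    rows = []
    patterns: dict[int, list] = {}
    lo, hi = config.risk_haplotype_span
    for chrom in range(1, config.n_chromosomes + 1):
        allele_idx = rng.integers(0, 4, size=(n_snps, 2))
        # guarantee two distinct letters per SNP
        clash = allele_idx[:, 0] == allele_idx[:, 1]
        allele_idx[clash, 1] = (allele_idx[clash, 0] + 1 + rng.integers(0, 3, clash.sum())) % 4
        for i in range(n_snps):
            rows.append(
                {
                    "chrom": chrom,
                    "pos": spacing * (i + 1),
                    "snp_id": f"snp{chrom}_{i}",
                    "allele_a": BASES[allele_idx[i, 0]],
                    "allele_b": BASES[allele_idx[i, 1]],
                }
            )
        blocks = []
        for start in range(0, n_snps, config.block_size_snps):
            stop = min(start + config.block_size_snps, n_snps)
            haps = rng.integers(0, 2, size=(4, stop - start)).astype(np.uint8)
            freqs = rng.dirichlet(np.ones(4))
            if chrom == config.risk_chromosome and start <= hi and lo < stop:
                # a block overlapping the risk span: controlled frequencies,
                # and private marker alleles on the risk haplotype (index 0)
                # at the first and last span SNPs inside this block
                freqs = np.array(config.risk_block_freqs, dtype=float)
                for tag in (max(lo, start) - start, min(hi, stop - 1) - start):
                    haps[0, tag] = 1
                    haps[1:, tag] = 0
            blocks.append((slice(start, stop), haps, freqs))
        patterns[chrom] = blocks
    snp_table = pd.DataFrame(rows)
    # the planted risk haplotype = haplotype 0 of the overlapped block(s)
    risk_pattern = np.empty(hi - lo + 1, dtype=np.uint8)
    for block_slice, haps, _ in patterns[config.risk_chromosome]:
        s = max(lo, block_slice.start)
        e = min(hi, block_slice.stop - 1)
        if s <= e:
            risk_pattern[s - lo : e - lo + 1] = haps[0, s - block_slice.start : e - block_slice.start + 1]
    return patterns, snp_table, risk_pattern


def _draw_founder_haplotypes(patterns, config: SimConfig, rng: np.random.Generator, n_haps: int) -> np.ndarray:
    """Draw ``n_haps`` founder haplotypes at once (blocks independent)."""
    n_snps = config.snps_per_chromosome
    out = np.empty((n_haps, config.n_chromosomes * n_snps), dtype=np.uint8)
    for chrom in range(1, config.n_chromosomes + 1):
        off = (chrom - 1) * n_snps
        for block_slice, haps, freqs in patterns[chrom]:
            cum = np.cumsum(freqs)
            idx = np.searchsorted(cum, rng.random(n_haps), side="right").clip(0, 3)
            out[:, off + block_slice.start : off + block_slice.stop] = haps[idx]
    return out


def gene_drop(pedigree: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Drop founder haplotypes through the pedigree (phased output).

    Each meiosis takes exactly one crossover per chromosome at a uniform
    physical position, so every offspring haplotype is a two-segment mosaic
    of its parent's pair and Mendelian consistency is exact by construction.
    """
    rng = config.rng("genedrop")
    patterns, snp_table, risk_pattern = _founder_haplotype_pool(config, rng)
    n = len(pedigree.ids)
    m = len(snp_table)
    n_snps = config.snps_per_chromosome
    h1 = np.empty((n, m), dtype=np.uint8)
    h2 = np.empty((n, m), dtype=np.uint8)
    index = {pid: i for i, pid in enumerate(pedigree.ids)}

    pos_within = snp_table["pos"].to_numpy()[:n_snps].astype(float)

    def gamete(parent_idx: int) -> np.ndarray:
        out = np.empty(m, dtype=np.uint8)
        a, b = h1[parent_idx], h2[parent_idx]
        for chrom in range(config.n_chromosomes):
            off = chrom * n_snps
            cut_bp = rng.uniform(0, config.chromosome_length_bp)
            cut = int(np.searchsorted(pos_within, cut_bp))
            start = rng.integers(0, 2)
            src1, src2 = (a, b) if start == 0 else (b, a)
            out[off : off + cut] = src1[off : off + cut]
            out[off + cut : off + n_snps] = src2[off + cut : off + n_snps]
        return out

    # founder haplotypes (and founder-by-proxy gametes for unknown single
    # parents) are pre-drawn in pedigree order so the stream is deterministic
    n_founder_haps = sum(
        (s is None) + (d is None) for s, d in zip(pedigree.sire, pedigree.dam)
    )
    pool = _draw_founder_haplotypes(patterns, config, rng, n_founder_haps)
    pool_next = iter(range(n_founder_haps))

    for i, pid in enumerate(pedigree.ids):
        s, d = pedigree.sire[i], pedigree.dam[i]
        for parent, which in ((s, "sire"), (d, "dam")):
            if parent is not None and parent not in index:
                raise InputError(f"pedigree references unknown {which} {parent!r}")
            if parent is not None and index[parent] >= i:
                raise InputError(f"{which} {parent!r} appears after its offspring")
        h1[i] = gamete(index[s]) if s is not None else pool[next(pool_next)]
        h2[i] = gamete(index[d]) if d is not None else pool[next(pool_next)]

    doses = (h1.astype(np.int16) + h2.astype(np.int16)).astype(np.int64)
    if config.missing_rate > 0:
        mask = rng.random(doses.shape) < config.missing_rate
        doses = np.where(mask, MISSING, doses)
    gm = GenotypeMatrix(
        sample_ids=list(pedigree.ids),
        snp_table=snp_table,
        doses=doses,
        haplotypes=(h1, h2),
    )
    gm.risk_haplotype = risk_pattern  # planted allele pattern over the span
    return gm


def risk_genotype(genotypes: GenotypeMatrix, config: SimConfig) -> np.ndarray:
    """Copies (0/1/2) of the planted risk haplotype carried by each sample."""
    if not genotypes.phased:
        raise InputError("risk genotype requires phased haplotypes")
    pattern = getattr(genotypes, "risk_haplotype", None)
    if pattern is None:
        raise InputError("genotypes carry no planted risk haplotype")
    lo, hi = config.risk_haplotype_span
    off = (config.risk_chromosome - 1) * config.snps_per_chromosome
    span = slice(off + lo, off + hi + 1)
    h1, h2 = genotypes.haplotypes
    m1 = np.all(h1[:, span] == pattern, axis=1)
    m2 = np.all(h2[:, span] == pattern, axis=1)
    return m1.astype(int) + m2.astype(int)


def assign_phenotypes(genotypes: GenotypeMatrix, config: SimConfig) -> pd.DataFrame:
    """Penetrance-model phenotypes plus ages.

    Case probability is f0/f1/f2 by risk-haplotype copies; case ages come
    from a normal(case_age_mean, case_age_sd) truncated to (0, 14] and
    control ages from uniform(control_age_low, control_age_high).
    """
    rng = config.rng("phenotype")
    g = risk_genotype(genotypes, config)
    f = np.array(
        [
            config.baseline_penetrance_f0,
            config.heterozygote_penetrance_f1,
            config.homozygote_penetrance_f2,
        ]
    )
    is_case = rng.random(len(g)) < f[g]
    a = (0.0 - config.case_age_mean) / config.case_age_sd
    b = (14.0 - config.case_age_mean) / config.case_age_sd
    case_ages = stats.truncnorm.rvs(
        a, b, loc=config.case_age_mean, scale=config.case_age_sd,
        size=int(is_case.sum()), random_state=rng,
    )
    ages = rng.uniform(config.control_age_low, config.control_age_high, size=len(g))
    ages[is_case] = case_ages
    status = np.where(is_case, "case", "control")
    return make_phenotype_table(genotypes.sample_ids, status, ages)


def simulate_reference_panel(
    cohort_frequencies: np.ndarray,
    config: SimConfig,
    snp_table: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Multi-breed reference panel via the Balding–Nichols construction.

    Each breed's allele frequency at a SNP is Beta(p(1-F)/F, (1-p)(1-F)/F)
    around the ancestral frequency p; haplotype alleles are then independent
    Bernoulli draws, so genotypes are in Hardy–Weinberg proportions within
    each breed.  Breed labels are kept in ``sample_meta``.
    """
    rng = config.rng("refpanel")
    p = np.asarray(cohort_frequencies, dtype=float)
    F = config.breed_divergence_f
    m = len(p)
    n_total = config.n_ref_breeds * config.n_ref_per_breed
    h1 = np.empty((n_total, m), dtype=np.uint8)
    h2 = np.empty((n_total, m), dtype=np.uint8)
    breeds = []
    ids = []
    scale = (1.0 - F) / F
    poly = (p > 0) & (p < 1)
    row = 0
    for b in range(config.n_ref_breeds):
        pb = p.copy()
        pb[poly] = rng.beta(p[poly] * scale, (1 - p[poly]) * scale)
        for j in range(config.n_ref_per_breed):
            h1[row] = rng.random(m) < pb
            h2[row] = rng.random(m) < pb
            ids.append(f"REF_B{b:02d}_{j:02d}")
            breeds.append(f"breed{b:02d}")
            row += 1
    if snp_table is None:
        snp_table = pd.DataFrame(
            {
                "chrom": np.ones(m, dtype=int),
                "pos": np.arange(1, m + 1),
                "snp_id": [f"snp{i}" for i in range(m)],
                "allele_a": "A",
                "allele_b": "B",
            }
        )
    return GenotypeMatrix(
        sample_ids=ids,
        snp_table=snp_table.reset_index(drop=True),
        doses=(h1.astype(np.int16) + h2.astype(np.int16)).astype(np.int64),
        haplotypes=(h1, h2),
        sample_meta=pd.DataFrame({"sample_id": ids, "breed": breeds}),
    )


@dataclass
class SimBundle:
    """Everything one simulated study provides."""

    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    reference: GenotypeMatrix


def simulate_cohort(config: SimConfig | None = None, with_reference: bool = True) -> SimBundle:
    """One-call simulation of pedigree, genotypes, phenotypes and panel."""
    config = config or SimConfig()
    ped = simulate_pedigree(config)
    gm = gene_drop(ped, config)
    phe = assign_phenotypes(gm, config)
    ped = dataclasses.replace(
        ped, case_flag=[s == "case" for s in phe["status"]]
    )
    ref = None
    if with_reference:
        freqs = np.nan_to_num(gm.allele_freqs(), nan=0.5)
        ref = simulate_reference_panel(freqs, config, snp_table=gm.snp_table)
    return SimBundle(config=config, pedigree=ped, genotypes=gm, phenotypes=phe, reference=ref)


def write_run_manifest(path, config: SimConfig, outputs: dict[str, str]) -> None:
    """Record the seed, all generator parameters and output paths."""
    payload = {
        "config": dataclasses.asdict(config),
        "outputs": outputs,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
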