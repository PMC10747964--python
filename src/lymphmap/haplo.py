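"""Sliding-window haplotypes, Gabriel-style blocks, runs of homozygosity
and the case/control homozygosity contingency test.

Haplotype counting prefers phased input; on unphased doses an
expectation-maximization phaser handles windows of up to 8 SNPs (the
window range used throughout is 2-8 SNPs, sliding 1 SNP at a time).
Haplotype strings are written in the allele alphabet of the SNP map, so a
window haplotype reads like "GCGCGGAA".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, ConfigError, GenotypeMatrix, InputError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Sliding windows

def sliding_windows(n_snps: int, min_width: int = 2, max_width: int = 8, step: int = 1) -> list[tuple[int, int]]:
    """All (start, width) windows; start+width never exceeds n_snps.

    For L SNPs and widths w in [min, max] there are sum_w (L - w + 1)
    windows; an input shorter than min_width yields an empty list with a
    warning.
    """
    if n_snps < min_width:
        logger.warning("only %d SNPs (< %d): no windows", n_snps, min_width)
        return []
    out = []
    for width in range(min_width, max_width + 1):
        for start in range(0, n_snps - width + 1, step):
            out.append((start, width))
    return out


# ---------------------------------------------------------------------------
# Window haplotype frequencies (phased tally or EM phasing)

MAX_EM_WIDTH = 8


@dataclass
class HaplotypeWindow:
    chromosome: object
    start: int
    width: int
    counts: dict[str, dict[str, float]]  # cohort -> haplotype string -> count
    em_converged: bool = True


def _dose_strings(alleles_a: np.ndarray, alleles_b: np.ndarray, haps: np.ndarray) -> list[str]:
    """Translate 0/1 haplotype rows into MAP-alphabet strings."""
    letters = np.where(haps.astype(bool), alleles_b, alleles_a)
    return ["".join(row) for row in letters]


def _em_phase(doses: np.ndarray, tol: float = 1e-6, max_iter: int = 200):
    """Haplotype-frequency EM on a window of unphased doses (w <= 8).

    Returns (freqs dict over binary tuples, expected counts per individual
    as dict hap->weight lists, converged flag).  Individuals with missing
    doses are excluded by the caller.
    """
    n, w = doses.shape
    if w > MAX_EM_WIDTH:
        raise ConfigError(f"EM phasing supports windows up to {MAX_EM_WIDTH} SNPs, got {w}")

    # enumerate the compatible haplotype pairs per individual
    pair_sets = []
    observed = set()
    for i in range(n):
        g = doses[i]
        hets = np.flatnonzero(g == 1)
        base = (g // 2).astype(np.uint8)  # 0->0, 2->1
        pairs = []
        if len(hets) == 0:
            h = tuple(base)
            pairs.append((h, h))
        else:
            first = hets[0]
            for combo in product((0, 1), repeat=len(hets) - 1):
                h1 = base.copy()
                h2 = base.copy()
                h1[first] = 1
                h2[first] = 0
                for site, bit in zip(hets[1:], combo):
                    h1[site] = bit
                    h2[site] = 1 - bit
                pairs.append((tuple(h1), tuple(h2)))
        pair_sets.append(pairs)
        for h1, h2 in pairs:
            observed.add(h1)
            observed.add(h2)

    freqs = {h: 1.0 / len(observed) for h in observed}
    converged = False
    for _ in range(max_iter):
        new = {h: 0.0 for h in observed}
        for pairs in pair_sets:
            weights = np.array(
                [freqs[h1] * freqs[h2] * (2.0 if h1 != h2 else 1.0) for h1, h2 in pairs]
            )
            total = weights.sum()
            if total == 0:
                weights = np.ones(len(pairs))
                total = float(len(pairs))
            weights /= total
            for (h1, h2), wgt in zip(pairs, weights):
                new[h1] += wgt
                new[h2] += wgt
        for h in new:
            new[h] /= 2.0 * n
        delta = max(abs(new[h] - freqs[h]) for h in observed)
        freqs = new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM phasing did not converge; reporting last iterate")

    # expected haplotype counts per individual under the final frequencies
    expected = []
    for pairs in pair_sets:
        weights = np.array(
            [freqs[h1] * freqs[h2] * (2.0 if h1 != h2 else 1.0) for h1, h2 in pairs]
        )
        total = weights.sum()
        if total == 0:
            weights = np.ones(len(pairs))
            total = float(len(pairs))
        weights /= total
        contrib: dict[tuple, float] = {}
        for (h1, h2), wgt in zip(pairs, weights):
            contrib[h1] = contrib.get(h1, 0.0) + wgt
            contrib[h2] = contrib.get(h2, 0.0) + wgt
        expected.append(contrib)
    return freqs, expected, converged


def window_haplotype_freqs(
    genotypes: GenotypeMatrix,
    window: tuple[int, int],
    cohorts: dict[str, str],
) -> HaplotypeWindow:
    """Haplotype-string counts per cohort over one window.

    ``cohorts`` maps sample_id -> cohort label.  With phased input the
    counts are direct string tallies; otherwise EM phasing produces
    expected counts.  Samples with a missing dose in the window are
    dropped, so counts sum to 2 x (complete samples) per cohort.
    """
    start, width = window
    st = genotypes.snp_table.iloc[start : start + width]
    if st["chrom"].nunique() != 1:
        raise InputError("window spans more than one chromosome")
    aa = st["allele_a"].to_numpy()
    ab = st["allele_b"].to_numpy()
    labels = [cohorts.get(s) for s in genotypes.sample_ids]
    counts: dict[str, dict[str, float]] = {}
    converged = True

    if genotypes.phased:
        h1, h2 = genotypes.haplotypes
        for i, lab in enumerate(labels):
            if lab is None:
                continue
            if np.any(genotypes.doses[i, start : start + width] == MISSING):
                continue
            for hap in (h1[i, start : start + width], h2[i, start : start + width]):
                s = "".join(np.where(hap.astype(bool), ab, aa))
                counts.setdefault(lab, {}).setdefault(s, 0)
                counts[lab][s] += 1
    else:
        for lab in sorted(set(l for l in labels if l is not None)):
            rows = [
                i for i, l in enumerate(labels)
                if l == lab and not np.any(genotypes.doses[i, start : start + width] == MISSING)
            ]
            if not rows:
                counts[lab] = {}
                continue
            sub = genotypes.doses[np.asarray(rows), start : start + width]
            _, expected, conv = _em_phase(sub)
            converged = converged and conv
            tally: dict[str, float] = {}
            for contrib in expected:
                for hap, wgt in contrib.items():
                    s = "".join(np.where(np.array(hap, dtype=bool), ab, aa))
                    tally[s] = tally.get(s, 0.0) + wgt
            counts[lab] = tally

    return HaplotypeWindow(
        chromosome=st["chrom"].iloc[0],
        start=start,
        width=width,
        counts=counts,
        em_converged=converged,
    )


# ---------------------------------------------------------------------------
# Gabriel-style haplotype blocks

DPRIME_GRID = np.linspace(0.0, 1.0, 201)


def _dprime_ci(hap_a: np.ndarray, hap_b: np.ndarray, mass: float = 0.90):
    """Likelihood-based confidence interval on |D'| from phased haplotypes.

    The likelihood of the 2x2 haplotype counts is profiled over |D'| with
    allele frequencies fixed at their MLEs; the CI bounds are the 5th and
    95th percentiles of the normalized likelihood mass on a |D'| grid.
    Returns (low, high) or None for an uninformative (monomorphic) pair.
    """
    pa = hap_a.mean()
    pb = hap_b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return None
    p11 = np.mean(hap_a * hap_b)
    d = p11 - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax <= 0:
        return None
    n11 = int(np.sum((hap_a == 1) & (hap_b == 1)))
    n10 = int(np.sum((hap_a == 1) & (hap_b == 0)))
    n01 = int(np.sum((hap_a == 0) & (hap_b == 1)))
    n00 = int(np.sum((hap_a == 0) & (hap_b == 0)))
    sign = 1.0 if d >= 0 else -1.0
    loglik = np.full(len(DPRIME_GRID), -np.inf)
    for k, dp in enumerate(DPRIME_GRID):
        dd = sign * dp * dmax
        f11 = pa * pb + dd
        f10 = pa * (1 - pb) - dd
        f01 = (1 - pa) * pb - dd
        f00 = (1 - pa) * (1 - pb) + dd
        fs = np.array([f11, f10, f01, f00])
        if np.any(fs < -1e-12):
            continue
        fs = np.clip(fs, 1e-12, None)
        loglik[k] = (
            n11 * np.log(fs[0]) + n10 * np.log(fs[1]) + n01 * np.log(fs[2]) + n00 * np.log(fs[3])
        )
    w = np.exp(loglik - loglik.max())
    w /= w.sum()
    cdf = np.cumsum(w)
    alpha = (1.0 - mass) / 2.0
    low = DPRIME_GRID[int(np.searchsorted(cdf, alpha))]
    high = DPRIME_GRID[int(np.searchsorted(cdf, 1.0 - alpha))]
    return float(low), float(high)


STRONG_LOW = 0.70
STRONG_HIGH = 0.98
RECOMB_HIGH = 0.90


def haplotype_blocks(
    genotypes: GenotypeMatrix,
    region: tuple[int, int] | None = None,
    min_informative_frac: float = 0.95,
) -> list[tuple[int, int]]:
    """Gabriel-style LD blocks over a (small) SNP index range.

    A pair is in strong LD when its |D'| CI has lower bound >= 0.70 and
    upper bound >= 0.98; it shows strong recombination when the upper bound
    is < 0.90; only those pairs are informative.  An interval is a block
    when at least ``min_informative_frac`` of its informative pairs are
    strong LD; maximal non-overlapping blocks are taken longest-first.
    """
    if not genotypes.phased:
        raise InputError("haplotype blocks need phased input")
    lo, hi = region if region is not None else (0, genotypes.n_snps - 1)
    idx = np.arange(lo, hi + 1)
    if len(idx) < 2:
        return []
    haps = np.concatenate([genotypes.haplotypes[0][:, idx], genotypes.haplotypes[1][:, idx]], axis=0)
    k = len(idx)
    strong = np.zeros((k, k), dtype=bool)
    informative = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            ci = _dprime_ci(haps[:, i], haps[:, j])
            if ci is None:
                continue
            low, high = ci
            if low >= STRONG_LOW and high >= STRONG_HIGH:
                strong[i, j] = informative[i, j] = True
            elif high < RECOMB_HIGH:
                informative[i, j] = True

    candidates = []
    for i in range(k):
        for j in range(i + 1, k):
            n_inf = int(informative[i : j + 1, i : j + 1].sum())
            n_str = int(strong[i : j + 1, i : j + 1].sum())
            if n_inf > 0 and n_str / n_inf >= min_informative_frac and strong[i, j]:
                candidates.append((i, j))
    candidates.sort(key=lambda ij: (-(ij[1] - ij[0]), ij[0]))
    taken: list[tuple[int, int]] = []
    used = np.zeros(k, dtype=bool)
    for i, j in candidates:
        if not used[i : j + 1].any():
            taken.append((int(idx[i]), int(idx[j])))
            used[i : j + 1] = True
    taken.sort()
    return taken


# ---------------------------------------------------------------------------
# Runs of homozygosity

def roh_in_region(
    genotypes: GenotypeMatrix,
    region: tuple[int, int] | None = None,
    min_run_snps: int = 2,
) -> dict[str, list[tuple[int, int]]]:
    """Maximal runs of consecutive homozygous SNPs per sample.

    Homozygous means dose 0 or 2; missing doses break a run.  Runs shorter
    than ``min_run_snps`` are dropped.  Returned intervals are SNP index
    pairs (inclusive) in genome-wide coordinates.
    """
    lo, hi = region if region is not None else (0, genotypes.n_snps - 1)
    out: dict[str, list[tuple[int, int]]] = {}
    sub = genotypes.doses[:, lo : hi + 1]
    hom = (sub == 0) | (sub == 2)
    for i, sid in enumerate(genotypes.sample_ids):
        runs = []
        start = None
        row = hom[i]
        for k in range(len(row) + 1):
            inside = k < len(row) and row[k]
            if inside and start is None:
                start = k
            elif not inside and start is not None:
                if k - start >= min_run_snps:
                    runs.append((lo + start, lo + k - 1))
                start = None
        out[sid] = runs
    return out


# ---------------------------------------------------------------------------
# 2x2 homozygosity test

@dataclass
class HomozygosityTable2x2:
    case_hom: int
    case_not: int
    control_hom: int
    control_not: int
    odds_ratio: float
    p_value: float

    @property
    def case_fraction(self) -> float:
        return self.case_hom / (self.case_hom + self.case_not)

    @property
    def control_fraction(self) -> float:
        return self.control_hom / (self.control_hom + self.control_not)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by the minimum-likelihood summation rule.

    With margins fixed, every table's hypergeometric probability is
    enumerated and those no more probable than the observed table (within a
    1 + 1e-7 tolerance for ties) are summed.  Symmetric under swapping the
    rows or the columns.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise InputError("contingency counts must be nonnegative")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0:
        raise InputError("empty contingency table")
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - kmin]
    return float(np.minimum(pmf[pmf <= p_obs * (1 + 1e-7)].sum(), 1.0))


def homozygosity_test(
    genotypes: GenotypeMatrix,
    snp_set: list[int],
    phenotypes: pd.DataFrame,
) -> HomozygosityTable2x2:
    """Fisher test of all-SNP homozygosity between cases and controls.

    A sample counts as homozygous only if it is homozygous (dose 0 or 2) at
    EVERY SNP in ``snp_set``; samples with a missing dose at any of them
    are excluded.
    """
    if len(phenotypes) == 0:
        raise InputError("empty phenotype table")
    idx = {s: i for i, s in enumerate(genotypes.sample_ids)}
    counts = {"case": [0, 0], "control": [0, 0]}
    snp_set = list(snp_set)
    for _, row in phenotypes.iterrows():
        i = idx.get(row["sample_id"])
        if i is None:
            raise InputError(f"phenotype sample {row['sample_id']!r} absent from genotypes")
        doses = genotypes.doses[i, snp_set]
        if np.any(doses == MISSING):
            continue
        hom = bool(np.all((doses == 0) | (doses == 2)))
        counts[row["status"]][0 if hom else 1] += 1
    (a, b), (c, d) = counts["case"], counts["control"]
    if a + b == 0 or c + d == 0:
        raise InputError("one cohort has no complete samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        oratio = (a * d) / (b * c) if b * c > 0 else np.inf
    return HomozygosityTable2x2(
        case_hom=a, case_not=b, control_hom=c, control_not=d,
        odds_ratio=float(oratio), p_value=fisher_exact_2x2(a, b, c, d),
    )
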