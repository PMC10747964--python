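"""MAF filtering, GRM construction and the mixed-linear-model scan.

The association model is the standard MLMA for a case/control trait
analysed on the observed 0/1 scale:

    y = X beta + x_snp b + g + e,   g ~ N(0, sigma_g^2 A),  e ~ N(0, sigma_e^2 I)

with A the genomic relationship matrix.  Variance components are estimated
once by REML on the null model (no SNP) — the EMMAX approximation — and
each SNP's effect is then a generalized-least-squares fit against
V = sigma_g^2 A + sigma_e^2 I, evaluated in the eigenbasis of A so the scan
costs O(n) per SNP after a single eigendecomposition.  The candidate SNP
remains in the GRM (no leave-one-chromosome-out).  Tests are two-sided
Wald chi-square(1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import MISSING, ConfigError, GenotypeMatrix, InputError

logger = logging.getLogger(__name__)


def filter_maf(genotypes: GenotypeMatrix, threshold: float = 0.02) -> GenotypeMatrix:
    """Drop SNPs with minor allele frequency strictly below ``threshold``.

    Monomorphic SNPs (MAF 0) are always dropped for any positive threshold.
    """
    freq = genotypes.allele_freqs()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(freq, 1.0 - freq)
    keep = maf >= threshold
    keep &= ~np.isnan(maf)
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise InputError(f"all {genotypes.n_snps} SNPs removed at MAF < {threshold}")
    logger.info("MAF filter < %g removed %d of %d SNPs", threshold, n_removed, genotypes.n_snps)
    return genotypes.subset_snps(keep)


@dataclass
class Grm:
    sample_ids: list[str]
    matrix: np.ndarray
    freqs: np.ndarray


def compute_grm(genotypes: GenotypeMatrix) -> Grm:
    """GCTA-style GRM: A_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)).

    Missing doses are mean-imputed per SNP; p_i is the observed frequency of
    the counted allele.  Zero-variance SNPs must have been filtered out.
    """
    d = np.where(genotypes.doses == MISSING, np.nan, genotypes.doses).astype(float)
    p = np.nanmean(d, axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        j = int(np.flatnonzero((p <= 0) | (p >= 1))[0])
        raise InputError(
            f"zero-variance SNP {genotypes.snp_table['snp_id'].iloc[j]!r} reached the GRM "
            "(apply the MAF filter first)"
        )
    d = np.where(np.isnan(d), 2.0 * p, d)
    z = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    a = (z @ z.T) / genotypes.n_snps
    return Grm(sample_ids=list(genotypes.sample_ids), matrix=a, freqs=p)


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    loglik: float

    @property
    def delta(self) -> float:
        """Ratio sigma_e^2 / sigma_g^2 (inf at the sigma_g^2 = 0 boundary)."""
        return np.inf if self.sigma_g2 == 0 else self.sigma_e2 / self.sigma_g2

    @property
    def h2(self) -> float:
        t = self.sigma_g2 + self.sigma_e2
        return 0.0 if t == 0 else self.sigma_g2 / t


@dataclass
class _Rotation:
    """Eigendecomposition of the GRM plus rotated data, reused by the scan."""

    eigvals: np.ndarray
    eigvecs: np.ndarray
    y_rot: np.ndarray
    x_rot: np.ndarray


def _rotate(phenotype: np.ndarray, grm: Grm, covariates: np.ndarray | None) -> _Rotation:
    n = len(phenotype)
    if grm.matrix.shape != (n, n):
        raise InputError("GRM dimension does not match phenotype length")
    x = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    s, u = np.linalg.eigh(grm.matrix)
    if s[0] < -1e-8:
        logger.warning("GRM has negative eigenvalues (min %.3g); flooring at 0", s[0])
    s = np.maximum(s, 0.0)
    return _Rotation(eigvals=s, eigvecs=u, y_rot=u.T @ phenotype, x_rot=u.T @ x)


def _reml_loglik(h2: float, lam: np.ndarray, eta2: np.ndarray) -> tuple[float, float]:
    """Profile restricted log-likelihood at heritability ratio h2.

    ``lam`` are the n-p eigenvalues of S A S (S the fixed-effect projection
    complement) and ``eta2`` the squared rotated data; the fixed-effect
    directions have already been projected out, which is what makes this
    the restricted likelihood and keeps a GRM null direction collinear with
    the intercept from spuriously driving h2 to 1.
    """
    dvec = h2 * lam + (1.0 - h2)
    if np.any(dvec <= 0):
        return -np.inf, np.nan
    k = len(lam)
    sigma2 = float(np.sum(eta2 / dvec)) / k
    if sigma2 <= 0:
        return -np.inf, np.nan
    ll = -0.5 * (k * (np.log(2 * np.pi * sigma2) + 1.0) + np.sum(np.log(dvec)))
    return ll, sigma2


def reml_null(
    phenotype: np.ndarray,
    grm: Grm,
    covariates: np.ndarray | None = None,
    grid_size: int = 64,
) -> VarianceComponents:
    """REML variance components of the null (no-SNP) model.

    EMMA-style: eigendecompose S A S with S = I - X(X'X)^-1 X', drop the p
    null directions belonging to the fixed effects, and profile the
    restricted likelihood over h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) on
    a grid over [0, 1) with golden-section refinement.  A flat likelihood
    (e.g. A = I, where the two components are not separately identifiable)
    resolves to the sigma_g^2 = 0 boundary by convention.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    n = len(phenotype)
    if grm.matrix.shape != (n, n):
        raise InputError("GRM dimension does not match phenotype length")
    x = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    p = x.shape[1]
    qx, _ = np.linalg.qr(x)
    sas = grm.matrix - qx @ (qx.T @ grm.matrix)
    sas = sas - (sas @ qx) @ qx.T
    sas = (sas + sas.T) / 2.0
    s, u = np.linalg.eigh(sas)
    if s[0] < -1e-8:
        logger.warning("projected GRM has negative eigenvalues (min %.3g); flooring at 0", s[0])
    lam = np.maximum(s[p:], 0.0)  # drop the p fixed-effect null directions
    eta = u[:, p:].T @ phenotype
    eta2 = eta * eta

    grid = np.linspace(0.0, 0.999, grid_size)
    lls = np.array([_reml_loglik(h, lam, eta2)[0] for h in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda h: -_reml_loglik(h, lam, eta2)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    h2 = float(res.x)
    ll, sigma2 = _reml_loglik(h2, lam, eta2)
    ll0, sigma2_0 = _reml_loglik(0.0, lam, eta2)
    if ll - ll0 < 1e-8:  # flat or boundary-preferring likelihood
        h2, ll, sigma2 = 0.0, ll0, sigma2_0
    vc = VarianceComponents(sigma_g2=h2 * sigma2, sigma_e2=(1.0 - h2) * sigma2, loglik=ll)
    logger.info("REML null model: sigma_g2=%.4g sigma_e2=%.4g h2=%.3f", vc.sigma_g2, vc.sigma_e2, vc.h2)
    return vc


ASSOC_COLUMNS = ["chrom", "pos", "snp_id", "freq", "effect", "se", "wald", "p"]


def mlma_scan(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    grm: Grm,
    vc: VarianceComponents,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP GLS effects and Wald p-values against V = sg2 A + se2 I.

    Uses the eigenbasis of A; the SNP stays in the GRM (classic MLMA).  A
    SNP collinear with the covariates gets a missing p with a logged reason.
    Missing doses are mean-imputed per SNP, matching the GRM convention.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    rot = _rotate(phenotype, grm, covariates)
    n, p = rot.x_rot.shape
    dvec = vc.sigma_g2 * rot.eigvals + vc.sigma_e2
    if np.any(dvec <= 0):
        raise InputError("variance matrix is singular; check variance components")
    w = 1.0 / dvec

    d = np.where(genotypes.doses == MISSING, np.nan, genotypes.doses).astype(float)
    freqs = np.nanmean(d, axis=0) / 2.0
    d = np.where(np.isnan(d), 2.0 * freqs, d)
    g_rot = rot.eigvecs.T @ d  # n x m

    xw = rot.x_rot * w[:, None]          # n x p
    xtwx_inv = np.linalg.inv(rot.x_rot.T @ xw)
    xtwy = xw.T @ rot.y_rot              # p
    a1 = xw.T @ g_rot                    # p x m  (X' W G)
    gwg = np.einsum("ij,ij->j", g_rot * w[:, None], g_rot)   # diag(G' W G)
    gwy = g_rot.T @ (w * rot.y_rot)      # m

    # residualized quadratic forms: x~' W x~ and x~' W y
    xtWx_res = gwg - np.einsum("pj,pj->j", a1, xtwx_inv @ a1)
    xtWy_res = gwy - a1.T @ (xtwx_inv @ xtwy)

    with np.errstate(divide="ignore", invalid="ignore"):
        effect = xtWy_res / xtWx_res
        var_b = 1.0 / xtWx_res
        wald = effect * effect / var_b
        pvals = stats.chi2.sf(wald, df=1)

    singular = xtWx_res <= 1e-10 * np.maximum(gwg, 1e-300)
    if singular.any():
        for j in np.flatnonzero(singular)[:10]:
            logger.warning(
                "SNP %s collinear with covariates; p set missing",
                genotypes.snp_table["snp_id"].iloc[j],
            )
        effect[singular] = np.nan
        wald[singular] = np.nan
        pvals[singular] = np.nan

    out = genotypes.snp_table[["chrom", "pos", "snp_id"]].copy()
    out["freq"] = freqs
    out["effect"] = effect
    out["se"] = np.sqrt(var_b)
    out["wald"] = wald
    out["p"] = np.clip(pvals, np.finfo(float).tiny, 1.0)
    out.loc[np.isnan(pvals), "p"] = np.nan
    return out


def subset_young_onset(
    phenotypes: pd.DataFrame,
    case_max_age: float = 6.0,
    control_min_age: float = 7.0,
) -> pd.DataFrame:
    """Young-onset design: cases with age <= 6, controls strictly above 7."""
    age = phenotypes["age_years"]
    is_case = phenotypes["status"] == "case"
    keep_case = is_case & age.notna() & (age <= case_max_age)
    keep_ctrl = ~is_case & age.notna() & (age > control_min_age)
    sel = phenotypes[keep_case | keep_ctrl].reset_index(drop=True)
    n_case = int((sel["status"] == "case").sum())
    n_ctrl = len(sel) - n_case
    if n_case == 0 or n_ctrl == 0:
        raise InputError(
            f"young-onset subset is degenerate: {n_case} cases, {n_ctrl} controls"
        )
    logger.info("young-onset subset: %d cases, %d controls", n_case, n_ctrl)
    return sel


def gwas_pipeline_quantitative(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    maf: float = 0.02,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """MAF filter -> GRM -> null REML -> scan for a quantitative trait vector
    aligned with the genotype sample order."""
    gm = filter_maf(genotypes, maf)
    grm = compute_grm(gm)
    y = np.asarray(phenotype, dtype=float)
    vc = reml_null(y, grm, covariates)
    return mlma_scan(gm, y, grm, vc, covariates)


def gwas_pipeline(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    maf: float = 0.02,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """MAF filter -> GRM -> null REML -> scan, aligned on the phenotype table."""
    order = [genotypes.by_sample_index(s) for s in phenotypes["sample_id"]]
    gm = genotypes.subset_samples(np.array(order))
    gm = filter_maf(gm, maf)
    grm = compute_grm(gm)
    y = (phenotypes["status"] == "case").to_numpy(dtype=float)
    vc = reml_null(y, grm, covariates)
    return mlma_scan(gm, y, grm, vc, covariates)
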