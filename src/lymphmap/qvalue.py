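"""Storey q-values with spline-smoothed pi0, genome-wide and per chromosome.

pi0 is estimated as pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a
lambda grid, smoothed with a natural cubic regression spline (3 df) and
read off at the largest lambda, then clipped to (0, 1].  q-values follow
the usual cumulative-minimum rule q_(i) = min_{j>=i} pi0 * m * p_(j) / j;
with pi0 = 1 this reduces exactly to Benjamini–Hochberg adjusted p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import InputError

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = np.round(np.arange(0.05, 0.9001, 0.05), 10)


def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (intercept, linear, K-2 curvature terms)."""
    k = knots
    K = len(k)

    def d(j, xx):
        num = np.clip(xx - k[j], 0, None) ** 3 - np.clip(xx - k[K - 1], 0, None) ** 3
        return num / (k[K - 1] - k[j])

    cols = [np.ones_like(x), x]
    for j in range(K - 2):
        cols.append(d(j, x) - d(K - 2, x))
    return np.column_stack(cols)


def estimate_pi0(pvalues: np.ndarray, lambda_grid: np.ndarray = DEFAULT_LAMBDA) -> tuple[float, np.ndarray]:
    """Spline-smoothed Storey pi0 estimate; returns (pi0, raw pi0(lambda))."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    lam = np.asarray(lambda_grid, dtype=float)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    # 3-df natural cubic spline: knots at the grid's min, median and max
    knots = np.quantile(lam, [0.0, 0.5, 1.0])
    basis = _natural_spline_basis(lam, knots)
    coef, *_ = np.linalg.lstsq(basis, pi0_lam, rcond=None)
    at_max = _natural_spline_basis(np.array([lam.max()]), knots) @ coef
    pi0 = float(np.clip(at_max[0], np.finfo(float).tiny, 1.0))
    if at_max[0] <= 0:
        logger.warning("pi0 spline estimate non-positive (%.3g); clipped", at_max[0])
    return pi0, pi0_lam


@dataclass
class QvalueResult:
    pi0: float
    qvalues: np.ndarray
    lambda_grid: np.ndarray
    pi0_lambda: np.ndarray


def storey_qvalues(
    pvalues,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA,
    pi0: float | None = None,
) -> QvalueResult:
    """Storey q-values for a vector of p-values in (0, 1].

    ``pi0`` may be forced (pi0=1 gives exactly Benjamini–Hochberg).
    q-values are invariant to the input order; ties in p share a q because
    the cumulative minimum runs over the stably sorted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise InputError("p-values must be a non-empty 1-d vector")
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    m = len(p)
    if pi0 is None:
        pi0, pi0_lam = estimate_pi0(p, lambda_grid)
    else:
        if not (0 < pi0 <= 1):
            raise InputError("pi0 must lie in (0, 1]")
        pi0_lam = np.array([])
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    # ties share the smallest q among equal p (cumulative min guarantees it)
    q = np.empty(m)
    q[order] = q_sorted
    return QvalueResult(pi0=pi0, qvalues=q, lambda_grid=np.asarray(lambda_grid), pi0_lambda=pi0_lam)


MIN_SNPS_PER_CHROM = 20


def add_qvalues(assoc: pd.DataFrame, pi0: float | None = None) -> pd.DataFrame:
    """Attach genome-wide and chromosome-wise Storey q-value columns.

    A chromosome with fewer than 20 testable SNPs gets pi0 fixed to 1 (the
    spline is unstable on so few points), with a logged warning.
    """
    out = assoc.reset_index(drop=True).copy()
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    res = storey_qvalues(out.loc[ok, "p"].to_numpy(), pi0=pi0)
    q[ok.to_numpy()] = res.qvalues
    out["q_genome"] = q
    out.attrs["pi0_genome"] = res.pi0

    qc = np.full(len(out), np.nan)
    for chrom, idx in out.groupby("chrom", sort=False).groups.items():
        mask = out.loc[idx, "p"].notna()
        pv = out.loc[idx, "p"][mask].to_numpy()
        if len(pv) == 0:
            continue
        pi0_c = pi0
        if pi0_c is None and len(pv) < MIN_SNPS_PER_CHROM:
            logger.warning(
                "chromosome %s has %d SNPs (<%d); pi0 fixed to 1",
                chrom, len(pv), MIN_SNPS_PER_CHROM,
            )
            pi0_c = 1.0
        res_c = storey_qvalues(pv, pi0=pi0_c)
        qc[np.asarray(idx)[mask.to_numpy()]] = res_c.qvalues
    out["q_chrom"] = qc
    return out
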